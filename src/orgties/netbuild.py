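"""Build symmetric contact networks from survey nominations.

Roster surveys yield *directed* reports: each responding organization
says, for every other roster member, whether it has contact, how often,
and which resources it exchanges. Converting reports to an undirected
network uses the standard symmetrization rule for whole-network data
with non-response: a relation between two members exists if **at least
one** of them (through any of its boundary spanners) reported it.

Under that rule a non-responder is not lost: its ties are imputed from
its partners' incoming reports — *labeled reconstruction*, i.e.
transposing the reported columns into the missing rows of the adjacency
matrix. :func:`labeled_reconstruction` implements that step explicitly
(as an elementwise maximum with the transpose) so the imputation is
auditable even though it is mathematically subsumed by symmetrization.

When reports disagree on frequency (two spanners of one organization,
or the two endpoints), the maximum is kept: it is the monotone
completion of the "at least one" existence rule. Exchange flags are
OR-ed across reports for the same reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .roster_io import (
    Nomination,
    Roster,
    RosterError,
    EXCHANGE_CR,
    EXCHANGE_EK,
    read_adjacency,
    write_adjacency,
)

logger = logging.getLogger(__name__)


@dataclass
class ContactNetwork:
    """Per-wave symmetric valued contact network.

    Three aligned node-by-node matrices describe each dyad: ``freq``
    holds the contact frequency ordinal (0 = no contact, 1–4 = annual
    through daily), ``ek`` and ``cr`` are binary indicators for
    expertise-&-knowledge sharing and client referral. A named resource
    exchange implies contact (``ek+cr >= 1`` forces ``freq >= 1``), but
    contact may exist with neither named resource.
    """

    wave: str
    nodes: list[str]
    freq: np.ndarray
    ek: np.ndarray
    cr: np.ndarray

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=int)
        self.ek = np.asarray(self.ek, dtype=int)
        self.cr = np.asarray(self.cr, dtype=int)
        self.validate()

    def validate(self) -> None:
        n = len(self.nodes)
        for name, m in (("freq", self.freq), ("ek", self.ek), ("cr", self.cr)):
            if m.shape != (n, n):
                raise ValueError(f"{name} matrix shape {m.shape} != ({n}, {n})")
            if not np.array_equal(m, m.T):
                raise ValueError(f"{name} matrix is not symmetric")
            if np.any(np.diag(m) != 0):
                raise ValueError(f"{name} matrix has a nonzero diagonal")
        if self.freq.min() < 0 or self.freq.max() > 4:
            raise ValueError("freq entries must be in 0-4")
        for name, m in (("ek", self.ek), ("cr", self.cr)):
            if not np.isin(m, (0, 1)).all():
                raise ValueError(f"{name} entries must be binary")
            if np.any((m == 1) & (self.freq == 0)):
                raise ValueError(f"{name} flag set on a dyad with no contact (freq=0)")

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def contact(self) -> np.ndarray:
        """Binary contact indicator matrix (freq >= 1)."""
        return (self.freq >= 1).astype(int)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        idx = pd.Index(self.nodes)
        return {
            "freq": pd.DataFrame(self.freq, index=idx, columns=idx),
            "ek": pd.DataFrame(self.ek, index=idx, columns=idx),
            "cr": pd.DataFrame(self.cr, index=idx, columns=idx),
        }

    def save(self, directory) -> None:
        """Write freq.csv, ek.csv, cr.csv into ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, frame in self.to_frames().items():
            write_adjacency(frame, directory / f"{name}.csv")

    @classmethod
    def load(cls, directory, wave: str) -> "ContactNetwork":
        directory = Path(directory)
        frames = {name: read_adjacency(directory / f"{name}.csv") for name in ("freq", "ek", "cr")}
        nodes = list(frames["freq"].index)
        for name, frame in frames.items():
            if list(frame.index) != nodes:
                raise RosterError(f"{name}.csv node labels differ from freq.csv")
        return cls(
            wave=wave,
            nodes=nodes,
            freq=frames["freq"].to_numpy(),
            ek=frames["ek"].to_numpy(),
            cr=frames["cr"].to_numpy(),
        )


@dataclass
class PanelNetworks:
    """Two waves restricted to the organizations present in both.

    Statistical comparison of network structure over time (QAP, stable
    networks) requires the same actors in both matrices, so the node
    set is the membership intersection, in roster order, and both
    networks share that ordering.
    """

    nodes: list[str]
    net_w1: ContactNetwork
    net_w2: ContactNetwork

    def __post_init__(self) -> None:
        if self.net_w1.nodes != self.nodes or self.net_w2.nodes != self.nodes:
            raise ValueError("panel networks must share the panel node ordering")


def labeled_reconstruction(directed: np.ndarray) -> np.ndarray:
    """Impute missing rows from reported columns by symmetrizing.

    For a directed report matrix, a non-responder's (all-zero) row is
    filled from the column of reports its partners made about it: the
    elementwise maximum of the matrix with its transpose.
    """
    directed = np.asarray(directed)
    return np.maximum(directed, directed.T)


def build_contact_network(
    noms: list[Nomination], roster: Roster, wave: str
) -> ContactNetwork:
    """Aggregate one wave's nominations into a symmetric contact network.

    The node set is the roster's membership for ``wave`` (roster order).
    For each dyad, frequency is the maximum over all reports in either
    direction from any spanner, and the exchange flags are OR-ed over
    the same reports; rows of non-responders are then completed by
    :func:`labeled_reconstruction`. Nominations from a different wave,
    or naming organizations outside the wave membership, are errors.
    """
    nodes = roster.members(wave)
    idx = {org_id: k for k, org_id in enumerate(nodes)}
    n = len(nodes)
    freq = np.zeros((n, n), dtype=int)
    ek = np.zeros((n, n), dtype=int)
    cr = np.zeros((n, n), dtype=int)
    for nom in noms:
        if nom.wave != wave:
            raise RosterError(
                f"nomination {nom.reporter!r}->{nom.alter!r} belongs to wave "
                f"{nom.wave!r}, not {wave!r}"
            )
        for org_id in (nom.reporter, nom.alter):
            if org_id not in idx:
                raise RosterError(
                    f"nomination names {org_id!r}, which is not a member of wave {wave!r}"
                )
        i, j = idx[nom.reporter], idx[nom.alter]
        freq[i, j] = max(freq[i, j], nom.frequency)
        if EXCHANGE_EK in nom.exchanges:
            ek[i, j] = 1
        if EXCHANGE_CR in nom.exchanges:
            cr[i, j] = 1
    freq = labeled_reconstruction(freq)
    ek = labeled_reconstruction(ek)
    cr = labeled_reconstruction(cr)
    if not noms:
        logger.warning("wave %s: no nominations, contact network is empty", wave)
    return ContactNetwork(wave=wave, nodes=nodes, freq=freq, ek=ek, cr=cr)


def align_panel(net_a: ContactNetwork, net_b: ContactNetwork) -> PanelNetworks:
    """Restrict two waves to their shared organizations.

    The panel node set is the intersection of the two node sets, kept
    in ``net_a``'s (roster) order; all matrices are subset accordingly.
    An empty intersection is an error.
    """
    shared = set(net_a.nodes) & set(net_b.nodes)
    if not shared:
        raise RosterError("panel alignment: the two waves share no organizations")
    nodes = [org_id for org_id in net_a.nodes if org_id in shared]
    logger.info(
        "panel: %d organizations present in both waves (of %d and %d)",
        len(nodes), len(net_a), len(net_b),
    )

    def restrict(net: ContactNetwork) -> ContactNetwork:
        sel = np.array([net.nodes.index(org_id) for org_id in nodes])
        return ContactNetwork(
            wave=net.wave,
            nodes=nodes,
            freq=net.freq[np.ix_(sel, sel)],
            ek=net.ek[np.ix_(sel, sel)],
            cr=net.cr[np.ix_(sel, sel)],
        )

    return PanelNetworks(nodes=nodes, net_w1=restrict(net_a), net_w2=restrict(net_b))
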