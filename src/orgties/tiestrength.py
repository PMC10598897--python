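"""Strong-tie classification.

Relationship strength between organizations is operationalized by three
dimensions jointly: contact *frequency* (annual/monthly/weekly/daily),
*reciprocity* of the resource exchange (expertise & knowledge sharing
requires active participation of both sides, client referral does not),
and *multiplexity* (a dyad exchanging several resource types stays
connected if one exchange stops, so multiplex relations are stronger).

The classification grid is:

====================================  =====  ======  =======  ======
exchange pattern                      daily  weekly  monthly  annual
====================================  =====  ======  =======  ======
expertise & knowledge + client ref.   strong strong  strong   —
expertise & knowledge only            strong strong  —        —
client referral only                  —      —       —        —
====================================  =====  ======  =======  ======

i.e. a relation is strong iff the organizations share expertise and
knowledge at least weekly, or engage in both expertise-&-knowledge
sharing and client referral at least monthly. Client-referral-only
contact is never strong (no reciprocity), and annual contact is never
strong. Exactly 5 of the 12 (frequency x nonempty-exchange-pattern)
cells are strong.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .netbuild import ContactNetwork

__all__ = ["StrongTieNetwork", "classify_strong", "strong_network"]


@dataclass
class StrongTieNetwork:
    """Binary symmetric network of strong inter-organizational relations."""

    wave: str
    nodes: list[str]
    adj: np.ndarray

    def __post_init__(self) -> None:
        self.adj = np.asarray(self.adj, dtype=int)
        n = len(self.nodes)
        if self.adj.shape != (n, n):
            raise ValueError(f"adjacency shape {self.adj.shape} != ({n}, {n})")
        if not np.isin(self.adj, (0, 1)).all():
            raise ValueError("strong-tie adjacency must be binary")
        if not np.array_equal(self.adj, self.adj.T):
            raise ValueError("strong-tie adjacency must be symmetric")
        if np.any(np.diag(self.adj) != 0):
            raise ValueError("strong-tie adjacency must have a zero diagonal")

    def __len__(self) -> int:
        return len(self.nodes)

    def degrees(self) -> np.ndarray:
        return self.adj.sum(axis=1)

    def edges(self) -> list[tuple[str, str]]:
        """Unordered strong dyads as (id, id) pairs in node order."""
        ii, jj = np.nonzero(np.triu(self.adj, 1))
        return [(self.nodes[i], self.nodes[j]) for i, j in zip(ii, jj)]

    def to_frame(self) -> pd.DataFrame:
        idx = pd.Index(self.nodes)
        return pd.DataFrame(self.adj, index=idx, columns=idx)


def classify_strong(freq: int, ek: int, cr: int) -> bool:
    """Classify one dyad: is the relation strong?

    Parameters are the contact frequency ordinal (0-4) and the binary
    expertise-&-knowledge and client-referral exchange flags. A named
    exchange on a dyad without contact (freq=0) violates the contact-
    network invariant and raises ``ValueError``.
    """
    if freq == 0 and (ek or cr):
        raise ValueError("exchange flag set on a dyad with no contact (freq=0)")
    if not 0 <= freq <= 4:
        raise ValueError(f"frequency ordinal {freq} outside 0-4")
    return bool(ek and cr and freq >= 2) or bool(ek and freq >= 3)


def strong_network(net: ContactNetwork) -> StrongTieNetwork:
    """Apply the strong-tie rule elementwise to a contact network.

    The result is a binary symmetric network whose edge set is a subset
    of the contact network's edges.
    """
    ek = net.ek.astype(bool)
    cr = net.cr.astype(bool)
    strong = (ek & cr & (net.freq >= 2)) | (ek & (net.freq >= 3))
    return StrongTieNetwork(wave=net.wave, nodes=list(net.nodes), adj=strong.astype(int))
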