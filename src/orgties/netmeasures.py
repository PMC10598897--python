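"""Descriptive whole-network measures for strong-tie structures.

The measures follow the standard reporting conventions of
whole-network analysis software: active organizations (>= 1 strong tie) and
isolates, the relation count as the symmetric adjacency-matrix cell
sum (i.e. ordered pairs, so each undirected tie counts twice), average
degree centrality as relations / n with isolates in the denominator,
the per-node degree range, and the share of contact relations that
qualify as strong. Displayed percentages and average degrees are
rounded half-up to the nearest integer.

The ordered-pair relation convention makes ``avg_degree`` exactly
``relation_count / n_orgs``: e.g. 782 relations among 119 organizations
give 6.57, displayed as 7.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .netbuild import ContactNetwork
from .roster_io import Roster
from .tiestrength import StrongTieNetwork

__all__ = [
    "MeasuresReport",
    "measures",
    "degree_sequence",
    "round_half_up",
    "pct_display",
    "avg_degree_display",
]


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero-point-five up
    (8.507 -> 9, 6.5 -> 7), matching conventional table display."""
    return int(math.floor(x + 0.5))


def pct_display(count: int, total: int) -> int:
    """Integer display percentage of ``count / total``, half-up."""
    if total == 0:
        return 0
    return round_half_up(100.0 * count / total)


def avg_degree_display(relation_count: int, n_orgs: int) -> int:
    """Integer display average degree: relations / n, half-up."""
    if n_orgs == 0:
        return 0
    return round_half_up(relation_count / n_orgs)


@dataclass
class MeasuresReport:
    """Descriptive statistics of one wave's strong-tie network."""

    wave: str
    n_orgs: int
    n_active: int
    pct_active: int
    n_isolates: int
    relation_count: int
    avg_degree: float
    avg_degree_display: int
    degree_range: tuple[int, int]
    contact_pair_count: int
    pct_strong_of_contacts: int
    gatekeeper_degrees: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "wave": self.wave,
            "n_orgs": self.n_orgs,
            "n_active": self.n_active,
            "pct_active": self.pct_active,
            "n_isolates": self.n_isolates,
            "relation_count": self.relation_count,
            "avg_degree": self.avg_degree,
            "avg_degree_display": self.avg_degree_display,
            "degree_min": self.degree_range[0],
            "degree_max": self.degree_range[1],
            "contact_pair_count": self.contact_pair_count,
            "pct_strong_of_contacts": self.pct_strong_of_contacts,
            "gatekeeper_degrees": dict(self.gatekeeper_degrees),
        }
        return d


def measures(
    strong: StrongTieNetwork,
    contact: ContactNetwork | None = None,
    roster: Roster | None = None,
) -> MeasuresReport:
    """Compute the descriptive report for a strong-tie network.

    ``contact`` (same node set) supplies the denominator for the share
    of contact relations that are strong; ``roster`` supplies gatekeeper
    identities for the per-gatekeeper degree listing. Both are optional.
    Isolates count toward the average-degree denominator.
    """
    n = len(strong)
    deg = strong.degrees()
    n_active = int((deg > 0).sum())
    relation_count = int(strong.adj.sum())
    if n == 0 or relation_count == 0:
        degree_range = (0, 0)
    else:
        degree_range = (int(deg.min()), int(deg.max()))
    avg = relation_count / n if n else 0.0

    contact_pairs = 0
    pct_strong = 0
    if contact is not None:
        if contact.nodes != strong.nodes:
            raise ValueError("contact and strong networks have different node sets")
        contact_pairs = int(contact.contact.sum())
        pct_strong = pct_display(relation_count, contact_pairs)

    gk_degrees: dict[str, int] = {}
    if roster is not None:
        pos = {org_id: k for k, org_id in enumerate(strong.nodes)}
        for org in roster.gatekeepers():
            if org.org_id in pos:
                gk_degrees[org.org_id] = int(deg[pos[org.org_id]])

    return MeasuresReport(
        wave=strong.wave,
        n_orgs=n,
        n_active=n_active,
        pct_active=pct_display(n_active, n),
        n_isolates=n - n_active,
        relation_count=relation_count,
        avg_degree=avg,
        avg_degree_display=avg_degree_display(relation_count, n),
        degree_range=degree_range,
        contact_pair_count=contact_pairs,
        pct_strong_of_contacts=pct_strong,
        gatekeeper_degrees=gk_degrees,
    )


def degree_sequence(strong: StrongTieNetwork) -> list[tuple[str, int]]:
    """Per-organization strong degree, descending (node order breaks
    ties) — the data behind degree-centrality scatter plots whose heavy
    right tail reveals hub organizations."""
    deg = strong.degrees()
    order = sorted(range(len(strong)), key=lambda i: (-deg[i], i))
    return [(strong.nodes[i], int(deg[i])) for i in order]
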