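"""Longitudinal stability of strong ties: Jaccard overlap and QAP tests.

Whether the strong relations observed in one year are the same dyads as
the year before is quantified by the Jaccard coefficient over unordered
dyads, |E1 ∩ E2| / |E1 ∪ E2| ∈ [0, 1] (0 = no overlap, 1 = complete
overlap). Statistical significance comes from the Quadratic Assignment
Procedure (QAP): the node labels of one matrix are permuted uniformly
at random (rows and columns simultaneously, preserving the network's
structure while destroying the node correspondence) and the coefficient
is recomputed; the observed value is compared against this permutation
null. P-values use the add-one convention, p = (1 + #extreme) / (B + 1),
and the two-tailed p is the doubled smaller tail capped at 1.

The same machinery applies per gatekeeper: the ego variant compares an
organization's alter-tie vector across waves, with a null that permutes
the entries of one vector.

The *stable network* is the elementwise AND of two waves' strong-tie
matrices — the relations present in both years.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations as _all_permutations

import numpy as np

from .netmeasures import pct_display
from .roster_io import Roster
from .tiestrength import StrongTieNetwork

__all__ = ["QapResult", "StabilityReport", "jaccard", "qap_jaccard", "ego_qap", "stability"]


@dataclass
class QapResult:
    """Observed Jaccard statistic with its permutation-null summary."""

    statistic: float
    n_permutations: int
    p_one_tailed_ge: float
    p_one_tailed_le: float
    p_two_tailed: float
    null_mean: float
    null_sd: float
    seed: int | None = None

    def as_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "n_permutations": self.n_permutations,
            "p_one_tailed_ge": self.p_one_tailed_ge,
            "p_one_tailed_le": self.p_one_tailed_le,
            "p_two_tailed": self.p_two_tailed,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "seed": self.seed,
        }


@dataclass
class StabilityReport:
    """Stable strong-tie network (two-wave intersection) and its counts."""

    stable_net: StrongTieNetwork
    n_stable_relations: int       # ordered-pair count (matrix cell sum)
    n_orgs_with_stable: int
    pct_orgs_with_stable: int

    def as_dict(self) -> dict:
        return {
            "n_stable_relations": self.n_stable_relations,
            "n_orgs_with_stable": self.n_orgs_with_stable,
            "pct_orgs_with_stable": self.pct_orgs_with_stable,
        }


def _dyad_vector(m: np.ndarray) -> np.ndarray:
    """Binary indicator over unordered off-diagonal dyads."""
    m = np.asarray(m)
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu] > 0


def _jaccard_bool(a: np.ndarray, b: np.ndarray) -> float:
    union = int(np.count_nonzero(a | b))
    if union == 0:
        raise ValueError("Jaccard undefined: both edge sets are empty")
    return int(np.count_nonzero(a & b)) / union


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard overlap of two binary symmetric matrices over unordered
    dyads. The matrices must share node set and ordering; both being
    edgeless leaves the coefficient undefined (``ValueError``)."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("Jaccard requires two square matrices of identical shape")
    return _jaccard_bool(_dyad_vector(a), _dyad_vector(b))


def _pvalues(observed: float, null: np.ndarray) -> tuple[float, float, float]:
    b = len(null)
    eps = 1e-12  # tolerate float round-off in tail counting
    p_ge = (1 + int(np.count_nonzero(null >= observed - eps))) / (b + 1)
    p_le = (1 + int(np.count_nonzero(null <= observed + eps))) / (b + 1)
    p_two = min(1.0, 2.0 * min(p_ge, p_le))
    return p_ge, p_le, p_two


def qap_jaccard(
    a: np.ndarray,
    b: np.ndarray,
    n_permutations: int = 2500,
    seed: int | None = None,
    exhaustive: bool = False,
) -> QapResult:
    """QAP permutation test of the Jaccard overlap between two networks.

    The null distribution relabels ``b``'s nodes by a uniformly random
    permutation applied simultaneously to rows and columns (sampled
    with replacement), recomputing the dyadic Jaccard each time. With
    ``exhaustive=True`` all n! permutations are enumerated instead
    (feasible only for small n); ``n_permutations`` is then the number
    enumerated.
    """
    a, b = np.asarray(a), np.asarray(b)
    observed = jaccard(a, b)
    av = _dyad_vector(a)
    if exhaustive:
        n = a.shape[0]
        null = np.array(
            [
                _jaccard_bool(av, _dyad_vector(b[np.ix_(p, p)]))
                for p in map(list, _all_permutations(range(n)))
            ]
        )
        n_permutations = len(null)
    else:
        if n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        rng = np.random.default_rng(seed)
        null = np.empty(n_permutations)
        for k in range(n_permutations):
            p = rng.permutation(a.shape[0])
            null[k] = _jaccard_bool(av, _dyad_vector(b[np.ix_(p, p)]))
    p_ge, p_le, p_two = _pvalues(observed, null)
    return QapResult(
        statistic=observed,
        n_permutations=n_permutations,
        p_one_tailed_ge=p_ge,
        p_one_tailed_le=p_le,
        p_two_tailed=p_two,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=0)),
        seed=seed,
    )


def ego_qap(
    a: np.ndarray,
    b: np.ndarray,
    node: int,
    n_permutations: int = 2500,
    seed: int | None = None,
) -> QapResult:
    """QAP Jaccard test for one organization's ego ties across waves.

    The statistic is the Jaccard overlap of the node's alter-tie
    vectors (length n − 1, the node's own entry removed); the null
    permutes the entries of the second vector. An ego with no ties in
    either wave has an undefined coefficient (``ValueError``).
    """
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError("ego QAP requires matrices of identical shape")
    row_a = np.delete(a[node], node) > 0
    row_b = np.delete(b[node], node) > 0
    observed = _jaccard_bool(row_a, row_b)
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    for k in range(n_permutations):
        null[k] = _jaccard_bool(row_a, rng.permutation(row_b))
    p_ge, p_le, p_two = _pvalues(observed, null)
    return QapResult(
        statistic=observed,
        n_permutations=n_permutations,
        p_one_tailed_ge=p_ge,
        p_one_tailed_le=p_le,
        p_two_tailed=p_two,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=0)),
        seed=seed,
    )


def stability(
    a: StrongTieNetwork, b: StrongTieNetwork, roster: Roster | None = None
) -> StabilityReport:
    """Stable strong-tie network: relations present in both waves.

    The stable network is the elementwise AND of the two adjacency
    matrices (node sets must match); counts use the same ordered-pair
    convention as the descriptive measures.
    """
    if a.nodes != b.nodes:
        raise ValueError("stability requires identical node sets and ordering")
    stable_adj = (a.adj & b.adj).astype(int)
    net = StrongTieNetwork(wave=f"{a.wave}&{b.wave}", nodes=list(a.nodes), adj=stable_adj)
    deg = net.degrees()
    n_with = int((deg > 0).sum())
    return StabilityReport(
        stable_net=net,
        n_stable_relations=int(stable_adj.sum()),
        n_orgs_with_stable=n_with,
        pct_orgs_with_stable=pct_display(n_with, len(net)),
    )
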