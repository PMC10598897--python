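"""Lambda sets: ranking relations by edge connectivity.

The lambda-set approach ranks every relation in a network by how much
of the flow between actors depends on it. The primitive is the pairwise
*edge connectivity* λ(i, j): the minimum number of edges whose removal
disconnects i from j, equal (max-flow = min-cut) to the number of
edge-disjoint i–j paths. A *lambda set* is a maximal group of nodes
whose internal pairwise connectivity exceeds their connectivity to any
outside node; the edges inside the top-ranked (highest-λ) lambda set
are the network's most flow-critical relations — the relations whose
disruption would most severely fragment resource flow.

Because λ obeys the connectivity triangle property
λ(i, k) >= min(λ(i, j), λ(j, k)), thresholding the λ-matrix at each
distinct value from high to low yields a nested hierarchy of node
groups; every threshold component of size >= 2 is a lambda set.

λ is computed from a Gomory–Hu tree per connected component (n − 1
unit-capacity max-flows per component): λ(i, j) is the minimum edge
weight on the unique tree path between i and j.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .tiestrength import StrongTieNetwork

__all__ = ["LambdaResult", "edge_connectivity", "lambda_matrix", "lambda_analysis"]


@dataclass
class LambdaResult:
    """Pairwise edge connectivity, lambda hierarchy and critical edges.

    ``hierarchy`` lists (λ level, node sets) from the highest level
    down; at each level the sets are the maximal groups whose internal
    connectivity is at least that level (and exceeds their connectivity
    to the outside). ``critical_edges`` are the network edges internal
    to the first-ranked top set (ties broken by the earliest node in
    roster order).
    """

    nodes: list[str]
    lambda_matrix: np.ndarray
    hierarchy: list[tuple[int, list[list[str]]]]
    critical_edges: list[tuple[str, str]]
    lambda_max: int

    def as_dict(self) -> dict:
        return {
            "nodes": list(self.nodes),
            "lambda_max": self.lambda_max,
            "hierarchy": [
                {"level": int(level), "sets": [list(s) for s in sets]}
                for level, sets in self.hierarchy
            ],
            "critical_edges": [list(e) for e in self.critical_edges],
        }


def _to_graph(strong: StrongTieNetwork) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(strong)))
    ii, jj = np.nonzero(np.triu(strong.adj, 1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return g


def edge_connectivity(strong: StrongTieNetwork, i: str, j: str) -> int:
    """λ(i, j): number of edge-disjoint paths between organizations
    ``i`` and ``j`` (0 if they lie in different components)."""
    if i == j:
        raise ValueError("edge connectivity requires two distinct nodes")
    pos = {org_id: k for k, org_id in enumerate(strong.nodes)}
    try:
        a, b = pos[i], pos[j]
    except KeyError as exc:
        raise KeyError(f"unknown node {exc.args[0]!r}") from None
    g = _to_graph(strong)
    return int(nx.connectivity.local_edge_connectivity(g, a, b))


def lambda_matrix(strong: StrongTieNetwork) -> np.ndarray:
    """All-pairs edge connectivity as a symmetric integer matrix.

    Computed per connected component via a Gomory–Hu tree with unit
    capacities; pairs in different components have λ = 0, the diagonal
    is 0 by convention.
    """
    g = _to_graph(strong)
    n = len(strong)
    lam = np.zeros((n, n), dtype=int)
    for comp in nx.connected_components(g):
        comp = sorted(comp)
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp).copy()
        nx.set_edge_attributes(sub, 1, "capacity")
        tree = nx.gomory_hu_tree(sub)
        # min edge weight along every tree path, by DFS from each source
        adj = {u: list(tree[u].items()) for u in tree}
        for src in comp:
            stack = [(src, np.iinfo(np.int64).max)]
            seen = {src}
            while stack:
                u, mn = stack.pop()
                for v, data in adj[u]:
                    if v in seen:
                        continue
                    seen.add(v)
                    m = min(mn, data["weight"])
                    lam[src, v] = lam[v, src] = int(m)
                    stack.append((v, m))
    return lam


def _threshold_sets(lam: np.ndarray, level: int) -> list[list[int]]:
    """Maximal node groups with all internal λ >= level (components of
    the thresholded λ relation), size >= 2, ordered by smallest member."""
    g = nx.Graph()
    g.add_nodes_from(range(lam.shape[0]))
    ii, jj = np.nonzero(np.triu(lam >= level, 1))
    g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    comps = [sorted(c) for c in nx.connected_components(g) if len(c) >= 2]
    return sorted(comps, key=lambda c: c[0])


def lambda_analysis(strong: StrongTieNetwork) -> LambdaResult:
    """Full lambda-set analysis of a strong-tie network.

    Builds the λ-matrix, the lambda-set hierarchy (thresholding at each
    distinct positive λ from high to low), and the critical edges: the
    network edges internal to the top lambda set. If several sets share
    the top level, the one containing the earliest node in roster order
    is ranked first and supplies the critical edges.

    Raises ``ValueError`` on an edgeless network — there are no
    relations to rank.
    """
    if strong.adj.sum() == 0:
        raise ValueError("lambda analysis: network has no relations to rank")
    lam = lambda_matrix(strong)
    levels = sorted({int(v) for v in np.unique(lam) if v > 0}, reverse=True)
    hierarchy: list[tuple[int, list[list[str]]]] = []
    for level in levels:
        sets = _threshold_sets(lam, level)
        hierarchy.append((level, [[strong.nodes[i] for i in c] for c in sets]))
    lambda_max = levels[0]
    top = _threshold_sets(lam, lambda_max)[0]
    members = set(top)
    critical = [
        (strong.nodes[i], strong.nodes[j])
        for i in top
        for j in top
        if i < j and strong.adj[i, j] and j in members
    ]
    return LambdaResult(
        nodes=list(strong.nodes),
        lambda_matrix=lam,
        hierarchy=hierarchy,
        critical_edges=critical,
        lambda_max=lambda_max,
    )
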