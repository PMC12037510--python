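"""Metabolic covariance networks: construction, sparsity thresholding,
percolation (minimal fully-connected sparsity), and modularity.

A group's network has one node per analysis region; the edge weight between
two regions is the Pearson correlation of their SUVRs across the group's
subjects. The weighted network is binarized by *sparsity* S — the fraction
of retained edges among all n(n-1)/2 pairs — keeping the top-ranked edges
by signed correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .datatypes import GroupNetwork, SUVRTable

__all__ = [
    "build_group_network",
    "threshold_by_sparsity",
    "min_connected_sparsity",
    "make_group_network",
    "ModularityResult",
    "modularity_partition",
    "modularity_score",
]


def build_group_network(table: SUVRTable) -> np.ndarray:
    """Across-subject Pearson correlation matrix between regions.

    Requires >= 4 subjects and nonzero variance in every region. The
    diagonal (self-correlation) is zeroed: it is not an edge.
    """
    if table.n_subjects < 4:
        raise ValueError(f"need >= 4 subjects to build a network, got {table.n_subjects}")
    sd = table.values.std(axis=0)
    flat = np.nonzero(sd == 0)[0]
    if flat.size:
        names = [table.atlas.analysis_names[j] for j in flat[:5]]
        raise ValueError(f"zero-variance region(s): {names}")
    w = np.corrcoef(table.values, rowvar=False)
    np.fill_diagonal(w, 0.0)
    return w


def _ranked_edges(weights: np.ndarray, ranking: str = "signed") -> list[tuple[int, int]]:
    # descending weight; ties broken by (i, j) lexicographic order
    n = weights.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    key = weights[iu, ju] if ranking == "signed" else np.abs(weights[iu, ju])
    order = sorted(range(iu.size), key=lambda e: (-key[e], iu[e], ju[e]))
    return [(int(iu[e]), int(ju[e])) for e in order]


def threshold_by_sparsity(
    weights: np.ndarray, sparsity: float, ranking: str = "signed"
) -> np.ndarray:
    """Binarize a weight matrix keeping the top ``round(S * n(n-1)/2)`` edges.

    ``ranking="signed"`` (default) ranks by the correlation itself, keeping
    the strongest positive couplings; ``ranking="abs"`` ranks by magnitude.
    Rounding of the edge count is half-up.
    """
    n = weights.shape[0]
    if weights.shape != (n, n):
        raise ValueError("weights must be square")
    if not 0 < sparsity <= 1:
        raise ValueError(f"sparsity must lie in (0, 1], got {sparsity}")
    n_pairs = n * (n - 1) // 2
    m = int(math.floor(sparsity * n_pairs + 0.5))
    if m == 0:
        raise ValueError(f"sparsity {sparsity} yields an empty network (n={n})")
    adj = np.zeros((n, n), dtype=int)
    for i, j in _ranked_edges(weights, ranking)[:m]:
        adj[i, j] = adj[j, i] = 1
    return adj


class _UnionFind:
    """Array union-find with path compression, for incremental percolation."""

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.n_components = n

    def find(self, i: int) -> int:
        root = i
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[i] != root:
            self.parent[i], i = root, self.parent[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri
            self.n_components -= 1


def min_connected_sparsity(weights: np.ndarray, ranking: str = "signed") -> float:
    """Smallest sparsity whose thresholded network spans all nodes.

    Adds edges in ranked order into a union-find structure and returns
    ``S* = k* / (n(n-1)/2)`` for the first edge count ``k*`` at which a
    single connected component covers every node (a percolation
    threshold). Lower-bounded by the spanning-tree sparsity 2/n.
    """
    n = weights.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    uf = _UnionFind(n)
    n_pairs = n * (n - 1) // 2
    for k, (i, j) in enumerate(_ranked_edges(weights, ranking), start=1):
        uf.union(i, j)
        if uf.n_components == 1:
            return k / n_pairs
    raise AssertionError("complete edge ranking must connect the graph")


def make_group_network(
    table: SUVRTable, sparsity: float | str = "auto_min_connected", ranking: str = "signed"
) -> GroupNetwork:
    """Build weights and adjacency for one group in a single call.

    ``sparsity`` may be a number in (0, 1] or ``"auto_min_connected"`` to
    use the group's percolation threshold.
    """
    w = build_group_network(table)
    s = min_connected_sparsity(w, ranking) if sparsity == "auto_min_connected" else float(sparsity)
    adj = threshold_by_sparsity(w, s, ranking)
    return GroupNetwork(table.atlas, w, adj, s, table.n_subjects)


@dataclass
class ModularityResult:
    partition: dict[int, int]  # node index -> module id
    Q: float
    seed: int

    @property
    def n_modules(self) -> int:
        return len(set(self.partition.values()))


def modularity_score(adjacency: np.ndarray, partition: dict[int, int]) -> float:
    """Newman-Girvan modularity Q = sum_c (e_c/m - (d_c/2m)^2)."""
    a = np.asarray(adjacency)
    n = a.shape[0]
    m = a.sum() / 2
    if m == 0:
        raise ValueError("modularity undefined for an edgeless graph")
    degrees = a.sum(axis=1)
    modules = sorted(set(partition.values()))
    q = 0.0
    for c in modules:
        nodes = [v for v in range(n) if partition[v] == c]
        e_c = a[np.ix_(nodes, nodes)].sum() / 2
        d_c = degrees[nodes].sum()
        q += e_c / m - (d_c / (2 * m)) ** 2
    return float(q)


def modularity_partition(adjacency: np.ndarray, seed: int = 0) -> ModularityResult:
    """Louvain modularity-maximizing partition of a binary network.

    Deterministic given the seed. Every node (including isolates) is
    assigned exactly one module; Q is recomputed from the definitional
    formula on the returned partition.
    """
    a = np.asarray(adjacency)
    if a.sum() == 0:
        raise ValueError("cannot partition an edgeless graph")
    g = nx.from_numpy_array(a)
    communities = nx.community.louvain_communities(g, seed=seed)
    partition = {int(v): c for c, nodes in enumerate(communities) for v in nodes}
    return ModularityResult(partition=partition, Q=modularity_score(a, partition), seed=seed)
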