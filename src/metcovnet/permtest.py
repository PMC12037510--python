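"""Permutation inference on group differences in edge-wise connectivity.

The observed statistic for edge (i, j) is the difference in across-subject
Pearson correlation between the two groups (optionally on the Fisher-z
scale). The null distribution is built by re-assigning the pooled subjects
into two groups of the original sizes and recomputing the statistic; the
two-tailed empirical p-value uses the add-one convention
``p = (1 + #{|T_perm| >= |T_obs|}) / (B + 1)``, so p is never below
``1/(B+1)``.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .covnet import make_group_network
from .datatypes import GroupNetwork, PermutationResult, SUVRTable

__all__ = ["permutation_edge_test", "significant_edges", "compare_at_sparsity"]

log = logging.getLogger(__name__)


def _edge_stat(values: np.ndarray, mode: str) -> np.ndarray:
    """Correlation matrix (zero diagonal); zero-variance columns yield 0 rows."""
    sd = values.std(axis=0)
    flat = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(values, rowvar=False)
    if flat.any():
        r[flat, :] = 0.0
        r[:, flat] = 0.0
    r = np.nan_to_num(r, nan=0.0)
    r = 0.5 * (r + r.T)  # exact symmetry, so tie comparisons cannot split
    if mode == "fisher_z":
        r = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    np.fill_diagonal(r, 0.0)
    return r


def permutation_edge_test(
    table_a: SUVRTable,
    table_b: SUVRTable,
    n_perm: int = 5000,
    seed: int = 0,
    statistic_mode: str = "raw_r",
) -> PermutationResult:
    """Edge-wise two-group permutation test (A minus B).

    Permutations are group-size-preserving label shuffles sampled with
    replacement from the permutation space. A zero-variance region in a
    permuted split contributes T = 0 for its edges in that permutation
    (counted, with a warning).
    """
    if table_a.atlas.analysis_ids != table_b.atlas.analysis_ids:
        raise ValueError("tables use different atlases")
    if statistic_mode not in ("raw_r", "fisher_z"):
        raise ValueError(f"unknown statistic_mode {statistic_mode!r}")
    na, nb = table_a.n_subjects, table_b.n_subjects
    if na < 4 or nb < 4:
        raise ValueError(f"each group needs >= 4 subjects (got {na} and {nb})")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    # canonical subject order: permutation draws depend on the pooled set,
    # not on which group was passed first (so A-vs-B and B-vs-A agree)
    pooled = np.vstack([table_a.values, table_b.values])
    order = np.argsort(np.asarray(table_a.subject_ids + table_b.subject_ids))
    pooled = pooled[order]
    t_obs = _edge_stat(table_a.values, statistic_mode) - _edge_stat(
        table_b.values, statistic_mode
    )
    abs_obs = np.abs(t_obs)

    rng = np.random.default_rng(seed)
    count = np.ones_like(t_obs)
    warned = False
    for _ in range(n_perm):
        perm = rng.permutation(na + nb)
        va = pooled[perm[:na]]
        vb = pooled[perm[na:]]
        if not warned and (np.any(va.std(axis=0) == 0) or np.any(vb.std(axis=0) == 0)):
            log.warning("zero-variance region in a permuted split; its edges count as T = 0")
            warned = True
        t_perm = _edge_stat(va, statistic_mode) - _edge_stat(vb, statistic_mode)
        # ties count as exceedances; the tolerance keeps algebraically equal
        # statistics (e.g. mirror splits) from escaping on rounding noise
        count += np.abs(t_perm) >= abs_obs - 1e-12
    pvalues = count / (n_perm + 1)
    np.fill_diagonal(pvalues, 1.0)
    return PermutationResult(
        delta=t_obs, pvalues=pvalues, n_perm=n_perm, seed=seed, statistic_mode=statistic_mode
    )


def significant_edges(result: PermutationResult, alpha: float = 0.05) -> list[tuple]:
    """Edges with p < alpha, as (i, j, delta, p), sorted by |delta| descending.

    Positive delta marks a strengthened connection in group A (disease),
    negative a weakened one.
    """
    if not 0 < alpha < 1 and alpha != 1:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    n = result.delta.shape[0]
    mask = result.edge_mask if result.edge_mask is not None else np.ones((n, n), bool)
    edges = [
        (i, j, float(result.delta[i, j]), float(result.pvalues[i, j]))
        for i in range(n)
        for j in range(i + 1, n)
        if mask[i, j] and result.pvalues[i, j] < alpha
    ]
    return sorted(edges, key=lambda e: -abs(e[2]))


def compare_at_sparsity(
    table_a: SUVRTable,
    table_b: SUVRTable,
    sparsity: float,
    n_perm: int = 5000,
    seed: int = 0,
    statistic_mode: str = "raw_r",
) -> tuple[tuple[GroupNetwork, GroupNetwork], PermutationResult]:
    """Group networks at a common sparsity plus a restricted permutation test.

    Builds both groups' binarized networks at ``sparsity``, then runs the
    edge-wise permutation test restricted to the union of the two edge
    sets (edges outside the union are reported with delta = 0, p = 1).
    Warns when the requested sparsity is below a group's minimal
    fully-connected sparsity.
    """
    from .covnet import min_connected_sparsity

    net_a = make_group_network(table_a, sparsity)
    net_b = make_group_network(table_b, sparsity)
    for label, net in (("A", net_a), ("B", net_b)):
        s_min = min_connected_sparsity(net.weights)
        if sparsity < s_min:
            warnings.warn(
                f"group {label}: sparsity {sparsity:.4f} is below the minimal "
                f"fully-connected sparsity {s_min:.4f}; network is fragmented",
                stacklevel=2,
            )
    union = (net_a.adjacency | net_b.adjacency).astype(bool)
    result = permutation_edge_test(table_a, table_b, n_perm, seed, statistic_mode)
    delta = np.where(union, result.delta, 0.0)
    pvalues = np.where(union, result.pvalues, 1.0)
    restricted = PermutationResult(
        delta=delta,
        pvalues=pvalues,
        n_perm=n_perm,
        seed=seed,
        statistic_mode=statistic_mode,
        edge_mask=union,
    )
    return (net_a, net_b), restricted
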