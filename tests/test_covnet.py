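"""Covariance network construction, thresholding, percolation, modularity."""

import networkx as nx
import numpy as np
import pytest

import metcovnet as mc
from metcovnet.covnet import modularity_score


def _table(values, n_ref=1):
    n, p = values.shape
    return mc.SUVRTable(
        [f"s{i}" for i in range(n)], mc.synthetic_atlas(p, n_reference=n_ref), values
    )


class TestBuildGroupNetwork:
    def test_identical_columns_weight_one(self, rng):
        col = rng.uniform(1, 2, 10)
        values = np.column_stack([col, col, rng.uniform(1, 2, 10)])
        w = mc.build_group_network(_table(values))
        assert w[0, 1] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        values = rng.uniform(0.5, 2.0, (2000, 6))
        w = mc.build_group_network(_table(values))
        off = w[~np.eye(6, dtype=bool)]
        assert np.max(np.abs(off)) < 0.07

    def test_matches_textbook_pearson_oracle(self, rng):
        values = rng.uniform(0.5, 2.0, (6, 4))
        w = mc.build_group_network(_table(values))
        for i in range(4):
            for j in range(i + 1, 4):
                x, y = values[:, i], values[:, j]
                num = np.sum((x - x.mean()) * (y - y.mean()))
                den = np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
                assert w[i, j] == pytest.approx(num / den, abs=1e-12)

    def test_affine_rescaling_invariance(self, rng):
        values = rng.uniform(0.5, 2.0, (20, 5))
        w1 = mc.build_group_network(_table(values))
        w2 = mc.build_group_network(_table(values * np.arange(1, 6) + 0.3))
        assert np.allclose(w1, w2, atol=1e-12)

    def test_zero_variance_region_named(self, rng):
        values = rng.uniform(0.5, 2.0, (10, 3))
        values[:, 1] = 1.0
        with pytest.raises(ValueError, match="region_002"):
            mc.build_group_network(_table(values))

    def test_too_few_subjects(self, rng):
        with pytest.raises(ValueError, match=">= 4"):
            mc.build_group_network(_table(rng.uniform(1, 2, (3, 4))))


class TestThresholdBySparsity:
    def test_edge_count_at_paper_sparsity(self, rng):
        w = rng.normal(size=(90, 90))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        adj = mc.threshold_by_sparsity(w, 0.35)
        assert adj.sum() // 2 == 1402  # round(0.35 * 4005)

    def test_full_sparsity_complete_graph(self, rng):
        w = rng.normal(size=(10, 10))
        w = (w + w.T) / 2
        adj = mc.threshold_by_sparsity(w, 1.0)
        assert adj.sum() // 2 == 45

    def test_smallest_sparsity_keeps_argmax_edge(self):
        w = np.zeros((6, 6))
        w[2, 4] = w[4, 2] = 0.9
        w[0, 1] = w[1, 0] = 0.5
        adj = mc.threshold_by_sparsity(w, 1 / 15)
        assert adj.sum() == 2 and adj[2, 4] == 1

    def test_monotone_nesting(self, rng):
        w = rng.normal(size=(15, 15))
        w = (w + w.T) / 2
        prev = None
        for s in (0.1, 0.3, 0.6, 1.0):
            adj = mc.threshold_by_sparsity(w, s)
            if prev is not None:
                assert np.all(adj >= prev)  # edge sets nest under the fixed tie-break
            prev = adj

    def test_empty_network_rejected(self, rng):
        w = rng.normal(size=(6, 6))
        w = (w + w.T) / 2
        with pytest.raises(ValueError, match="empty"):
            mc.threshold_by_sparsity(w, 1e-6)


class TestMinConnectedSparsity:
    def test_chain_preference_gives_tree_bound(self):
        n = 12
        w = np.zeros((n, n))
        for i in range(n - 1):  # chain edges dominate everything else
            w[i, i + 1] = w[i + 1, i] = 1.0 - 0.01 * i
        s = mc.min_connected_sparsity(w)
        assert s == pytest.approx(2 / n)

    def test_spanning_tree_lower_bound_n90(self, rng):
        w = rng.normal(size=(90, 90))
        w = (w + w.T) / 2
        assert mc.min_connected_sparsity(w) >= 89 / 4005

    @pytest.mark.parametrize("seed", range(10))
    def test_connected_at_threshold_disconnected_below(self, seed):
        # BFS oracle via networkx on random 20-node matrices
        rng = np.random.default_rng(seed)
        w = rng.normal(size=(20, 20))
        w = (w + w.T) / 2
        np.fill_diagonal(w, 0)
        s = mc.min_connected_sparsity(w)
        n_pairs = 190
        k_star = round(s * n_pairs)
        adj = mc.threshold_by_sparsity(w, s)
        assert adj.sum() // 2 == k_star
        assert nx.is_connected(nx.from_numpy_array(adj))
        if k_star > 1:
            adj_minus = mc.threshold_by_sparsity(w, (k_star - 1) / n_pairs)
            g = nx.from_numpy_array(adj_minus)
            assert not nx.is_connected(g)


class TestModularity:
    @staticmethod
    def _two_cliques(k=8):
        adj = np.zeros((2 * k, 2 * k), dtype=int)
        adj[:k, :k] = 1
        adj[k:, k:] = 1
        np.fill_diagonal(adj, 0)
        return adj

    def test_two_disconnected_cliques(self):
        adj = self._two_cliques()
        res = mc.modularity_partition(adj, seed=0)
        assert res.Q == pytest.approx(0.5)
        labels = [res.partition[i] for i in range(16)]
        assert len(set(labels[:8])) == 1 and len(set(labels[8:])) == 1
        assert labels[0] != labels[8]

    def test_complete_graph_single_module(self):
        adj = np.ones((10, 10), dtype=int)
        np.fill_diagonal(adj, 0)
        res = mc.modularity_partition(adj, seed=0)
        assert res.n_modules == 1
        assert res.Q == pytest.approx(0.0, abs=1e-12)

    def test_q_matches_double_loop_oracle(self, rng):
        for trial in range(5):
            n = int(rng.integers(8, 30))
            adj = (rng.random((n, n)) < 0.25).astype(int)
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            if adj.sum() == 0:
                continue
            partition = {i: int(rng.integers(0, 3)) for i in range(n)}
            m = adj.sum() / 2
            q_oracle = 0.0
            for i in range(n):
                for j in range(n):
                    if partition[i] == partition[j]:
                        ki, kj = adj[i].sum(), adj[j].sum()
                        q_oracle += (adj[i, j] - ki * kj / (2 * m)) / (2 * m)
            assert modularity_score(adj, partition) == pytest.approx(q_oracle, abs=1e-12)

    def test_deterministic_given_seed(self, rng):
        adj = (rng.random((25, 25)) < 0.2).astype(int)
        adj = np.triu(adj, 1)
        adj = adj + adj.T
        r1 = mc.modularity_partition(adj, seed=3)
        r2 = mc.modularity_partition(adj, seed=3)
        assert r1.partition == r2.partition and r1.Q == r2.Q

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError, match="edgeless"):
            mc.modularity_partition(np.zeros((5, 5), dtype=int))


def test_make_group_network_auto_sparsity(rng):
    values = rng.multivariate_normal(np.zeros(8), np.eye(8) * 0.01 + 0.005, size=60) + 1.2
    net = mc.make_group_network(_table(values), "auto_min_connected")
    assert nx.is_connected(nx.from_numpy_array(net.adjacency))
    assert net.sparsity == pytest.approx(mc.min_connected_sparsity(net.weights))
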