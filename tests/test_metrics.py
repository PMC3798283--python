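"""Weighted graph metrics against brute-force and closed-form oracles."""

import numpy as np
import pytest

from brainstates.thresholding import BrainGraph
from brainstates.metrics import (
    char_path_length,
    clustering_onnela,
    global_efficiency,
    local_efficiency,
    modularity_value,
    modularity_weighted,
    nodal_strength,
    shortest_functional_paths,
)
from tests.conftest import random_weighted_graph


def graph_from(w):
    w = np.asarray(w, float)
    n = len(w)
    dens = np.count_nonzero(np.triu(w, 1)) / (n * (n - 1) / 2)
    return BrainGraph(w, density=dens)


def floyd_warshall_oracle(w):
    """All-pairs shortest paths on lengths 1/w by dynamic programming."""
    n = len(w)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and w[i, j] > 0:
                d[i, j] = 1.0 / w[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def clustering_oracle(w):
    """Exhaustive triple enumeration of the Onnela coefficient."""
    n = len(w)
    wh = w / w.max()
    c = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if wh[i, j] > 0]
        k = len(nb)
        if k < 2:
            continue
        total = 0.0
        for a in range(len(nb)):
            for b in range(a + 1, len(nb)):
                j, h = nb[a], nb[b]
                if wh[j, h] > 0:
                    total += (wh[i, j] * wh[i, h] * wh[j, h]) ** (1 / 3)
        c[i] = 2.0 * total / (k * (k - 1))
    return c


def local_efficiency_oracle(w):
    """Brute-force neighbor-subgraph efficiency."""
    n = len(w)
    wh = w / w.max()
    out = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if wh[i, j] > 0]
        k = len(nb)
        if k < 2:
            continue
        sub = wh[np.ix_(nb, nb)]
        d = floyd_warshall_oracle(sub)
        total = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and np.isfinite(d[a, b]) and d[a, b] > 0:
                    total += (wh[i, nb[a]] * wh[i, nb[b]] / d[a, b]) ** (1 / 3)
        out[i] = total / (k * (k - 1))
    return out


class TestPaths:
    def test_triangle_unit_weights(self):
        w = np.ones((3, 3)) - np.eye(3)
        d = shortest_functional_paths(graph_from(w))
        np.testing.assert_allclose(d, [[0, 1, 1], [1, 0, 1], [1, 1, 0]])

    def test_three_node_chain(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = w[1, 2] = w[2, 1] = 1.0
        g = graph_from(w)
        d = shortest_functional_paths(g)
        assert d[0, 2] == pytest.approx(2.0)
        length, frac = char_path_length(g, d)
        assert length == pytest.approx(4 / 3)
        assert frac == 0.0

    def test_matches_floyd_warshall_on_random_graphs(self, rng):
        for _ in range(25):
            g = random_weighted_graph(8, 0.4, rng)
            d = shortest_functional_paths(g)
            np.testing.assert_allclose(d, floyd_warshall_oracle(g.weights),
                                       rtol=1e-12)

    def test_halving_weights_doubles_length(self, rng):
        g = random_weighted_graph(10, 0.5, rng, connected_bias=True)
        l1, _ = char_path_length(g)
        l2, _ = char_path_length(graph_from(g.weights / 2))
        assert l2 == pytest.approx(2 * l1)

    def test_disconnection_reported_not_raised(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = w[2, 3] = w[3, 2] = 1.0  # two dyads
        length, frac = char_path_length(graph_from(w))
        assert length == pytest.approx(1.0)
        assert frac == pytest.approx(8 / 12)
        e = global_efficiency(graph_from(w))
        assert e == pytest.approx(4 / 12)  # cross-pairs contribute 0


class TestEfficiencyAndClustering:
    def test_complete_graph_unit_values(self):
        w = np.ones((5, 5)) - np.eye(5)
        g = graph_from(w)
        assert global_efficiency(g) == pytest.approx(1.0)
        ci, cmean = clustering_onnela(g)
        np.testing.assert_allclose(ci, 1.0)
        el = local_efficiency(g)
        np.testing.assert_allclose(el, 1.0)

    def test_star_graph_zero_clustering(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 0.7
        ci, cmean = clustering_onnela(graph_from(w))
        np.testing.assert_allclose(ci, 0.0)
        assert cmean == 0.0

    def test_single_neighbor_zero_local_efficiency(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.4
        el = local_efficiency(graph_from(w))
        assert el[0] == 0.0 and el[2] == 0.0

    @pytest.mark.parametrize("trial", range(10))
    def test_random_graphs_match_bruteforce(self, rng, trial):
        g = random_weighted_graph(8, 0.5, rng)
        assert global_efficiency(g) == pytest.approx(
            _efficiency_oracle(g.weights), rel=1e-12)
        ci, _ = clustering_onnela(g)
        np.testing.assert_allclose(ci, clustering_oracle(g.weights), rtol=1e-10)
        np.testing.assert_allclose(local_efficiency(g),
                                   local_efficiency_oracle(g.weights), rtol=1e-10)

    def test_scale_invariance_of_c_and_e_ratio_metrics(self, rng):
        g = random_weighted_graph(12, 0.4, rng)
        ci1, _ = clustering_onnela(g)
        ci2, _ = clustering_onnela(graph_from(g.weights * 7.3))
        np.testing.assert_allclose(ci1, ci2, rtol=1e-12)
        el1 = local_efficiency(g)
        el2 = local_efficiency(graph_from(g.weights * 7.3))
        np.testing.assert_allclose(el1, el2, rtol=1e-12)


def _efficiency_oracle(w):
    d = floyd_warshall_oracle(w)
    n = len(w)
    total = sum(1.0 / d[i, j] for i in range(n) for j in range(n)
                if i != j and np.isfinite(d[i, j]))
    return total / (n * (n - 1))


class TestStrength:
    def test_hand_example(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[0, 2] = w[2, 0] = 0.3
        s = nodal_strength(graph_from(w))
        assert s[0] == pytest.approx(0.8)
        assert s[1] == pytest.approx(0.5)

    def test_conservation(self, rng):
        g = random_weighted_graph(15, 0.3, rng)
        s = nodal_strength(g)
        assert s.sum() == pytest.approx(g.weights.sum())


class TestModularity:
    @staticmethod
    def two_cliques(k=5, weight=1.0):
        n = 2 * k
        w = np.zeros((n, n))
        w[:k, :k] = weight
        w[k:, k:] = weight
        np.fill_diagonal(w, 0.0)
        return graph_from(w)

    def test_two_cliques_closed_form(self):
        g = self.two_cliques()
        res = modularity_weighted(g, n_restarts=10, seed=0)
        assert res.mean_q == pytest.approx(0.5, abs=1e-12)
        assert res.mean_n_modules == pytest.approx(2.0)

    def test_single_clique_q_nonpositive(self):
        w = np.ones((6, 6)) - np.eye(6)
        res = modularity_weighted(graph_from(w), n_restarts=5, seed=1)
        assert res.best_q <= 1e-12
        assert res.mean_n_modules == pytest.approx(1.0)

    def test_same_seed_reproduces_mean_q(self, rng):
        g = random_weighted_graph(20, 0.25, rng, connected_bias=True)
        r1 = modularity_weighted(g, n_restarts=8, seed=42)
        r2 = modularity_weighted(g, n_restarts=8, seed=42)
        assert r1.mean_q == r2.mean_q
        assert r1.mean_n_modules == r2.mean_n_modules

    def test_modularity_value_matches_definition(self, rng):
        g = random_weighted_graph(10, 0.4, rng)
        labels = rng.integers(0, 3, size=10)
        w = g.weights
        s = w.sum(axis=1)
        l = s.sum()
        q = sum((w[i, j] - s[i] * s[j] / l) / l
                for i in range(10) for j in range(10)
                if labels[i] == labels[j])
        assert modularity_value(w, labels) == pytest.approx(q, abs=1e-12)

    def test_fine_tuning_never_decreases_q(self, rng):
        from brainstates.metrics import _fine_tune

        for _ in range(5):
            g = random_weighted_graph(15, 0.3, rng, connected_bias=True)
            labels = rng.integers(0, 4, size=15)
            q0 = modularity_value(g.weights, labels)
            q1 = modularity_value(g.weights, _fine_tune(g.weights, labels))
            assert q1 >= q0 - 1e-12


def test_binary_graph_weighted_metrics_equal_binary_oracles(rng):
    """With all weights equal, weighted metrics reduce to binary ones."""
    import networkx as nx

    g = random_weighted_graph(12, 0.4, rng, connected_bias=True)
    w = (g.weights > 0).astype(float)
    gb = graph_from(w)
    nxg = nx.from_numpy_array(w)
    # binary clustering
    ci, _ = clustering_onnela(gb)
    nx_c = nx.clustering(nxg)
    np.testing.assert_allclose(ci, [nx_c[i] for i in range(12)], rtol=1e-10)
    # path length equals hop count
    d = shortest_functional_paths(gb)
    nx_d = dict(nx.all_pairs_shortest_path_length(nxg))
    for i in range(12):
        for j in range(12):
            if j in nx_d[i]:
                assert d[i, j] == pytest.approx(nx_d[i][j])
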