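"""Weighted metrics: clustering coefficients, paths, betweenness, nulls."""

import numpy as np
import pytest
from scipy.sparse.csgraph import floyd_warshall

from hierconn.metrics import (
    average_path_length,
    betweenness,
    gzh_clustering,
    onnela_clustering,
    shortest_paths,
    shuffle_null,
    small_world_index,
    weight_to_distance,
)

from conftest import random_weighted_matrix


def triangle(w12, w13, w23):
    return np.array([[0, w12, w13], [w12, 0, w23], [w13, w23, 0.0]])


def onnela_oracle(w):
    wh = w / w.max()
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if wh[i, j] > 0]
        k = len(nb)
        if k < 2:
            continue
        s = 0.0
        for a in range(k):
            for b in range(a + 1, k):
                j, h = nb[a], nb[b]
                s += (wh[i, j] * wh[i, h] * wh[j, h]) ** (1.0 / 3.0)
        out[i] = 2.0 * s / (k * (k - 1))
    return out


def gzh_oracle(w):
    wh = w / w.max()
    n = w.shape[0]
    out = np.zeros(n)
    for i in range(n):
        num = 0.0
        for j in range(n):
            for h in range(n):
                if j != h:
                    num += wh[i, j] * wh[j, h] * wh[h, i]
        row = wh[i].sum()
        denom = row**2 - (wh[i] ** 2).sum()
        out[i] = num / denom if denom > 0 else 0.0
    return out


class TestClusteringCoefficients:
    def test_equal_weight_triangle_is_one_for_both(self):
        w = triangle(2, 2, 2)
        assert onnela_clustering(w) == pytest.approx([1, 1, 1])
        assert gzh_clustering(w) == pytest.approx([1, 1, 1])

    def test_onnela_single_triangle_hand_value(self):
        # normalized weights (0.25, 0.5, 1): every node gets (1/8)^(1/3) = 0.5
        w = triangle(1, 2, 4)
        assert onnela_clustering(w) == pytest.approx([0.5, 0.5, 0.5])

    def test_no_triangles_gives_zero(self):
        path = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0.0]])
        assert (onnela_clustering(path) == 0).all()
        star = np.zeros((5, 5))
        star[0, 1:] = star[1:, 0] = 1.0
        assert (gzh_clustering(star) == 0).all()

    def test_gzh_reduces_to_binary_clustering_on_01_graphs(self, rng):
        import networkx as nx

        for _ in range(5):
            a = (random_weighted_matrix(10, rng, density=0.5) > 0).astype(float)
            a = np.triu(a, 1)
            a = a + a.T
            if a.max() == 0:
                continue
            ours = gzh_clustering(a)
            binary = nx.clustering(nx.from_numpy_array(a))
            assert ours == pytest.approx([binary[i] for i in range(10)], abs=1e-12)

    @pytest.mark.parametrize("fn", [onnela_clustering, gzh_clustering])
    def test_invariant_under_global_rescaling_and_bounded(self, fn, rng):
        w = random_weighted_matrix(15, rng, density=0.6)
        a, b = fn(w), fn(w * 7.5)
        assert a == pytest.approx(b, abs=1e-12)
        assert (a >= 0).all() and (a <= 1).all()

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(5):
            w = random_weighted_matrix(12, rng, density=0.5)
            assert onnela_clustering(w) == pytest.approx(onnela_oracle(w), abs=1e-12)
            assert gzh_clustering(w) == pytest.approx(gzh_oracle(w), abs=1e-12)


class TestDistancesAndPaths:
    def test_reciprocal_transform(self):
        w = triangle(2, 0, 4)
        d = weight_to_distance(w)
        assert d[0, 1] == 0.5
        assert np.isinf(d[0, 2])
        assert d[2, 2] == 0

    def test_two_node_geodesic(self):
        d = weight_to_distance(np.array([[0, 2], [2, 0.0]]))
        assert shortest_paths(d)[0, 1] == 0.5

    def test_disconnected_pair_is_infinite(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        g = shortest_paths(weight_to_distance(w))
        assert np.isinf(g[0, 2])

    def test_doubling_weights_halves_geodesics(self, rng):
        w = random_weighted_matrix(10, rng, density=0.5)
        g1 = shortest_paths(weight_to_distance(w))
        g2 = shortest_paths(weight_to_distance(2 * w))
        finite = np.isfinite(g1)
        assert g2[finite] == pytest.approx(g1[finite] / 2, abs=1e-12)

    def test_johnson_matches_floyd_warshall_oracle(self, rng):
        for _ in range(20):
            w = random_weighted_matrix(20, rng, density=0.3)
            d = weight_to_distance(w)
            ours = shortest_paths(d)
            dd = d.copy()
            dd[np.isinf(dd)] = 0.0
            oracle = floyd_warshall(dd, directed=False)
            assert np.abs(ours - oracle)[np.isfinite(oracle)].max() <= 1e-12
            assert np.array_equal(np.isinf(ours), np.isinf(oracle))

    def test_average_path_length_examples(self):
        g = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0.0]])
        assert average_path_length(g) == (1.0, 0)
        g = np.full((3, 3), np.inf)
        np.fill_diagonal(g, 0)
        g[0, 1] = g[1, 0] = 2.0
        L, n_inf = average_path_length(g)
        assert L == 2.0 and n_inf == 2

    def test_adding_an_edge_never_increases_length(self, rng):
        for _ in range(10):
            w = random_weighted_matrix(10, rng, density=0.4)
            i, j = rng.choice(10, size=2, replace=False)
            w2 = w.copy()
            w2[i, j] = w2[j, i] = w.max() + 1.0
            g1 = shortest_paths(weight_to_distance(w))
            g2 = shortest_paths(weight_to_distance(w2))
            assert (g2 <= g1 + 1e-12).all()


class TestBetweenness:
    def test_path_graph_center(self):
        w = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0.0]])
        assert betweenness(w) == pytest.approx([0, 1, 0])

    def test_complete_equal_graph_is_zero(self):
        w = np.ones((6, 6))
        np.fill_diagonal(w, 0)
        assert betweenness(w) == pytest.approx(np.zeros(6), abs=1e-12)

    def test_matches_path_enumeration_oracle(self, rng):
        for _ in range(10):
            w = random_weighted_matrix(15, rng, density=0.3, scale=1.0)
            assert betweenness(w) == pytest.approx(
                _betweenness_enumeration_oracle(w), abs=1e-9)


def _betweenness_enumeration_oracle(w):
    """Count shortest paths explicitly by DFS over the geodesic structure."""
    d = weight_to_distance(w)
    dd = d.copy()
    dd[np.isinf(dd)] = 0.0
    sp = floyd_warshall(dd, directed=False)
    n = w.shape[0]
    credit = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if t <= s or not np.isfinite(sp[s, t]) or sp[s, t] == 0:
                continue
            paths = []

            def extend(node, length, trail):
                if node == t:
                    paths.append(trail)
                    return
                for v in range(n):
                    if v in trail or not np.isfinite(d[node, v]):
                        continue
                    new_len = length + d[node, v]
                    if abs(new_len + sp[v, t] - sp[s, t]) <= 1e-10:
                        extend(v, new_len, trail + [v])

            extend(s, 0.0, [s])
            for p in paths:
                for node in p[1:-1]:
                    credit[node] += 1.0 / len(paths)
    return credit / ((n - 1) * (n - 2) / 2.0)


class TestShuffleNull:
    def test_weight_multiset_preserved_exactly(self, rng):
        w = random_weighted_matrix(12, rng, density=0.5)
        null = shuffle_null(w, 5)
        iu = np.triu_indices(12, k=1)
        assert sorted(w[iu]) == sorted(null[iu])
        assert np.array_equal(null, null.T)
        assert np.diagonal(null).sum() == 0

    def test_constant_matrix_is_fixed_point(self):
        w = np.ones((8, 8))
        np.fill_diagonal(w, 0)
        assert np.array_equal(shuffle_null(w, 0), w)

    def test_seed_determinism(self, rng):
        w = random_weighted_matrix(10, rng)
        assert np.array_equal(shuffle_null(w, 42), shuffle_null(w, 42))

    def test_degree_variance_increases_for_planted_structure(self):
        from hierconn.synthetic import GeneratorConfig, generate_cohort

        wins = 0
        for seed in range(6):
            stack, _ = generate_cohort(GeneratorConfig(seed=seed))
            avg = stack.average()
            base = avg.sum(axis=1).var()
            null_var = np.mean([
                shuffle_null(avg, k).sum(axis=1).var() for k in range(3)])
            wins += null_var > base
        assert wins >= 4


class TestSmallWorldIndex:
    def test_constant_matrix_fixed_point_is_exactly_one(self):
        w = np.full((10, 10), 2.0)
        np.fill_diagonal(w, 0)
        rep = small_world_index(w, n_rand=3, seed=0)
        assert rep.gamma == 1.0 and rep.lambda_ == 1.0 and rep.sw_index == 1.0

    def test_index_is_gamma_over_lambda(self, rng):
        w = random_weighted_matrix(20, rng, density=0.5)
        rep = small_world_index(w, n_rand=10, seed=1, cc_formula="gzh")
        assert rep.sw_index == pytest.approx(rep.gamma / rep.lambda_, abs=1e-12)
        assert rep.n_rand == 10

    def test_insensitive_to_null_sample_size(self):
        from hierconn.synthetic import GeneratorConfig, generate_cohort

        stack, _ = generate_cohort(GeneratorConfig(seed=2))
        avg = stack.average()
        a = small_world_index(avg, n_rand=100, seed=0, cc_formula="gzh")
        b = small_world_index(avg, n_rand=300, seed=1, cc_formula="gzh")
        assert b.sw_index == pytest.approx(a.sw_index, rel=0.02)
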