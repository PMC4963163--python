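import itertools

import networkx as nx
import numpy as np
import pytest

import wconn
from wconn import Connectome
from wconn.metrics import (
    binary_geodesics,
    clustering_binary,
    clustering_onnela,
    clustering_zhang,
    cumulative_distribution,
    mean_geodesic,
    node_degree,
    node_strength,
    scale_weights,
    weighted_geodesics,
)

from conftest import random_connectome


def minhop_maxweight_oracle(c: Connectome):
    """Independent enumeration oracle: all min-hop paths, max weight sum."""
    g = nx.from_numpy_array(c.weights)
    n = c.n_nodes
    out = np.full((n, n), np.nan)
    np.fill_diagonal(out, 0.0)
    for i, j in itertools.combinations(range(n), 2):
        if not nx.has_path(g, i, j):
            continue
        best = max(
            sum(c.weights[a, b] for a, b in zip(path, path[1:]))
            for path in nx.all_shortest_paths(g, i, j)
        )
        out[i, j] = out[j, i] = best
    return out


class TestDegreeStrength:
    def test_path_graph_degrees(self, path_abc):
        assert node_degree(wconn.binarize(path_abc)).values.tolist() == [1, 2, 1]

    def test_complete_graph_degrees(self):
        w = np.ones((68, 68))
        np.fill_diagonal(w, 0)
        c = Connectome([f"n{i}" for i in range(68)], w)
        assert set(node_degree(wconn.binarize(c)).values) == {67.0}

    def test_degrees_equal_column_sums(self, rng):
        c = random_connectome(rng, n=20)
        g = wconn.binarize(c)
        np.testing.assert_array_equal(
            node_degree(g).values, g.adjacency.sum(axis=0).astype(float)
        )

    def test_single_edge_strength(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        s = node_strength(Connectome(list("abc"), w))
        assert s.values.tolist() == [0.5, 0.5, 0.0]

    def test_unit_weights_make_strength_equal_degree(self, rng):
        c = random_connectome(rng, n=15)
        c.weights = (c.weights > 0).astype(float)
        np.testing.assert_array_equal(
            node_strength(c).values, node_degree(wconn.binarize(c)).values
        )


class TestCumulativeDistribution:
    def test_three_distinct_values(self):
        v = wconn.NodeMetricVector("m", [1.0, 2.0, 3.0], list("abc"))
        cum = cumulative_distribution(v)
        assert cum["value"].tolist() == [1.0, 2.0, 3.0]
        assert cum["fraction"].tolist() == pytest.approx([1.0, 2 / 3, 1 / 3])

    def test_constant_vector_single_step(self):
        v = wconn.NodeMetricVector("m", [5.0] * 4, list("abcd"))
        cum = cumulative_distribution(v)
        assert len(cum) == 1 and cum["fraction"][0] == 1.0

    def test_fractions_non_increasing(self, rng):
        v = wconn.NodeMetricVector(
            "m", rng.uniform(size=30), [f"n{i}" for i in range(30)]
        )
        frac = cumulative_distribution(v)["fraction"].to_numpy()
        assert np.all(np.diff(frac) <= 0)


class TestBinaryGeodesics:
    def test_path_graph_distances(self, path_abc):
        p = binary_geodesics(wconn.binarize(path_abc))
        assert p.values[0, 2] == 2.0

    def test_complete_graph_all_one(self):
        w = np.ones((6, 6))
        np.fill_diagonal(w, 0)
        p = binary_geodesics(wconn.binarize(Connectome([f"n{i}" for i in range(6)], w)))
        off = p.values[~np.eye(6, dtype=bool)]
        assert set(off) == {1.0}

    def test_against_networkx_on_random_graphs(self, rng):
        for _ in range(20):
            c = random_connectome(rng, n=20, p=0.15)
            p = binary_geodesics(wconn.binarize(c))
            g = nx.from_numpy_array(c.weights > 0)
            expected = dict(nx.all_pairs_shortest_path_length(g))
            for i in range(20):
                for j in range(20):
                    if j in expected[i]:
                        assert p.values[i, j] == expected[i][j]
                    else:
                        assert np.isnan(p.values[i, j])


class TestWeightedGeodesics:
    def test_weak_direct_edge_beats_strong_detour(self, triangle):
        # min-hop has priority: the one-edge path wins despite lower weight
        p = weighted_geodesics(triangle)
        assert p.values[0, 1] == pytest.approx(0.1)

    def test_two_hop_max_weight_choice(self):
        # 1-2 (0.1), 2-4 (0.9), 1-3 (0.4), 3-4 (0.5): both 1-4 routes have
        # two hops; the 1-2-4 route is heavier (1.0 > 0.9)
        w = np.zeros((4, 4))
        for (i, j), v in {(0, 1): 0.1, (1, 3): 0.9, (0, 2): 0.4, (2, 3): 0.5}.items():
            w[i, j] = w[j, i] = v
        p = weighted_geodesics(Connectome([f"n{i}" for i in range(4)], w))
        assert p.values[0, 3] == pytest.approx(1.0)

    def test_uniform_weights_reduce_to_hop_counts(self, rng):
        c = random_connectome(rng, n=12, p=0.4)
        c.weights = (c.weights > 0).astype(float)
        pw = weighted_geodesics(c)
        pb = binary_geodesics(wconn.binarize(c))
        np.testing.assert_allclose(pw.values, pb.values, atol=1e-12)

    def test_matches_enumeration_oracle_exactly(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 9))
            c = random_connectome(rng, n=n, p=float(rng.uniform(0.2, 0.9)))
            got = weighted_geodesics(c).values
            expected = minhop_maxweight_oracle(c)
            np.testing.assert_array_equal(np.isnan(got), np.isnan(expected))
            np.testing.assert_allclose(got, expected, atol=1e-12, equal_nan=True)

    def test_symmetric_output(self, rng):
        c = random_connectome(rng, n=15, p=0.3)
        v = weighted_geodesics(c).values
        np.testing.assert_allclose(v, v.T, atol=1e-12, equal_nan=True)


class TestMeanGeodesic:
    def test_path_graph_endpoint(self, path_abc):
        p = binary_geodesics(wconn.binarize(path_abc))
        assert mean_geodesic(p, "A") == pytest.approx(1.5)

    def test_complete_graph_all_ones(self):
        w = np.ones((8, 8))
        np.fill_diagonal(w, 0)
        p = binary_geodesics(wconn.binarize(Connectome([f"n{i}" for i in range(8)], w)))
        assert set(mean_geodesic(p).values) == {1.0}

    def test_equals_row_mean(self, rng):
        c = random_connectome(rng, n=15, p=0.6)
        p = weighted_geodesics(c)
        vec = mean_geodesic(p)
        for i in range(15):
            row = np.delete(p.values[i], i)
            assert vec.values[i] == pytest.approx(row.mean())

    def test_disconnected_graph_raises(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        p = binary_geodesics(wconn.binarize(Connectome(list("abcd"), w)))
        with pytest.raises(ValueError, match="disconnected"):
            mean_geodesic(p)

    def test_threshold_never_shortens_binary_paths(self, rng):
        # removing edges can only lengthen hop counts while connected
        for _ in range(10):
            c = random_connectome(rng, n=15, p=0.7)
            p0 = mean_geodesic(binary_geodesics(wconn.binarize(c))).values
            ct = wconn.apply_count_threshold(c, 60)
            pt = binary_geodesics(wconn.binarize(ct))
            if not pt.is_connected():
                continue
            assert np.all(mean_geodesic(pt).values >= p0 - 1e-12)


class TestScaleWeights:
    def test_two_edge_example(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.02
        w[1, 2] = w[2, 1] = 0.01
        s = scale_weights(Connectome(list("abc"), w))
        assert s[0, 1] == 1.0 and s[1, 2] == 0.5

    def test_max_is_exactly_one(self, rng):
        c = random_connectome(rng, n=10)
        assert scale_weights(c).max() == 1.0

    def test_edgeless_network_is_an_error(self):
        with pytest.raises(ValueError, match="edgeless"):
            scale_weights(Connectome(list("ab"), np.zeros((2, 2))))


def triple_loop_clustering(c: Connectome, variant: str):
    """Brute-force ordered-pair sums straight from the definitions."""
    w_hat = c.weights / c.weights.max()
    a = (c.weights > 0).astype(float)
    n = c.n_nodes
    out = np.zeros(n)
    for i in range(n):
        k = a[i].sum()
        num = 0.0
        for j in range(n):
            for m in range(n):
                if variant == "binary":
                    num += a[i, j] * a[j, m] * a[m, i]
                elif variant == "onnela":
                    num += (w_hat[i, j] * w_hat[j, m] * w_hat[m, i]) ** (1 / 3)
                else:
                    num += w_hat[i, j] * w_hat[j, m] * w_hat[m, i]
        if variant in ("binary", "onnela"):
            out[i] = num / (k * (k - 1)) if k > 1 else 0.0
        else:
            denom = w_hat[i].sum() ** 2 - (w_hat[i] ** 2).sum()
            out[i] = num / denom if denom > 0 else 0.0
    return out


class TestClustering:
    def test_triangle_node_is_fully_clustered(self):
        w = np.ones((3, 3)) - np.eye(3)
        c = Connectome(list("abc"), w)
        assert clustering_binary(wconn.binarize(c), "a") == 1.0
        assert clustering_onnela(c, "a") == pytest.approx(1.0)
        assert clustering_zhang(c, "a") == pytest.approx(1.0)

    def test_star_center_has_zero_clustering(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 0.7
        c = Connectome([f"n{i}" for i in range(5)], w)
        assert clustering_binary(wconn.binarize(c), "n0") == 0.0
        assert clustering_onnela(c, "n0") == 0.0
        assert clustering_zhang(c, "n0") == 0.0

    def test_onnela_hand_value_on_weighted_triangle(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.5
        c = Connectome(["n1", "n2", "n3"], w)
        # two ordered neighbor pairs, each (1 * 0.5 * 0.5)^(1/3), over k(k-1)=2
        assert clustering_onnela(c, "n1") == pytest.approx(0.25 ** (1 / 3))

    def test_zhang_hand_value_on_weighted_triangle(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[0, 2] = w[2, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.5
        c = Connectome(["n1", "n2", "n3"], w)
        # numerator 2 * 0.25 = 0.5; denominator 1.5^2 - 1.25 = 1.0
        assert clustering_zhang(c, "n1") == pytest.approx(0.5)

    def test_isolated_node_convention_zero(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.4
        c = Connectome(list("abc"), w)
        assert clustering_zhang(c, "c") == 0.0
        assert clustering_binary(wconn.binarize(c), "c") == 0.0

    @pytest.mark.parametrize("variant", ["binary", "onnela", "zhang"])
    def test_matches_triple_loop_oracle(self, rng, variant):
        for _ in range(10):
            c = random_connectome(rng, n=15, p=0.4)
            if c.n_edges == 0:
                continue
            expected = triple_loop_clustering(c, variant)
            if variant == "binary":
                got = clustering_binary(wconn.binarize(c)).values
            elif variant == "onnela":
                got = clustering_onnela(c).values
            else:
                got = clustering_zhang(c).values
            np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_all_values_in_unit_interval(self, rng):
        for _ in range(5):
            c = random_connectome(rng, n=20, p=0.5)
            for vals in (
                clustering_binary(wconn.binarize(c)).values,
                clustering_onnela(c).values,
                clustering_zhang(c).values,
            ):
                assert np.all(vals >= 0) and np.all(vals <= 1 + 1e-12)

    def test_binary_limit_all_variants_agree(self, rng):
        c = random_connectome(rng, n=15, p=0.5)
        c.weights = (c.weights > 0) * 0.37  # equal positive weights
        cb = clustering_binary(wconn.binarize(c)).values
        np.testing.assert_allclose(clustering_onnela(c).values, cb, atol=1e-12)
        np.testing.assert_allclose(clustering_zhang(c).values, cb, atol=1e-12)

    def test_strength_stable_under_weak_edge_removal(self, rng):
        c = wconn.generate_connectome(wconn.SynthConfig(rng_seed=5))
        s0 = node_strength(c).values
        cutoff = 1e-6 * c.weights.max()
        ct = c.copy()
        ct.weights = np.where(ct.weights >= cutoff, ct.weights, 0.0)
        ct.counts = np.where(ct.weights > 0, ct.counts, 0)
        s1 = node_strength(ct).values
        assert np.all(np.abs(s1 - s0) <= 1e-4 * np.maximum(s0, 1e-30))
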