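import numpy as np
import pytest

from neonet.connectome import ThresholdedGraph
from neonet.graph_metrics import (
    characteristic_path_length,
    clustering_coefficients,
    compute_global_metrics,
    compute_nodal_metrics,
    global_efficiency,
    local_efficiency,
    node_strength,
    shortest_path_matrix,
)

from _oracles import (
    bf_characteristic_path_length,
    bf_clustering_binary,
    bf_clustering_weighted,
    bf_global_efficiency,
    bf_local_efficiency,
    bf_shortest_paths,
    bf_strength,
    random_graph,
)


def _triangle(w12=1.0, w13=1.0, w23=1.0):
    w = np.zeros((3, 3))
    w[0, 1] = w[1, 0] = w12
    w[0, 2] = w[2, 0] = w13
    w[1, 2] = w[2, 1] = w23
    return w


def _complete(n, weight=1.0):
    w = np.full((n, n), weight)
    np.fill_diagonal(w, 0.0)
    return w


class TestNodeStrength:
    def test_three_node_example(self):
        s = node_strength(_triangle(0.5, 0.3, 0.2))
        np.testing.assert_allclose(s, [0.8, 0.7, 0.5])

    def test_complete_unit_graph(self):
        for n in (3, 7, 12):
            np.testing.assert_allclose(node_strength(_complete(n)), n - 1)

    def test_empty_graph(self):
        np.testing.assert_array_equal(node_strength(np.zeros((5, 5))), 0.0)


class TestClustering:
    def test_triangle_fully_clustered_any_weights(self):
        c, mean = clustering_coefficients(_triangle(0.2, 0.9, 0.4))
        np.testing.assert_allclose(c, 1.0)
        assert mean == pytest.approx(1.0)

    def test_path_has_no_triangles(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.5
        w[1, 2] = w[2, 1] = 0.5
        c, mean = clustering_coefficients(w)
        np.testing.assert_array_equal(c, 0.0)
        assert mean == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_binary_matches_triple_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        w = random_graph(rng, n_max=7)
        c, _ = clustering_coefficients(w, mode="binary")
        np.testing.assert_allclose(c, bf_clustering_binary(w), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_weighted_matches_triple_enumeration(self, seed):
        rng = np.random.default_rng(100 + seed)
        w = random_graph(rng, n_max=7)
        c, _ = clustering_coefficients(w, mode="weighted")
        np.testing.assert_allclose(c, bf_clustering_weighted(w), atol=1e-12)


class TestShortestPaths:
    def test_single_edge_inverse_length(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 0.5
        assert shortest_path_matrix(w)[0, 1] == pytest.approx(2.0)

    def test_two_hop_beats_weak_direct_edge(self):
        # strong A-B-C detour (1/0.9 + 1/0.9 = 2.22) beats direct 1/0.4 = 2.5
        w = _triangle(0.9, 0.4, 0.9)
        d = shortest_path_matrix(w)
        assert d[0, 2] == pytest.approx(2 / 0.9)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_simple_path_enumeration(self, seed):
        rng = np.random.default_rng(200 + seed)
        w = random_graph(rng, n_max=7)
        np.testing.assert_allclose(
            shortest_path_matrix(w), bf_shortest_paths(w), atol=1e-10
        )

    def test_neglog_mapping(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = 0.5
        d = shortest_path_matrix(w, mapping="neglog")
        assert d[0, 1] == pytest.approx(-np.log(0.5))

    def test_negative_weight_rejected(self):
        w = np.zeros((2, 2))
        w[0, 1] = w[1, 0] = -0.5
        with pytest.raises(ValueError, match="negative"):
            shortest_path_matrix(w)


class TestCharacteristicPathLength:
    def test_complete_unit_graph(self):
        d, frac = characteristic_path_length(shortest_path_matrix(_complete(6)))
        assert d == pytest.approx(1.0)
        assert frac == 1.0

    def test_two_disjoint_edges(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 1.0
        w[2, 3] = w[3, 2] = 1.0
        d, frac = characteristic_path_length(shortest_path_matrix(w))
        assert d == pytest.approx(1.0)
        assert frac == pytest.approx(4 / 12)

    def test_three_node_unit_path(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 1.0
        w[1, 2] = w[2, 1] = 1.0
        d, _ = characteristic_path_length(shortest_path_matrix(w))
        assert d == pytest.approx(4 / 3)  # (1+1+2+2+1+1)/6

    def test_fully_disconnected_errors(self):
        with pytest.raises(ValueError, match="disconnected"):
            characteristic_path_length(shortest_path_matrix(np.zeros((4, 4))))


class TestGlobalEfficiency:
    def test_complete_unit_graph_is_one(self):
        assert global_efficiency(shortest_path_matrix(_complete(8))) == pytest.approx(1.0)

    def test_empty_graph_is_zero(self):
        assert global_efficiency(shortest_path_matrix(np.zeros((5, 5)))) == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        w = random_graph(rng, n_max=4)
        mine = global_efficiency(shortest_path_matrix(w))
        ref = bf_global_efficiency(bf_shortest_paths(w))
        assert mine == pytest.approx(ref, abs=1e-12)


class TestLocalEfficiency:
    def test_unit_triangle_all_ones(self):
        np.testing.assert_allclose(local_efficiency(_triangle()), 1.0)

    def test_star_graph_all_zero(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 0.8
        np.testing.assert_array_equal(local_efficiency(w), 0.0)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_composed_oracles(self, seed):
        rng = np.random.default_rng(400 + seed)
        w = random_graph(rng, n_max=7)
        np.testing.assert_allclose(
            local_efficiency(w), bf_local_efficiency(w), atol=1e-10
        )


class TestInvariants:
    @pytest.mark.parametrize("c", [0.5, 2.0])
    def test_scale_covariance(self, c):
        rng = np.random.default_rng(5)
        w = random_graph(rng, n_max=7)
        s0, s1 = node_strength(w), node_strength(c * w)
        np.testing.assert_allclose(s1, c * s0, atol=1e-12)
        d0, d1 = shortest_path_matrix(w), shortest_path_matrix(c * w)
        finite = np.isfinite(d0)
        np.testing.assert_allclose(d1[finite], d0[finite] / c, atol=1e-10)
        e0 = global_efficiency(d0)
        e1 = global_efficiency(d1)
        assert e1 == pytest.approx(c * e0, abs=1e-12)
        c0, _ = clustering_coefficients(w)
        c1, _ = clustering_coefficients(c * w)
        np.testing.assert_allclose(c0, c1)

    def test_adding_an_edge_never_hurts_integration(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            w = random_graph(rng, n_max=6)
            zeros = np.argwhere(np.triu(w == 0, k=1))
            if len(zeros) == 0:
                continue
            i, j = zeros[rng.integers(len(zeros))]
            w2 = w.copy()
            w2[i, j] = w2[j, i] = rng.uniform(0.1, 1.0)
            d_before = shortest_path_matrix(w)
            d_after = shortest_path_matrix(w2)
            assert (d_after <= d_before + 1e-12).all()
            assert global_efficiency(d_after) >= global_efficiency(d_before) - 1e-12

    def test_bounds_for_weights_in_unit_interval(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            w = random_graph(rng, n_max=7)
            d = shortest_path_matrix(w)
            off = d[~np.eye(d.shape[0], dtype=bool)]
            assert (off[np.isfinite(off)] >= 1 - 1e-12).all()
            assert 0.0 <= global_efficiency(d) <= 1.0

    def test_strength_matches_enumeration(self):
        rng = np.random.default_rng(8)
        w = random_graph(rng, n_max=7)
        np.testing.assert_allclose(node_strength(w), bf_strength(w), atol=1e-12)


def test_networkx_cross_check_weighted_paths():
    """Independent library route: Dijkstra on 1/w lengths via networkx."""
    nx = pytest.importorskip("networkx")
    rng = np.random.default_rng(9)
    w = random_graph(rng, n_max=7, p_edge=0.6)
    g = nx.Graph()
    n = w.shape[0]
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if w[i, j] > 0:
                g.add_edge(i, j, length=1.0 / w[i, j])
    mine = shortest_path_matrix(w)
    for i in range(n):
        lengths = nx.single_source_dijkstra_path_length(g, i, weight="length")
        for j in range(n):
            ref = lengths.get(j, np.inf)
            assert mine[i, j] == pytest.approx(ref, abs=1e-10)


def test_global_and_nodal_summaries_consistent():
    rng = np.random.default_rng(10)
    w = random_graph(rng, n_max=7)
    g = ThresholdedGraph(w, cost=0.3, labels=tuple(f"r{i}" for i in range(w.shape[0])),
                         session_id="s")
    gm = compute_global_metrics(g)
    nodal = compute_nodal_metrics(g)
    assert gm.strength == pytest.approx(nodal["strength"].mean())
    assert gm.clustering == pytest.approx(nodal["clustering"].mean())
    assert len(nodal) == w.shape[0]
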