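"""Thresholding and topology measures, with independent graph-library oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conncrit import (
    binarize,
    clustering_coefficient,
    compute_threshold,
    delta_clustering,
    largest_component_fraction,
)
from conncrit.errors import ParameterError

from conftest import make_matrix, make_network, random_symmetric


def ring_lattice_adjacency(n, k):
    a = np.zeros((n, n), dtype=np.int8)
    for off in range(1, k // 2 + 1):
        idx = np.arange(n)
        a[idx, (idx + off) % n] = 1
        a[(idx + off) % n, idx] = 1
    return a


def net_from_adjacency(adj):
    """ThresholdedNetwork with unit weights on the given adjacency."""
    return make_network(adj.astype(float) * 0.9, 0.5)


class TestComputeThreshold:
    @pytest.fixture
    def two_point_matrix(self):
        # six upper-triangle |w| values {0.1, 0.1, 0.1, 0.3, 0.3, 0.3}
        return make_matrix({(0, 1): 0.1, (0, 2): 0.1, (0, 3): 0.1,
                            (1, 2): 0.3, (1, 3): 0.3, (2, 3): -0.3})

    def test_n_zero_gives_the_mean(self, two_point_matrix):
        assert compute_threshold(two_point_matrix, 0.0).w_t == pytest.approx(0.2)

    def test_population_sd_multiplier(self, two_point_matrix):
        # population sd of a balanced two-point set {0.1, 0.3} is 0.1
        assert compute_threshold(two_point_matrix, 1.0).w_t == pytest.approx(0.3)

    def test_matches_independent_two_pass_computation(self, rng):
        m = make_matrix(random_symmetric(50, rng))
        spec = compute_threshold(m, 1.7)
        vals = np.abs(m.weights[np.triu_indices(50, 1)])
        mean = sum(vals) / len(vals)
        sd = (sum((v - mean) ** 2 for v in vals) / len(vals)) ** 0.5
        assert abs(spec.w_t - (mean + 1.7 * sd)) < 1e-12

    def test_degenerate_sd_warns(self, caplog):
        m = make_matrix({(0, 1): 0.25, (0, 2): 0.25, (1, 2): 0.25})
        with caplog.at_level("WARNING"):
            spec = compute_threshold(m, 2.0)
        assert spec.sd_abs_w == 0.0
        assert spec.w_t == pytest.approx(0.25)


class TestBinarize:
    def test_negative_weights_survive_by_magnitude(self):
        net = make_network({(0, 1): -0.5}, 0.4)
        assert net.adjacency[0, 1] == 1
        assert net.retained_weights[0, 1] == -0.5

    def test_tie_with_threshold_is_excluded(self):
        net = make_network({(0, 1): 0.4}, 0.4)
        assert net.adjacency[0, 1] == 0
        assert net.retained_weights[0, 1] == 0.0

    def test_zero_threshold_keeps_all_nonzero_weights(self, rng):
        m = make_matrix(random_symmetric(10, rng))
        net = binarize(m, 0.0)
        assert np.array_equal(net.adjacency == 1, m.weights != 0)

    def test_extreme_thresholds_bracket_density(self, rng):
        m = make_matrix(random_symmetric(12, rng))
        dense = binarize(m, 0.0)
        empty = binarize(m, np.abs(m.weights).max())
        assert dense.adjacency.sum() == np.count_nonzero(m.weights)
        assert empty.adjacency.sum() == 0

    def test_negative_threshold_rejected(self, rng):
        with pytest.raises(ParameterError):
            binarize(make_matrix(random_symmetric(5, rng)), -0.1)


class TestTopology:
    def test_complete_graph_is_one_component(self):
        adj = 1 - np.eye(6, dtype=np.int8)
        assert largest_component_fraction(net_from_adjacency(adj)) == 1.0

    def test_two_disjoint_triangles(self):
        adj = np.zeros((6, 6), dtype=np.int8)
        for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
            adj[a, b] = adj[b, a] = 1
        assert largest_component_fraction(net_from_adjacency(adj)) == 0.5

    def test_edgeless_graph_counts_singletons(self):
        assert largest_component_fraction(
            net_from_adjacency(np.zeros((10, 10), dtype=np.int8))
        ) == 0.1

    def test_triangle_transitivity_is_one(self):
        adj = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=np.int8)
        assert clustering_coefficient(net_from_adjacency(adj)) == 1.0

    def test_star_has_no_triangles(self):
        adj = np.zeros((5, 5), dtype=np.int8)
        adj[0, 1:] = adj[1:, 0] = 1
        assert clustering_coefficient(net_from_adjacency(adj)) == 0.0

    def test_ring_lattice_closed_form(self):
        # transitivity of a degree-k ring lattice is 3(k-2)/(4(k-1))
        net = net_from_adjacency(ring_lattice_adjacency(20, 4))
        assert clustering_coefficient(net) == pytest.approx(0.5)

    def test_agrees_with_networkx_and_igraph_on_random_graphs(self, rng):
        import igraph
        import networkx as nx

        for _ in range(100):
            n = int(rng.integers(5, 30))
            adj = (random_symmetric(n, rng) > 0.3).astype(np.int8)
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            net = net_from_adjacency(adj)
            g_nx = nx.from_numpy_array(adj)
            assert clustering_coefficient(net) == pytest.approx(
                nx.transitivity(g_nx), abs=1e-12
            )
            lcc_nx = max(len(c) for c in nx.connected_components(g_nx)) / n
            assert largest_component_fraction(net) == pytest.approx(lcc_nx)
            g_ig = igraph.Graph.Adjacency(adj.tolist(), mode="undirected")
            t_ig = g_ig.transitivity_undirected(mode="zero")
            assert clustering_coefficient(net) == pytest.approx(t_ig, abs=1e-12)

    def test_lcc_fraction_non_increasing_in_threshold(self, rng):
        for _ in range(20):
            m = make_matrix(random_symmetric(25, rng))
            fractions = [
                largest_component_fraction(binarize(m, w_t))
                for w_t in np.linspace(0, 1, 21)
            ]
            assert all(b <= a + 1e-15 for a, b in zip(fractions, fractions[1:]))


class TestDeltaClustering:
    def test_constant_series_gives_zeros(self):
        series = [(float(i), 0.4) for i in range(5)]
        assert [d for _, d in delta_clustering(series)] == [0.0] * 4

    def test_direct_subtraction(self):
        out = delta_clustering([(0.0, 0.5), (1.0, 0.3), (2.0, 0.3)])
        assert out == [(0.0, 0.2), (1.0, 0.0)]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=2, max_size=30))
    def test_telescoping_identity(self, cs):
        series = [(float(i), c) for i, c in enumerate(cs)]
        deltas = delta_clustering(series)
        assert sum(d for _, d in deltas) == pytest.approx(cs[0] - cs[-1], abs=1e-9)

    def test_too_short_or_unordered_rejected(self):
        with pytest.raises(ParameterError):
            delta_clustering([(0.0, 0.5)])
        with pytest.raises(ParameterError):
            delta_clustering([(1.0, 0.5), (0.5, 0.4)])
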