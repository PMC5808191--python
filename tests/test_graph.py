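"""Connectivity construction and graph-metric correctness."""

import numpy as np
import pytest

import oracles
import rsvmcluster as rc


class TestPearsonConnectivity:
    def test_identical_and_anticorrelated_columns_give_one(self):
        t = np.arange(6, dtype=float)
        ts = rc.ROITimeSeries(np.column_stack([t, t + 2, -3 * t]))
        conn = rc.pearson_connectivity(ts)
        assert conn.values[0, 1] == pytest.approx(1.0)
        assert conn.values[0, 2] == pytest.approx(1.0)  # |r| of anticorrelation
        assert np.all(np.diag(conn.values) == 0)

    def test_matches_direct_covariance_formula(self):
        vals = np.array(
            [[1.0, 2.0, 0.5], [3.0, 1.5, 2.5], [2.0, 4.0, 1.0], [5.0, 3.0, 4.0]]
        )
        conn = rc.pearson_connectivity(rc.ROITimeSeries(vals))
        for i in range(3):
            for j in range(i + 1, 3):
                expected = abs(oracles.pearson_formula(vals[:, i], vals[:, j]))
                assert conn.values[i, j] == pytest.approx(expected)
                assert conn.values[j, i] == pytest.approx(expected)

    def test_constant_column_rejected_by_name(self):
        vals = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(ValueError, match="R002"):
            rc.ROITimeSeries(vals)

    def test_too_few_timepoints_rejected(self):
        with pytest.raises(ValueError, match="3 time points"):
            rc.ROITimeSeries(np.random.default_rng(0).random((2, 4)))


class TestThresholdGraph:
    def _conn(self, value, n=4):
        m = np.full((n, n), float(value))
        np.fill_diagonal(m, 0.0)
        return rc.ConnectivityMatrix(m)

    def test_above_threshold_gives_complete_graph(self):
        g = rc.threshold_graph(self._conn(0.3), 0.25)
        assert g.adjacency.sum() == 4 * 3

    def test_below_threshold_gives_empty_graph(self):
        g = rc.threshold_graph(self._conn(0.1), 0.25)
        assert g.adjacency.sum() == 0

    def test_exact_threshold_is_not_an_edge(self):
        g = rc.threshold_graph(self._conn(0.25), 0.25)
        assert g.adjacency.sum() == 0

    @pytest.mark.parametrize("tau", [-0.1, 1.0, 1.5])
    def test_invalid_threshold_rejected(self, tau):
        with pytest.raises(ValueError, match="threshold"):
            rc.threshold_graph(self._conn(0.3), tau)


class TestToyGraphs:
    """Hand-computed metric tables for named small graphs."""

    @pytest.mark.parametrize("name", sorted(rc.toy_graph_fixtures()))
    def test_fixture_metrics(self, name):
        fx = rc.toy_graph_fixtures()[name]
        g = rc.BrainGraph(fx["adjacency"], threshold=0.0)
        m = rc.compute_metrics(g)
        np.testing.assert_array_equal(m.degree, fx["degree"])
        np.testing.assert_allclose(m.clustering, fx["clustering"])
        if "local_efficiency" in fx:
            np.testing.assert_allclose(m.local_efficiency, fx["local_efficiency"])
        if "shortest_path" in fx:
            np.testing.assert_array_equal(m.shortest_path, fx["shortest_path"])

    def test_disconnected_pairs_get_sentinel_n(self):
        fx = rc.toy_graph_fixtures()["disconnected"]
        d = rc.shortest_paths(rc.BrainGraph(fx["adjacency"], threshold=0.0))
        assert d[2, 3] == 6  # sentinel = number of nodes
        assert d[0, 1] == 1

    def test_path_graph_endpoint_distance(self):
        fx = rc.toy_graph_fixtures()["path4"]
        d = rc.shortest_paths(rc.BrainGraph(fx["adjacency"], threshold=0.0))
        assert d[0, 3] == 3  # n - 1 hops end to end


class TestMetricsAgainstBruteForce:
    """All four metric families agree exactly with independent oracles."""

    @pytest.mark.parametrize("trial", range(40))
    def test_random_graphs_match_oracles(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(4, 16))
        p = float(rng.uniform(0.1, 0.7))
        adj = oracles.random_adjacency(rng, n, p)
        g = rc.BrainGraph(adj, threshold=0.0)
        np.testing.assert_array_equal(
            rc.degrees(g), oracles.degrees_by_edge_count(adj)
        )
        np.testing.assert_array_equal(
            rc.shortest_paths(g), oracles.floyd_warshall(adj)
        )
        np.testing.assert_allclose(
            rc.clustering_coefficients(g), oracles.clustering_by_triples(adj)
        )
        np.testing.assert_allclose(
            rc.local_efficiencies(g),
            oracles.local_efficiency_by_enumeration(adj),
        )


class TestMetricInvariants:
    def test_empty_graph_metrics(self):
        g = rc.BrainGraph(np.zeros((7, 7), dtype=int), threshold=0.0)
        m = rc.compute_metrics(g)
        assert np.all(m.degree == 0)
        assert np.all(m.clustering == 0)
        assert np.all(m.local_efficiency == 0)
        off = ~np.eye(7, dtype=bool)
        assert np.all(m.shortest_path[off] == 7)

    def test_raising_threshold_is_monotone(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 1, (12, 12))
        vals = np.triu(vals, 1) + np.triu(vals, 1).T
        conn = rc.ConnectivityMatrix(vals)
        for lo, hi in [(0.1, 0.3), (0.3, 0.5), (0.2, 0.6)]:
            m_lo = rc.compute_metrics(rc.threshold_graph(conn, lo))
            m_hi = rc.compute_metrics(rc.threshold_graph(conn, hi))
            assert np.all(m_hi.degree <= m_lo.degree)
            assert np.all(m_hi.shortest_path >= m_lo.shortest_path)

    def test_metric_value_ranges(self):
        rng = np.random.default_rng(6)
        adj = oracles.random_adjacency(rng, 10, 0.4)
        m = rc.compute_metrics(rc.BrainGraph(adj, threshold=0.0))
        assert np.all((m.degree >= 0) & (m.degree <= 9))
        assert np.all((m.clustering >= 0) & (m.clustering <= 1))
        assert np.all((m.local_efficiency >= 0) & (m.local_efficiency <= 1))
        assert np.all(np.diag(m.shortest_path) == 0)
        np.testing.assert_array_equal(m.shortest_path, m.shortest_path.T)
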