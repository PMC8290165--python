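"""Metric layer: closed forms, brute-force agreement, invariances."""

import json

import networkx as nx
import numpy as np
import pytest

from vasculograph import (
    MetricsReport,
    average_path_length,
    clustering_coefficient,
    network_structure_entropy,
    summarize,
    volume_node_regression,
)
from vasculograph.metrics import reports_table

from _oracles import brute_apl, brute_clustering, brute_entropy


class TestClusteringCoefficient:
    @pytest.mark.parametrize(
        "graph, expected",
        [
            (nx.complete_graph(4), 1.0),
            (nx.star_graph(4), 0.0),
            (nx.Graph([(0, 1), (1, 2), (2, 0), (0, 3)]), 7 / 12),
        ],
        ids=["K4", "S5", "triangle_pendant"],
    )
    def test_closed_forms(self, graph, expected):
        assert clustering_coefficient(graph) == pytest.approx(expected, abs=1e-12)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            clustering_coefficient(nx.empty_graph(0))

    def test_relabeling_invariance(self):
        g = nx.gnp_random_graph(20, 0.2, seed=7)
        mapping = dict(zip(g.nodes(), np.random.default_rng(0).permutation(20)))
        h = nx.relabel_nodes(g, {k: int(v) for k, v in mapping.items()})
        assert clustering_coefficient(g) == pytest.approx(clustering_coefficient(h), abs=1e-12)


class TestAveragePathLength:
    @pytest.mark.parametrize(
        "graph, convention, expected",
        [
            (nx.path_graph(3), "connected_pairs", 4 / 3),
            (nx.path_graph(3), "zero_fill", 4 / 3),
            (nx.complete_graph(4), "connected_pairs", 1.0),
            (nx.Graph([(0, 1), (2, 3)]), "connected_pairs", 1.0),
            (nx.Graph([(0, 1), (2, 3)]), "zero_fill", 1 / 3),
        ],
        ids=["P3_cp", "P3_zf", "K4", "2edges_cp", "2edges_zf"],
    )
    def test_closed_forms(self, graph, convention, expected):
        assert average_path_length(graph, convention) == pytest.approx(expected, abs=1e-12)

    def test_no_reachable_pair_rejected(self):
        with pytest.raises(ValueError):
            average_path_length(nx.empty_graph(3), "connected_pairs")

    def test_single_node_rejected(self):
        with pytest.raises(ValueError):
            average_path_length(nx.empty_graph(1))

    def test_unknown_convention_rejected(self):
        with pytest.raises(ValueError):
            average_path_length(nx.path_graph(3), "harmonic")


class TestNetworkStructureEntropy:
    @pytest.mark.parametrize("n", [3, 5, 10])
    def test_cycle_is_maximally_uniform(self, n):
        e, nse = network_structure_entropy(nx.cycle_graph(n))
        assert e == pytest.approx(np.log(n), abs=1e-12)
        assert nse == pytest.approx(1.0, abs=1e-12)

    def test_star_closed_form(self):
        e, nse = network_structure_entropy(nx.star_graph(4))
        assert e == pytest.approx(2 * np.log(2), abs=1e-12)
        assert nse == pytest.approx(2 * np.log(2) / np.log(5), abs=1e-12)

    def test_single_edge(self):
        e, nse = network_structure_entropy(nx.Graph([(0, 1)]))
        assert e == pytest.approx(np.log(2), abs=1e-12)
        assert nse == pytest.approx(1.0, abs=1e-12)

    def test_edgeless_rejected(self):
        with pytest.raises(ValueError):
            network_structure_entropy(nx.empty_graph(3))

    def test_degree_zero_nodes_excluded_with_warning(self):
        g = nx.Graph([(0, 1)])
        g.add_node(2)
        with pytest.warns(UserWarning):
            e, nse = network_structure_entropy(g)
        assert e == pytest.approx(np.log(2), abs=1e-12)


class TestOracleAgreement:
    def test_metrics_match_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(123)
        for k in range(50):
            n = int(rng.integers(2, 51))
            p = float(rng.uniform(0.05, 0.4))
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(0, 2**31)))
            assert clustering_coefficient(g) == pytest.approx(brute_clustering(g), abs=1e-9)
            for conv in ("connected_pairs", "zero_fill"):
                try:
                    expected = brute_apl(g, conv)
                except ValueError:
                    with pytest.raises(ValueError):
                        average_path_length(g, conv)
                    continue
                assert average_path_length(g, conv) == pytest.approx(expected, abs=1e-9)
            degs = [d for _, d in g.degree()]
            if sum(degs) > 0:
                e, nse = network_structure_entropy(g)
                be, bnse = brute_entropy(g)
                assert e == pytest.approx(be, abs=1e-9)
                assert nse == pytest.approx(bnse, abs=1e-9)


class TestSummarize:
    def test_tree_phantom_report(self, tree3, tree3_raster):
        from vasculograph import build_graph, prune_spurs, skeletonize

        _, mask = tree3_raster
        vg = build_graph(prune_spurs(skeletonize(mask), 13.5))
        report = summarize(vg, mask, specimen_id="tree3", group="normal")
        assert (report.n_nodes, report.n_edges, report.n_components) == (16, 15, 1)
        assert report.cc == 0.0  # a tree has no triangles
        assert report.segmented_vascular_volume_um3 == pytest.approx(
            mask.count() * 4.5**3
        )

    def test_report_roundtrips_through_json(self, tmp_path):
        report = MetricsReport(
            cc=0.1, apl=3.2, apl_convention="zero_fill", entropy=4.5, nse=0.97,
            n_nodes=10, n_edges=9, n_components=1, n_self_loops=0,
            segmented_vascular_volume_um3=1234.5, specimen_id="s", group="g",
        )
        path = tmp_path / "r.json"
        report.to_json(path)
        assert MetricsReport.from_json(path) == report
        assert MetricsReport(**json.loads(report.to_json())) == report


class TestVolumeNodeRegression:
    def _reports(self, vols, nodes):
        return [
            MetricsReport(
                cc=0, apl=0, apl_convention="zero_fill", entropy=0, nse=0,
                n_nodes=int(n), n_edges=0, n_components=1, n_self_loops=0,
                segmented_vascular_volume_um3=float(v),
            )
            for v, n in zip(vols, nodes)
        ]

    def test_exact_linear_points(self):
        vols = [1.0, 2.0, 3.0, 4.0]
        slope, intercept, r = volume_node_regression(self._reports(vols, [2 * v for v in vols]))
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-9)
        assert r == pytest.approx(1.0)

    def test_replication_invariance(self):
        vols, nodes = [1.0, 2.0, 4.0], [3, 5, 9]
        one = volume_node_regression(self._reports(vols, nodes))
        two = volume_node_regression(self._reports(vols * 2, nodes * 2))
        assert one[0] == pytest.approx(two[0]) and one[1] == pytest.approx(two[1])

    def test_permutation_null_far_below_observed(self):
        rng = np.random.default_rng(6)
        vols = rng.uniform(1, 10, 12)
        nodes = 3 * vols + rng.normal(0, 0.5, 12)
        observed = abs(volume_node_regression(self._reports(vols, nodes))[2])
        null = []
        for _ in range(500):
            null.append(abs(volume_node_regression(self._reports(vols, rng.permutation(nodes)))[2]))
        assert np.mean(null) < observed / 2

    def test_too_few_or_constant_rejected(self):
        with pytest.raises(ValueError):
            volume_node_regression(self._reports([1, 2], [1, 2]))
        with pytest.raises(ValueError):
            volume_node_regression(self._reports([5, 5, 5], [1, 2, 3]))

    def test_reports_table_shape(self):
        table = reports_table(self._reports([1, 2, 3], [1, 2, 3]))
        assert len(table) == 3 and "n_nodes" in table.columns


# --- property-based invariants --------------------------------------------

from hypothesis import given, settings
from hypothesis import strategies as st


@st.composite
def small_graphs(draw):
    n = draw(st.integers(min_value=2, max_value=12))
    edges = draw(
        st.lists(
            st.tuples(st.integers(0, n - 1), st.integers(0, n - 1)), max_size=30
        )
    )
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from((u, v) for u, v in edges if u != v)
    return g


@settings(deadline=None, max_examples=60, derandomize=True)
@given(small_graphs())
def test_metric_bounds_and_convention_order(g):
    """CC and NSE stay in [0, 1]; zero-fill APL never exceeds the
    connected-pairs APL (unreachable pairs only ever shrink the mean)."""
    cc = clustering_coefficient(g)
    assert 0.0 <= cc <= 1.0
    if any(d > 0 for _, d in g.degree()):
        e, nse = network_structure_entropy(g)
        assert 0.0 <= nse <= 1.0
        assert e >= 0.0
    try:
        cp = average_path_length(g, "connected_pairs")
    except ValueError:
        return
    zf = average_path_length(g, "zero_fill")
    assert zf <= cp + 1e-12
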