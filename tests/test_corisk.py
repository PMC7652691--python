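"""CoRisk integration: arrows, inner/outer tally, hubs, layout, export."""

import numpy as np
import pandas as pd
import pytest

from corisk.bicluster import BiclusterPartition, BipartiteGraph
from corisk.corisk import (
    CoRiskNetwork,
    RiskEdge,
    build_corisk,
    classify_inner_outer,
    detect_asymmetric_hubs,
    explode_layout,
    export_network,
    heterogeneity_chi_square,
    inner_outer_table,
    plot_network,
    read_network,
)
from corisk.errors import ComputationError, DataValidationError
from corisk.risk import OrResult, PairRiskResult, ReplicatedPairSet


def _toy_network():
    """Two biclusters: {p0,p1,A,B} and {p2,p3,C,D}; p0 and p2 inner."""
    g = BipartiteGraph(
        ["p0", "p1", "p2", "p3"],
        ["A", "B", "C", "D"],
        {("p0", "A"), ("p0", "B"), ("p1", "A"),
         ("p2", "C"), ("p2", "D"), ("p3", "C")},
    )
    comm = {"p0": 0, "p1": 0, "A": 0, "B": 0,
            "p2": 1, "p3": 1, "C": 1, "D": 1}
    part = BiclusterPartition(comm, 2, 0.5)
    return g, part


def _replicated(pairs):
    """pairs: list of (a, b, pattern)."""
    entries = []
    uniq = set()
    for a, b, pattern in pairs:
        pr = PairRiskResult(a, b, OrResult(2.5, 1.5, 4.0, 1e-4, 1e-3),
                            significant_overall=True,
                            direction_pattern=pattern)
        entries.append((a, b, pr, pr))
        uniq |= {a, b}
    return ReplicatedPairSet(entries, uniq)


class TestBuildCorisk:
    def test_a_only_arrow_points_to_a(self):
        g, part = _toy_network()
        net = build_corisk(g, part, _replicated([("A", "B", "a_only")]))
        assert len(net.risk_edges) == 1
        e = net.risk_edges[0]
        assert (e.source, e.target) == ("B", "A")
        assert e.significant_direction == "ab_vs_a"
        assert e.or_pair == pytest.approx(2.5)

    def test_b_only_arrow_points_to_b(self):
        g, part = _toy_network()
        net = build_corisk(g, part, _replicated([("A", "B", "b_only")]))
        assert (net.risk_edges[0].source, net.risk_edges[0].target) == ("A", "B")

    def test_both_gives_two_opposing_arrows(self):
        g, part = _toy_network()
        net = build_corisk(g, part, _replicated([("A", "B", "both")]))
        assert {(e.source, e.target) for e in net.risk_edges} == {
            ("A", "B"), ("B", "A")}

    def test_unknown_comorbidity_raises(self):
        g, part = _toy_network()
        with pytest.raises(DataValidationError, match="absent"):
            build_corisk(g, part, _replicated([("A", "Z", "both")]))

    def test_patient_classes_populated(self):
        g, part = _toy_network()
        net = build_corisk(g, part, _replicated([]))
        assert net.patient_class == {"p0": "inner", "p1": "outer",
                                     "p2": "inner", "p3": "outer"}

    def test_self_loop_edge_rejected(self):
        with pytest.raises(DataValidationError, match="self-loop"):
            RiskEdge("A", "A", 2.0, "ab_vs_a")


class TestInnerOuter:
    def test_tally_shape_and_counts(self):
        g, part = _toy_network()
        net = build_corisk(g, part, _replicated([]))
        _, table = classify_inner_outer(net)
        assert list(table.index) == ["one_comorbidity",
                                     "multiple_comorbidities"]
        assert table.to_numpy().tolist() == [[1, 1], [1, 1]]

    def test_formatted_table_totals(self):
        counts = pd.DataFrame([[30, 10], [10, 30]],
                              index=["one_comorbidity",
                                     "multiple_comorbidities"],
                              columns=["bicluster_0", "bicluster_1"])
        out = inner_outer_table(counts)
        assert out.loc["one_comorbidity", "bicluster_0"] == "30 (75.0)"
        assert out.loc["total", "total"] == "80 (100.0)"
        assert out.loc["one_comorbidity", "total"] == "40 (50.00)"


class TestHeterogeneity:
    def test_matches_scipy_on_known_table(self):
        from scipy.stats import chi2_contingency

        counts = [[30, 10, 5], [10, 30, 5]]
        res = heterogeneity_chi_square(counts)
        ref = chi2_contingency(np.array(counts), correction=False)
        assert res.chi2 == pytest.approx(ref.statistic)
        assert res.df == 2
        assert res.n == 90

    def test_homogeneous_table_p_near_one(self):
        res = heterogeneity_chi_square([[20, 20], [20, 20]])
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_raises(self):
        with pytest.raises(ComputationError, match="margin"):
            heterogeneity_chi_square([[0, 0], [5, 5]])

    def test_wrong_shape_raises(self):
        with pytest.raises(DataValidationError, match="2 x C"):
            heterogeneity_chi_square([[1, 2, 3]])


class TestHubs:
    def test_net_receiver_detected(self):
        g, part = _toy_network()
        # a_only sends the arrow toward the pair's first member
        net = build_corisk(g, part, _replicated([
            ("B", "A", "a_only"),   # A -> B
            ("B", "C", "a_only"),   # C -> B
        ]))
        hubs = detect_asymmetric_hubs(net)
        indeg = {e.target for e in net.risk_edges}
        assert all(h[0] in indeg for h in hubs)
        assert all(h[1] > h[2] for h in hubs)

    def test_sorted_by_excess(self):
        g, part = _toy_network()
        net = CoRiskNetwork(g, part, [
            RiskEdge("A", "B", 2.0, "ab_vs_b"),
            RiskEdge("C", "B", 2.0, "ab_vs_b"),
            RiskEdge("A", "D", 2.0, "ab_vs_b"),
        ])
        hubs = detect_asymmetric_hubs(net)
        assert hubs[0] == ("B", 2, 0)
        assert hubs[1] == ("D", 1, 0)

    def test_balanced_node_not_a_hub(self):
        g, part = _toy_network()
        net = CoRiskNetwork(g, part, [
            RiskEdge("A", "B", 2.0, "ab_vs_b"),
            RiskEdge("B", "A", 2.0, "ab_vs_a"),
        ])
        assert detect_asymmetric_hubs(net) == []


class TestLayout:
    def test_within_community_distances_preserved(self):
        g, part = _toy_network()
        net = build_corisk(g, part, _replicated([]))
        base = explode_layout(net, explode_factor=0.0, seed=3)
        exploded = explode_layout(net, explode_factor=1.0, seed=3)
        for u, v in [("p0", "A"), ("p0", "B"), ("p2", "C")]:
            d0 = np.linalg.norm(np.subtract(base[u], base[v]))
            d1 = np.linalg.norm(np.subtract(exploded[u], exploded[v]))
            assert d1 == pytest.approx(d0, abs=1e-9)

    def test_communities_move_apart(self):
        g, part = _toy_network()
        net = build_corisk(g, part, _replicated([]))
        base = explode_layout(net, explode_factor=0.0, seed=3)
        exploded = explode_layout(net, explode_factor=1.0, seed=3)

        def centroid_gap(pos):
            c0 = np.mean([pos[n] for n in ["p0", "p1", "A", "B"]], axis=0)
            c1 = np.mean([pos[n] for n in ["p2", "p3", "C", "D"]], axis=0)
            return np.linalg.norm(c0 - c1)

        assert centroid_gap(exploded) > centroid_gap(base)

    def test_seeded_determinism(self):
        g, part = _toy_network()
        net = build_corisk(g, part, _replicated([]))
        assert explode_layout(net, seed=5) == explode_layout(net, seed=5)

    def test_negative_factor_rejected(self):
        g, part = _toy_network()
        net = build_corisk(g, part, _replicated([]))
        with pytest.raises(DataValidationError):
            explode_layout(net, explode_factor=-1.0)

    def test_large_graph_hybrid_layout_covers_all_nodes(self):
        rng = np.random.default_rng(0)
        n_p = 120
        patients = [f"p{i}" for i in range(n_p)]
        comorbs = [f"c{j}" for j in range(6)]
        edges = {(p, comorbs[rng.integers(0, 6)]) for p in patients}
        g = BipartiteGraph(patients, comorbs, edges)
        from corisk.corisk import _base_layout

        pos = _base_layout(g, seed=1, dense_limit=50)
        assert set(pos) == set(patients) | set(comorbs)


class TestExportImport:
    @pytest.mark.parametrize("fmt", ["graphml", "json"])
    def test_round_trip(self, tmp_path, fmt):
        g, part = _toy_network()
        net = build_corisk(g, part, _replicated([("A", "B", "both")]),
                           single_or={"A": 1.7, "B": 0.9})
        net.coordinates = explode_layout(net, seed=0)
        path = tmp_path / f"net.{fmt}"
        export_network(net, fmt, path)
        back = read_network(fmt, path)
        assert set(back.bipartite.patient_nodes) == set(g.patient_nodes)
        assert back.bipartite.edges == g.edges
        assert back.partition.community_of == part.community_of
        assert {(e.source, e.target, e.significant_direction)
                for e in back.risk_edges} == {
            ("A", "B", "ab_vs_b"), ("B", "A", "ab_vs_a")}
        assert back.node_or["A"] == pytest.approx(1.7)
        assert back.patient_class == net.patient_class
        for n, (x, y) in net.coordinates.items():
            assert back.coordinates[n] == pytest.approx((x, y))

    def test_unknown_format_raises(self, tmp_path):
        g, part = _toy_network()
        net = build_corisk(g, part, _replicated([]))
        with pytest.raises(DataValidationError, match="format"):
            export_network(net, "dot", tmp_path / "x")

    def test_plot_writes_svg(self, tmp_path):
        g, part = _toy_network()
        net = build_corisk(g, part, _replicated([("A", "B", "a_only")]))
        path = tmp_path / "net.svg"
        plot_network(net, path)
        assert path.stat().st_size > 0
        assert path.read_text()[:200].lstrip().startswith("<?xml")
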