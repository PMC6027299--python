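"""Network construction, betweenness ranking and coverage statistics."""
import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cernet.network import (
    betweenness,
    build_network,
    coverage_table,
    coverage_table_from_counts,
    coverage_union,
    extract_subnetwork,
    is_connected,
    network_totals,
    rank_bc,
    select_hubs,
    write_graphml,
    write_sif,
)
from oracles import brute_betweenness


def triple_frame(triples):
    rows = [(l, m, g, 0.5, 1e-6, -0.5, 1e-6, -0.4, 1e-6) for l, m, g in triples]
    return pd.DataFrame(rows, columns=[
        "lnc_id", "mirna_id", "mrna_id",
        "pcc_lnc_mrna", "p_lnc_mrna", "pcc_lnc_mirna", "p_lnc_mirna",
        "pcc_mrna_mirna", "p_mrna_mirna"])


class TestBuild:
    def test_single_triple(self):
        g = build_network(triple_frame([("l1", "m1", "g1")]))
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2
        assert g.nodes["m1"]["cls"] == "miRNA"

    def test_shared_mirna(self):
        g = build_network(triple_frame([("l1", "m1", "g1"), ("l2", "m1", "g2")]))
        assert g.number_of_nodes() == 5 and g.number_of_edges() == 4

    def test_duplicate_triples_idempotent(self):
        t = [("l1", "m1", "g1")]
        g1 = build_network(triple_frame(t))
        g2 = build_network(triple_frame(t * 3))
        assert nx.utils.graphs_equal(g1, g2)

    def test_class_conflict_rejected(self):
        with pytest.raises(ValueError, match="x"):
            build_network(triple_frame([("x", "m1", "g1"), ("l1", "x", "g2")]))

    def test_size_bounds(self):
        """edges <= 2T and nodes <= 3T, equality iff nothing is shared."""
        shared = triple_frame([("l1", "m1", "g1"), ("l1", "m1", "g2")])
        disjoint = triple_frame([("l1", "m1", "g1"), ("l2", "m2", "g2")])
        gs, gd = build_network(shared), build_network(disjoint)
        assert gs.number_of_edges() < 4 and gs.number_of_nodes() < 6
        assert gd.number_of_edges() == 4 and gd.number_of_nodes() == 6


class TestBetweenness:
    def test_path_graph(self):
        g = nx.path_graph(["a", "b", "c"])
        bc = betweenness(g)
        assert bc == {"a": 0.0, "b": 1.0, "c": 0.0}

    def test_star_closed_form(self):
        g = nx.star_graph(5)  # center 0, leaves 1..5
        bc = betweenness(g)
        assert bc[0] == 10.0  # C(5, 2)
        assert all(bc[i] == 0.0 for i in range(1, 6))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 21))
        g = nx.gnp_random_graph(n, 0.25, seed=int(rng.integers(2**31)))
        expected = brute_betweenness(list(g.nodes), list(g.edges))
        got = betweenness(g)
        for node in g.nodes:
            assert got[node] == pytest.approx(expected[node], abs=1e-9)

    def test_disconnected_graph_per_component(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("x", "y")])
        bc = betweenness(g)
        assert bc["b"] == 1.0 and bc["x"] == 0.0


class TestRanking:
    def test_single_node_cumulative_100(self):
        g = nx.path_graph(["a", "b", "c"])
        ranked = rank_bc(g)
        assert ranked["node"].iloc[0] == "b"
        assert ranked["cumulative_pct"].iloc[0] == pytest.approx(100.0)

    def test_tie_break_and_cumulative_arithmetic(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        ranked = rank_bc(g, bc={"c": 1.0, "a": 1.0, "b": 2.0})
        assert ranked["node"].tolist() == ["b", "a", "c"]
        assert ranked["cumulative_pct"].tolist() == pytest.approx([50.0, 75.0, 100.0])

    def test_zero_total_warns(self):
        g = nx.empty_graph(3)
        with pytest.warns(UserWarning):
            ranked = rank_bc(g)
        assert (ranked["cumulative_pct"] == 0).all()


class TestHubs:
    def ranked(self):
        return pd.DataFrame({
            "node": ["m1", "l1", "g1", "l2", "l3"],
            "cls": ["miRNA", "lncRNA", "mRNA", "lncRNA", "lncRNA"],
            "bc": [10.0, 8.0, 7.0, 5.0, 1.0],
            "cumulative_pct": [32.3, 58.1, 80.6, 96.8, 100.0],
        })

    def test_class_restriction_skips_top_mirna(self):
        assert select_hubs(self.ranked(), k=2) == ["l1", "l2"]

    def test_k_zero(self):
        assert select_hubs(self.ranked(), k=0) == []

    def test_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            hubs = select_hubs(self.ranked(), k=5)
        assert hubs == ["l1", "l2", "l3"]


class TestSubnetworks:
    four = triple_frame([
        ("hub", "m1", "g1"), ("hub", "m1", "g2"),
        ("l2", "m2", "g2"), ("l2", "m2", "g3"),
    ])

    def test_hand_counted_coverage(self):
        r = extract_subnetwork(self.four, "hub")
        assert r.coverage == {"demi_pct": 50.0, "dem_pct": 66.67,
                              "triple_pct": 50.0}

    def test_hub_in_every_triple_is_full_coverage(self):
        t = triple_frame([("hub", "m1", "g1"), ("hub", "m2", "g2")])
        r = extract_subnetwork(t, "hub")
        assert set(r.coverage.values()) == {100.0}

    def test_absent_hub_rejected(self):
        with pytest.raises(ValueError):
            extract_subnetwork(self.four, "nope")

    def test_graph_scope_can_be_larger(self):
        # m1 also partners l2's mRNA g3 through a shared-miRNA triple
        t = triple_frame([("hub", "m1", "g1"), ("l2", "m1", "g3")])
        tri = extract_subnetwork(t, "hub", scope="triples")
        gra = extract_subnetwork(t, "hub", scope="graph")
        assert tri.mrnas == frozenset({"g1"})
        assert gra.mrnas == frozenset({"g1", "g3"})

    def test_union_idempotent_and_additive(self):
        r_hub = extract_subnetwork(self.four, "hub")
        r_l2 = extract_subnetwork(self.four, "l2")
        solo = coverage_union([r_hub], self.four)
        assert solo["demi_pct"] == r_hub.coverage["demi_pct"]
        both = coverage_union([r_hub, r_l2], self.four)
        assert both["mirnas"] == 2 and both["triples"] == 4
        assert both["demi_pct"] == 100.0
        # union covers at least the best individual, at most the sum
        for key in ("demi_pct", "dem_pct", "triple_pct"):
            best = max(r_hub.coverage[key], r_l2.coverage[key])
            assert best <= both[key] <= r_hub.coverage[key] + r_l2.coverage[key]

    def test_coverage_table_layout(self):
        table = coverage_table([extract_subnetwork(self.four, "hub")], self.four)
        assert table["network"].tolist() == ["1 hub lncRNAs", "hub", "full network"]
        full = table.iloc[-1]
        assert (full[["demi_pct", "dem_pct", "triple_pct"]] == 100.0).all()


class TestCountsTable:
    def test_counts_reproduce_worked_example_percentages(self):
        from cernet import load_gc_coverage_counts

        table = coverage_table_from_counts(load_gc_coverage_counts())
        by = table.set_index("network")
        assert by.loc["3 hub lncRNAs", "demi_pct"] == 87.5
        assert by.loc["DLEU2", "triple_pct"] == 21.72


def test_connectivity_reported_not_required():
    g1 = build_network(triple_frame([("l1", "m1", "g1")]))
    g2 = build_network(triple_frame([("l1", "m1", "g1"), ("l2", "m2", "g2")]))
    assert is_connected(g1) and not is_connected(g2)


def test_exports_round_trip(tmp_path):
    t = triple_frame([("l1", "m1", "g1"), ("l2", "m1", "g2")])
    g = build_network(t)
    sif = write_sif(g, tmp_path / "net.sif")
    lines = sif.read_text().strip().splitlines()
    assert len(lines) == g.number_of_edges()
    gml = write_graphml(g, tmp_path / "net.graphml", bc=betweenness(g))
    back = nx.read_graphml(gml)
    assert back.number_of_nodes() == g.number_of_nodes()
    assert back.nodes["m1"]["cls"] == "miRNA"
    assert back.nodes["m1"]["bc"] == pytest.approx(betweenness(g)["m1"])
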