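"""Morphological rewriting rules: guards, subtypes, conservation, inverses."""

import networkx as nx
import pytest

from mitonets import (
    MLGraph,
    canonical_certificate,
    enumerate_moves,
    fission,
    graph_statistics,
    legal_moves,
    mitophagy,
    outgrowth,
    resorption,
    ts_fusion,
    tt_fusion,
    validate_mlg,
    vertex_flip,
)
from mitonets.ops import OP_LABELS
from mitonets.synthetic import PopulationSpec, generate_population

# expected (delta n1, delta n3) per applied operation
CONSERVATION = {
    "fission": (2, 0),
    "tt_fusion": (-2, 0),
    "ts_fusion": (-1, 1),
    "outgrowth": (1, 1),
    "resorption": (-1, -1),
    "mitophagy": (-2, 0),
    "vertex_flip": (0, 0),
}


class TestFission:
    def test_bridge_fission_splits_component(self, single_edge):
        r = fission(single_edge, (0, 1))
        assert r.applied and r.subtype == "Type2"
        s = graph_statistics(r.result)
        assert (s.V, s.E, s.C, s.n1) == (4, 2, 2, 4)

    def test_cycle_fission_keeps_component(self, k4):
        r = fission(k4, (0, 1))
        assert r.applied and r.subtype == "Type1"
        s = graph_statistics(r.result)
        assert (s.V, s.n1, s.n3, s.E, s.C) == (6, 2, 4, 7, 1)

    def test_missing_edge_rejected(self, single_edge):
        assert fission(single_edge, (0, 9)).reason == "no such edge"

    def test_length_split_at_fraction(self, single_edge):
        r = fission(single_edge, (0, 1), fraction=0.25)
        lengths = sorted(
            r.result.length(u, v) for u, v in r.result.edges()
        )
        assert lengths == pytest.approx([0.5, 1.5])


class TestTTFusion:
    def test_joins_two_components(self, two_edges):
        r = tt_fusion(two_edges, 0, 2)
        assert r.applied and r.subtype == "Type2"
        assert r.result.n_nodes == 2 and r.result.n_edges == 1
        assert r.result.total_length() == pytest.approx(3.0)

    def test_donut_rejected(self, single_edge):
        assert tt_fusion(single_edge, 0, 1).reason == "self-loop"

    def test_non_tip_rejected(self, k13):
        assert tt_fusion(k13, 0, 1).reason == "degree != 1"

    def test_planarity_guard(self):
        """Fusing the two pendant tips of an augmented K5-minus-edge would
        complete a non-planar graph; the move must be refused."""
        g = nx.complete_graph(5)
        g.remove_edge(0, 1)
        g.add_edge(0, "t0")
        g.add_edge(1, "t1")
        ml = MLGraph(list(g.edges))
        r = tt_fusion(ml, "t0", "t1")
        assert r.status == "rejected" and r.reason == "planarity"

    def test_undoes_fission_up_to_isomorphism(self, k4):
        r = fission(k4, (0, 1))
        g2 = r.result
        new_tips = [v for v in g2.leaves()]
        back = tt_fusion(g2, *new_tips)
        assert back.applied
        assert canonical_certificate(back.result) == canonical_certificate(k4)


class TestTSFusion:
    def test_tip_onto_disjoint_edge_builds_star(self, two_edges):
        r = ts_fusion(two_edges, 0, (2, 3))
        assert r.applied and r.subtype == "Type2"
        s = graph_statistics(r.result)
        assert (s.n1, s.n3) == (3, 1)

    def test_own_edge_rejected(self, single_edge):
        assert ts_fusion(single_edge, 0, (0, 1)).reason == "own edge"

    def test_edge_incident_to_anchor_rejected(self, h_tree):
        # tip 2's anchor is junction 0; edge (0, 1) is incident to it
        assert ts_fusion(h_tree, 2, (0, 1)).reason == "adjacent edge"

    def test_length_split_at_junction(self, two_edges):
        r = ts_fusion(two_edges, 0, (2, 3))
        assert r.result.total_length() == pytest.approx(3.0)


class TestOutgrowth:
    def test_single_edge_becomes_star(self, single_edge):
        r = outgrowth(single_edge, (0, 1))
        k13 = MLGraph([(0, 1), (0, 2), (0, 3)])
        assert canonical_certificate(r.result) == canonical_certificate(k13)

    def test_star_becomes_h_tree(self, k13, h_tree):
        r = outgrowth(k13, (0, 1))
        assert canonical_certificate(r.result) == canonical_certificate(h_tree)
        s = graph_statistics(r.result)
        assert (s.n1, s.n3, s.E) == (4, 2, 5)

    def test_resorption_undoes_outgrowth(self, single_edge):
        r = outgrowth(single_edge, (0, 1))
        new_tip = [v for v in r.result.leaves() if v not in (0, 1)][0]
        back = resorption(r.result, new_tip)
        assert back.applied
        assert canonical_certificate(back.result) == canonical_certificate(single_edge)

    def test_adds_tip_length(self, single_edge):
        r = outgrowth(single_edge, (0, 1), tip_length=0.5)
        assert r.result.total_length() == pytest.approx(2.5)


class TestResorption:
    def test_star_leaf_to_single_edge(self, k13):
        r = resorption(k13, 1)
        assert r.applied and r.result.n_nodes == 2
        # pendant length absorbed: total conserved
        assert r.result.total_length() == pytest.approx(6.0)

    def test_pendant_on_triangle_rejected(self):
        tri = MLGraph([(0, 1), (1, 2), (2, 0), (2, 3)])
        assert resorption(tri, 3).reason == "parallel edge"

    def test_isolated_tubule_is_mitophagy_domain(self, single_edge):
        assert resorption(single_edge, 0).reason == "isolated tubule"


class TestMitophagy:
    def test_removes_isolated_tubule_only(self, k4):
        g = MLGraph(
            [("a", "b")] + [e for e in k4.edges()],
        )
        r = mitophagy(g, "a")
        assert r.applied
        assert canonical_certificate(r.result) == canonical_certificate(
            MLGraph(k4.edges())
        )
        assert mitophagy(g, 0).reason == "not an isolated tubule"

    def test_last_tubule_leaves_empty_graph(self, single_edge):
        r = mitophagy(single_edge, 0)
        assert r.applied and r.result.n_nodes == 0
        assert validate_mlg(r.result).valid


class TestVertexFlip:
    def test_h_tree_flip_is_symmetric(self, h_tree):
        results = vertex_flip(h_tree, (0, 1))
        applied = [r for r in results if r.applied]
        assert len(applied) == 2
        for r in applied:
            assert canonical_certificate(r.result) == canonical_certificate(h_tree)

    def test_k4_flips_all_rejected(self, k4):
        results = vertex_flip(k4, (0, 1))
        assert all(r.status == "rejected" for r in results)

    def test_tip_edge_rejected(self, k13):
        results = vertex_flip(k13, (0, 1))
        assert results[0].reason == "requires two degree-3 nodes"

    def test_counts_unchanged(self, prism):
        for r in vertex_flip(prism, (0, 1)):
            if r.applied:
                s0, s1 = graph_statistics(prism), graph_statistics(r.result)
                assert (s0.n1, s0.n3, s0.E) == (s1.n1, s1.n3, s1.E)


class TestEnumerateMoves:
    def test_single_edge_moves(self, single_edge):
        ms = enumerate_moves(single_edge)
        ops = {(lbl, m) for lbl, _, m in ms.entries}
        assert ops == {("fission", 1), ("outgrowth", 1), ("mitophagy", 1)}

    def test_k4_fission_multiplicity_six(self, k4):
        ms = enumerate_moves(k4, ["fission"])
        assert ms.entries == [("fission", ms.entries[0][1], 6)]

    def test_empty_graph_has_no_moves(self):
        assert enumerate_moves(MLGraph()).entries == []


@pytest.fixture(scope="module")
def operation_pool():
    """Graphs spanning trees, cycles, and multiple components."""
    pop = generate_population(PopulationSpec(style="wildtype", size=12, seed=21))
    pop += generate_population(PopulationSpec(style="dko", size=8, seed=22))
    return pop


class TestClosureAndConservation:
    def test_every_applied_move_stays_in_class(self, operation_pool):
        """Closure plus the per-operation (dn1, dn3) bookkeeping."""
        checked = 0
        for g in operation_pool:
            s0 = graph_statistics(g)
            for move in legal_moves(g, OP_LABELS):
                assert validate_mlg(move.result).valid, (
                    f"{move.op_label} broke the class"
                )
                s1 = graph_statistics(move.result)
                dn1, dn3 = CONSERVATION[move.op_label]
                assert (s1.n1 - s0.n1, s1.n3 - s0.n3) == (dn1, dn3), move.op_label
                checked += 1
        assert checked > 300

    def test_subtype_matches_component_change(self, operation_pool):
        for g in operation_pool[:8]:
            c0 = graph_statistics(g).C
            for move in legal_moves(g, ("fission", "tt_fusion", "ts_fusion")):
                c1 = graph_statistics(move.result).C
                if move.subtype == "Type1":
                    assert c1 == c0
                else:
                    assert abs(c1 - c0) == 1

    def test_length_conservation(self, operation_pool):
        """Fission, tip-side splitting, resorption smoothing conserve total
        length; outgrowth adds exactly the tip length; mitophagy removes
        exactly the component length."""
        for g in operation_pool[:8]:
            total = g.total_length()
            for move in legal_moves(g, ("fission", "ts_fusion", "resorption", "tt_fusion")):
                assert move.result.total_length() == pytest.approx(total, abs=1e-9)
            for move in legal_moves(g, ("outgrowth",)):
                assert move.result.total_length() == pytest.approx(total + 0.5, abs=1e-9)
            for move in legal_moves(g, ("mitophagy",)):
                removed = total - move.result.total_length()
                assert removed > 0
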