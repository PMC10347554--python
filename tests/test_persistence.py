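"""Flag-complex persistence, bottleneck distance, cohort comparison."""

import math

import networkx as nx
import numpy as np
import pytest

from mitonets import MLGraph, enumerate_connected_mlg, graph_statistics
from mitonets.persistence import (
    FiltrationSpec,
    PersistenceDiagram,
    bottleneck_distance,
    cohort_comparison,
    vr_persistence,
)

from conftest import persistence_oracle


def with_lengths(g: MLGraph, lengths) -> MLGraph:
    return MLGraph(g.edges(), lengths={e: w for e, w in zip(g.edges(), lengths)})


class TestFiltration:
    def test_single_edge_components_merge_at_half_length(self, single_edge):
        d = vr_persistence(single_edge, FiltrationSpec("weighted"))
        assert sorted(d.in_dim(0)) == [(0.0, 1.0), (0.0, math.inf)]

    def test_cube_has_circuit_rank_many_essential_cycles(self, cube):
        d = vr_persistence(cube, FiltrationSpec("weighted"))
        h1 = d.in_dim(1)
        assert len(h1) == 5  # |E| - |V| + C = 12 - 8 + 1
        assert all(b == 0.5 and math.isinf(dd) for b, dd in h1)

    def test_k4_triangles_fill_instantly(self, k4):
        assert vr_persistence(k4, FiltrationSpec("weighted")).in_dim(1) == []

    def test_essential_h0_equals_components(self, two_edges, wt_population_50):
        d = vr_persistence(two_edges, FiltrationSpec("weighted"))
        assert len(d.essential(0)) == 2
        for g in wt_population_50[:15]:
            d = vr_persistence(g, FiltrationSpec("weighted"))
            assert len(d.essential(0)) == graph_statistics(g).C

    def test_triangle_free_h1_equals_circuit_rank(self, wt_population_50):
        checked = 0
        for g in wt_population_50:
            if any(nx.triangles(g.nx).values()):
                continue
            d = vr_persistence(g, FiltrationSpec("weighted"))
            assert len(d.in_dim(1)) == graph_statistics(g).circuit_rank
            checked += 1
        assert checked >= 5

    def test_weighted_mode_requires_lengths(self):
        with pytest.raises(ValueError, match="lengths"):
            vr_persistence(MLGraph([(0, 1)]), FiltrationSpec("weighted"))

    def test_unweighted_edges_enter_together(self, cube):
        d = vr_persistence(cube, FiltrationSpec("unweighted"))
        finite_h0 = [p for p in d.in_dim(0) if math.isfinite(p[1])]
        assert all(death == 0.5 for _, death in finite_h0)

    def test_geodesic_disconnected_pairs_never_enter(self, two_edges):
        d = vr_persistence(two_edges, FiltrationSpec("geodesic", max_dim=2))
        assert len(d.essential(0)) == 2

    def test_geodesic_octahedron_void(self):
        octa = nx.octahedral_graph()
        g = MLGraph(list(octa.edges), lengths={e: 1.0 for e in octa.edges})
        d = vr_persistence(g, FiltrationSpec("geodesic", max_dim=2))
        assert d.in_dim(2) == [(0.5, 1.0)]


class TestOracleAgreement:
    def test_matches_rank_based_oracle_on_small_classes(self):
        """Reduction pairs equal persistent-Betti inclusion-exclusion bars
        on every connected class up to 6 nodes with random lengths."""
        rng = np.random.default_rng(1)
        for n in (2, 4, 6):
            for _, g in enumerate_connected_mlg(n):
                lengths = rng.uniform(0.4, 3.0, size=g.n_edges)
                gw = with_lengths(g, lengths)
                impl = sorted(vr_persistence(gw, FiltrationSpec("weighted")).points)
                oracle = sorted(persistence_oracle(gw, "weighted", max_dim=1))
                assert [
                    (q, pytest.approx(b), pytest.approx(d)) for q, b, d in oracle
                ] == impl

    def test_matches_oracle_on_eight_node_fixture(self, cube):
        rng = np.random.default_rng(2)
        gw = with_lengths(cube, rng.uniform(0.5, 2.0, size=cube.n_edges))
        impl = sorted(vr_persistence(gw, FiltrationSpec("weighted")).points)
        oracle = sorted(persistence_oracle(gw, "weighted", max_dim=1))
        assert [(q, pytest.approx(b), pytest.approx(d)) for q, b, d in oracle] == impl


def random_diagram(rng, n_points: int, dim: int = 1) -> PersistenceDiagram:
    pts = []
    for _ in range(n_points):
        b = rng.uniform(0, 2)
        pts.append((dim, b, b + rng.uniform(0.05, 2)))
    return PersistenceDiagram(points=tuple(pts))


class TestBottleneck:
    def test_identical_diagrams_zero(self, cube):
        d = vr_persistence(cube, FiltrationSpec("weighted"))
        assert bottleneck_distance(d, d, 1) == 0.0

    def test_single_point_vs_empty_euclidean(self):
        one = PersistenceDiagram(points=((1, 1.0, 3.0),))
        empty = PersistenceDiagram(points=())
        assert bottleneck_distance(one, empty, 1, "euclidean") == pytest.approx(
            math.sqrt(2), abs=1e-9
        )

    def test_single_point_vs_empty_chebyshev(self):
        one = PersistenceDiagram(points=((1, 1.0, 3.0),))
        empty = PersistenceDiagram(points=())
        assert bottleneck_distance(one, empty, 1, "chebyshev") == pytest.approx(
            1.0, abs=1e-9
        )

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            d1 = random_diagram(rng, int(rng.integers(0, 5)))
            d2 = random_diagram(rng, int(rng.integers(0, 5)))
            assert bottleneck_distance(d1, d2, 1) == pytest.approx(
                bottleneck_distance(d2, d1, 1), abs=1e-12
            )

    @pytest.mark.parametrize("metric", ["euclidean", "chebyshev"])
    def test_triangle_inequality_on_sampled_triples(self, metric):
        rng = np.random.default_rng(4)
        for _ in range(30):
            ds = [random_diagram(rng, int(rng.integers(0, 5))) for _ in range(3)]
            cap = 10.0  # shared cap so the three distances are comparable
            d01 = bottleneck_distance(ds[0], ds[1], 1, metric, essential_cap=cap)
            d12 = bottleneck_distance(ds[1], ds[2], 1, metric, essential_cap=cap)
            d02 = bottleneck_distance(ds[0], ds[2], 1, metric, essential_cap=cap)
            assert d02 <= d01 + d12 + 1e-9

    def test_matches_exhaustive_matching_oracle(self):
        """Binary-search matching equals brute-force min-max over all
        point assignments (diagonal allowed) on small diagrams."""
        import itertools

        def brute(P, Q, metric):
            from mitonets.persistence import _diag_dist, _pair_dist

            n, m = len(P), len(Q)
            best = math.inf
            # assign each P point to a Q point or the diagonal
            for targets in itertools.product(range(m + 1), repeat=n):
                used = [t for t in targets if t < m]
                if len(used) != len(set(used)):
                    continue
                cost = 0.0
                for p, t in zip(P, targets):
                    cost = max(
                        cost,
                        _pair_dist(p, Q[t], metric) if t < m else _diag_dist(*p, metric),
                    )
                for j in range(m):
                    if j not in targets:
                        cost = max(cost, _diag_dist(*Q[j], metric))
                best = min(best, cost)
            return best

        rng = np.random.default_rng(5)
        for _ in range(12):
            d1 = random_diagram(rng, int(rng.integers(0, 4)))
            d2 = random_diagram(rng, int(rng.integers(0, 4)))
            for metric in ("euclidean", "chebyshev"):
                got = bottleneck_distance(d1, d2, 1, metric, essential_cap=10.0)
                want = brute(d1.in_dim(1), d2.in_dim(1), metric)
                if math.isinf(want):  # both empty
                    want = 0.0
                assert got == pytest.approx(want, abs=1e-9)


class TestCohort:
    def test_duplicate_graphs_distance_zero(self, k4, cube):
        comp = cohort_comparison(
            {"a": [k4, k4], "b": [cube, cube]}, FiltrationSpec("weighted"), dims=[0]
        )
        M = comp.matrices[0]
        assert M.loc["a:0", "a:1"] == 0.0
        assert np.allclose(M.values, M.values.T)
        assert np.allclose(np.diag(M.values), 0.0)

    def test_requires_two_groups_of_two(self, k4):
        with pytest.raises(ValueError):
            cohort_comparison({"a": [k4, k4]}, FiltrationSpec("weighted"))
        with pytest.raises(ValueError):
            cohort_comparison({"a": [k4, k4], "b": [k4]}, FiltrationSpec("weighted"))

    def test_cyclic_vs_tree_populations_separate_in_h1(self, cohort_populations):
        """Cycle-rich and tree-like populations are closer within than
        across groups in H1 - the topological signature that separates
        wild-type from fission-fusion knockout networks."""
        comp = cohort_comparison(
            cohort_populations, FiltrationSpec("weighted"), dims=[1]
        )
        assert comp.mean_within(1) < comp.mean_between(1)
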