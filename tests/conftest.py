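"""Shared fixtures: canonical small graphs, synthetic populations, oracles."""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np
import pytest

from mitonets import MLGraph
from mitonets.synthetic import PopulationSpec, generate_population

# frozen seeds for the shared populations (study conditions, not dials)
WT50_SEED = 7
DKO50_SEED = 8
COHORT_WT_SEED = 101
COHORT_DKO_SEED = 102


@pytest.fixture
def single_edge() -> MLGraph:
    return MLGraph([(0, 1)], lengths={(0, 1): 2.0})


@pytest.fixture
def two_edges() -> MLGraph:
    return MLGraph([(0, 1), (2, 3)], lengths={(0, 1): 1.0, (2, 3): 2.0})


@pytest.fixture
def k13() -> MLGraph:
    return MLGraph([(0, 1), (0, 2), (0, 3)], lengths={(0, 1): 1.0, (0, 2): 2.0, (0, 3): 3.0})


@pytest.fixture
def k4() -> MLGraph:
    g = nx.complete_graph(4)
    return MLGraph(list(g.edges), lengths={e: 1.0 for e in g.edges})


@pytest.fixture
def h_tree() -> MLGraph:
    """Junctions 0, 1; leaves 2-5."""
    edges = [(0, 1), (0, 2), (0, 3), (1, 4), (1, 5)]
    return MLGraph(edges, lengths={e: 1.0 for e in edges})


@pytest.fixture
def prism() -> MLGraph:
    g = nx.circular_ladder_graph(3)  # triangular prism
    return MLGraph(list(g.edges), lengths={e: 1.0 for e in g.edges})


@pytest.fixture
def cube() -> MLGraph:
    g = nx.convert_node_labels_to_integers(nx.hypercube_graph(3))
    return MLGraph(list(g.edges), lengths={e: 1.0 for e in g.edges})


@pytest.fixture
def k33() -> MLGraph:
    return MLGraph(list(nx.complete_bipartite_graph(3, 3).edges))


@pytest.fixture(scope="session")
def wt_population_50() -> list[MLGraph]:
    return generate_population(PopulationSpec(style="wildtype", size=50, seed=WT50_SEED))


@pytest.fixture(scope="session")
def dko_population_50() -> list[MLGraph]:
    return generate_population(PopulationSpec(style="dko", size=50, seed=DKO50_SEED))


@pytest.fixture(scope="session")
def cohort_populations() -> dict[str, list[MLGraph]]:
    return {
        "wt": generate_population(PopulationSpec(style="wildtype", size=20, seed=COHORT_WT_SEED)),
        "dko": generate_population(PopulationSpec(style="dko", size=20, seed=COHORT_DKO_SEED)),
    }


# -- independent oracles --------------------------------------------------


def wagner_planarity_oracle(g: nx.Graph) -> bool:
    """Planarity by brute-force minor search (no K5 and no K3,3 minor).

    Exponential; intended for graphs with at most ~7 nodes.
    """

    def has_minor(g: nx.Graph, h: nx.Graph) -> bool:
        nodes = list(g.nodes)
        k = h.number_of_nodes()
        if len(nodes) < k:
            return False
        h_nodes = list(h.nodes)
        # assign each g-node to one of the k branch sets or to "unused"
        for assignment in itertools.product(range(k + 1), repeat=len(nodes)):
            parts: list[list] = [[] for _ in range(k)]
            for node, slot in zip(nodes, assignment):
                if slot < k:
                    parts[slot].append(node)
            if any(not p for p in parts):
                continue
            if any(not nx.is_connected(g.subgraph(p)) for p in parts):
                continue
            ok = True
            for i, j in h.edges:
                ii, jj = h_nodes.index(i), h_nodes.index(j)
                if not any(
                    g.has_edge(a, b) for a in parts[ii] for b in parts[jj]
                ):
                    ok = False
                    break
            if ok:
                return True
        return False

    if has_minor(g, nx.complete_graph(5)):
        return False
    if has_minor(g, nx.complete_bipartite_graph(3, 3)):
        return False
    return True


def gf2_rank(mat: np.ndarray) -> int:
    """Rank of a 0/1 matrix over GF(2) by plain row reduction."""
    m = mat.astype(np.uint8).copy() % 2
    rows, cols = m.shape
    rank = 0
    for c in range(cols):
        pivot = None
        for r in range(rank, rows):
            if m[r, c]:
                pivot = r
                break
        if pivot is None:
            continue
        m[[rank, pivot]] = m[[pivot, rank]]
        for r in range(rows):
            if r != rank and m[r, c]:
                m[r] ^= m[rank]
        rank += 1
        if rank == rows:
            break
    return rank


def persistence_oracle(graph: MLGraph, mode: str = "weighted", max_dim: int = 1):
    """Bars via persistent Betti ranks - independent of reduction order.

    Builds the flag filtration directly and computes, for every pair of
    filtration values, the persistent Betti number
    beta_q^{i,j} = dim Z_q(K_i) - dim (B_q(K_j) intersect C_q(K_i)),
    then reads off bar multiplicities by inclusion-exclusion on the value
    grid.  Exponential-ish and for small graphs only.
    """
    import math

    g = graph.nx
    nodes = sorted(g.nodes, key=repr)
    if mode == "weighted":
        edge_val = {tuple(sorted(e, key=repr)): g.edges[e][MLGraph.LENGTH_KEY] / 2.0 for e in g.edges}
    elif mode == "unweighted":
        edge_val = {tuple(sorted(e, key=repr)): 0.5 for e in g.edges}
    else:
        raise ValueError(mode)

    simplices: list[tuple[float, tuple]] = [(0.0, (v,)) for v in nodes]
    for e, val in edge_val.items():
        simplices.append((val, e))
    for tri in itertools.combinations(nodes, 3):
        pairs = [tuple(sorted(p, key=repr)) for p in itertools.combinations(tri, 2)]
        if all(p in edge_val for p in pairs):
            simplices.append((max(edge_val[p] for p in pairs), tri))
    if max_dim >= 2:
        for quad in itertools.combinations(nodes, 4):
            pairs = [tuple(sorted(p, key=repr)) for p in itertools.combinations(quad, 2)]
            if all(p in edge_val for p in pairs):
                simplices.append((max(edge_val[p] for p in pairs), quad))

    values = sorted({v for v, _ in simplices})

    def complex_at(t: float) -> list[tuple]:
        return [s for v, s in simplices if v <= t]

    def boundary_matrix(simps: list[tuple], q: int) -> tuple[np.ndarray, int]:
        q_simps = [s for s in simps if len(s) == q + 1]
        f_simps = [s for s in simps if len(s) == q]
        idx = {s: i for i, s in enumerate(f_simps)}
        mat = np.zeros((len(f_simps), len(q_simps)), dtype=np.uint8)
        for j, s in enumerate(q_simps):
            for face in itertools.combinations(s, q):
                mat[idx[face], j] = 1
        return mat, len(q_simps)

    def cycle_dim(simps: list[tuple], q: int) -> int:
        if q == 0:
            return sum(1 for s in simps if len(s) == 1)
        mat, nq = boundary_matrix(simps, q)
        return nq - gf2_rank(mat)

    def boundary_in(simps_j: list[tuple], simps_i: list[tuple], q: int) -> int:
        """dim of B_q(K_j) intersected with C_q(K_i)."""
        set_i = set(simps_i)
        q_simps_j = [s for s in simps_j if len(s) == q + 2]
        f_simps_j = [s for s in simps_j if len(s) == q + 1]
        if not q_simps_j:
            return 0
        # order faces: those outside K_i first; intersection dim =
        # rank(full) - rank(rows outside K_i)
        outside = [s for s in f_simps_j if s not in set_i]
        ordered = outside + [s for s in f_simps_j if s in set_i]
        idx = {s: i for i, s in enumerate(ordered)}
        mat = np.zeros((len(ordered), len(q_simps_j)), dtype=np.uint8)
        for j, s in enumerate(q_simps_j):
            for face in itertools.combinations(s, q + 1):
                mat[idx[face], j] = 1
        full = gf2_rank(mat)
        top = gf2_rank(mat[: len(outside), :]) if outside else 0
        return full - top

    def persistent_betti(q: int, i: int, j: int) -> int:
        if i < 0:
            return 0
        simps_i = complex_at(values[i])
        simps_j = complex_at(values[j])
        return cycle_dim(simps_i, q) - boundary_in(simps_j, simps_i, q)

    bars: list[tuple[int, float, float]] = []
    k = len(values) - 1
    for q in range(max_dim + 1):
        for i in range(len(values)):
            for j in range(i + 1, len(values)):
                mu = (
                    persistent_betti(q, i, j - 1)
                    - persistent_betti(q, i, j)
                    - persistent_betti(q, i - 1, j - 1)
                    + persistent_betti(q, i - 1, j)
                )
                bars.extend([(q, values[i], values[j])] * mu)
            mu_inf = persistent_betti(q, i, k) - persistent_betti(q, i - 1, k)
            bars.extend([(q, values[i], math.inf)] * mu_inf)
    bars.sort()
    return bars
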