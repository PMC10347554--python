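"""The mitochondria-like graph class and its summary statistics.

A mitochondria-like graph is an undirected, simple, planar graph in which
every node has degree 1 (a tubule tip) or degree 3 (a three-way junction),
possibly disconnected.  The class arises from skeletonized fluorescence
images of budding-yeast mitochondria, which are tethered beneath the
spheroidal cell cortex and therefore planar.  Degree-2 nodes have no
biological interpretation and degree >= 4 junctions are only transient, so
neither belongs to the class - but both remain *representable* in
:class:`MLGraph` so that intermediate rewriting states can exist.

Edge lengths, when present, are tubule lengths in micrometres and must be
positive.  Lengths never participate in isomorphism: the state of a network
is its unweighted graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping

import networkx as nx

from .canon import certificate as _certificate

__all__ = [
    "MLGraph",
    "GraphStats",
    "ValidationReport",
    "validate_mlg",
    "graph_statistics",
    "canonical_certificate",
]

NodeId = Hashable
Edge = tuple[NodeId, NodeId]


class MLGraph:
    """Undirected simple graph with optional positive edge lengths (um).

    Thin wrapper around :class:`networkx.Graph`; the wrapper exists to give
    the domain a name, to centralize validation, and to carry lengths under
    a single attribute key.
    """

    LENGTH_KEY = "length"

    def __init__(
        self,
        edges: Iterable[Edge] = (),
        nodes: Iterable[NodeId] = (),
        lengths: Mapping[Edge, float] | None = None,
    ) -> None:
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for e in edges:
            u, v = e
            if u == v:
                raise ValueError(f"self-loop at node {u!r}")
            g.add_edge(u, v)
        if lengths is not None:
            for (u, v), w in lengths.items():
                if not g.has_edge(u, v):
                    raise KeyError(f"length given for absent edge ({u!r}, {v!r})")
                if not w > 0:
                    raise ValueError(f"non-positive length {w} on edge ({u!r}, {v!r})")
                g.edges[u, v][self.LENGTH_KEY] = float(w)
        self._g = g

    # -- construction -----------------------------------------------------

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "MLGraph":
        out = cls.__new__(cls)
        h = nx.Graph()
        h.add_nodes_from(g.nodes)
        for u, v, data in g.edges(data=True):
            if u == v:
                raise ValueError(f"self-loop at node {u!r}")
            attrs = {}
            if cls.LENGTH_KEY in data:
                w = float(data[cls.LENGTH_KEY])
                if not w > 0:
                    raise ValueError(f"non-positive length {w} on edge ({u!r}, {v!r})")
                attrs[cls.LENGTH_KEY] = w
            h.add_edge(u, v, **attrs)
        out._g = h
        return out

    def copy(self) -> "MLGraph":
        out = MLGraph.__new__(MLGraph)
        out._g = self._g.copy()
        return out

    # -- basic accessors --------------------------------------------------

    @property
    def nx(self) -> nx.Graph:
        return self._g

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def nodes(self) -> list[NodeId]:
        return list(self._g.nodes)

    def edges(self) -> list[Edge]:
        return list(self._g.edges)

    def degree(self, v: NodeId) -> int:
        return self._g.degree[v]

    def has_edge(self, u: NodeId, v: NodeId) -> bool:
        return self._g.has_edge(u, v)

    def neighbors(self, v: NodeId) -> list[NodeId]:
        return list(self._g.neighbors(v))

    def has_lengths(self) -> bool:
        return all(self.LENGTH_KEY in d for _, _, d in self._g.edges(data=True))

    def length(self, u: NodeId, v: NodeId) -> float | None:
        return self._g.edges[u, v].get(self.LENGTH_KEY)

    def total_length(self) -> float:
        return float(
            sum(d.get(self.LENGTH_KEY, 0.0) for _, _, d in self._g.edges(data=True))
        )

    def leaves(self) -> list[NodeId]:
        """L(G): the degree-1 nodes."""
        return [v for v, d in self._g.degree if d == 1]

    def junctions(self) -> list[NodeId]:
        return [v for v, d in self._g.degree if d == 3]

    def k_neighborhood(self, v: NodeId, k: int) -> set[NodeId]:
        """N_k(v): the set of nodes at shortest-path distance exactly k hops."""
        dist = nx.single_source_shortest_path_length(self._g, v, cutoff=k)
        return {u for u, d in dist.items() if d == k}

    def components(self) -> list[set[NodeId]]:
        return [set(c) for c in nx.connected_components(self._g)]

    def fresh_node(self) -> int:
        """An integer id not already present (for rewriting)."""
        existing = {v for v in self._g.nodes if isinstance(v, int)}
        return (max(existing) + 1) if existing else 0

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"MLGraph(|V|={self.n_nodes}, |E|={self.n_edges})"


@dataclass(frozen=True)
class ValidationReport:
    valid: bool
    violations: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class GraphStats:
    """Whole-graph summary statistics.

    F counts faces of a planar embedding *including* the outer face, fixed
    by the Euler relation V - E + F - C = 1 (so chi = V - E + F = 2 for a
    single component on the sphere).  alpha is the dispersion fraction: the
    share of tips whose sole neighbor is also a tip, i.e. tips sitting on
    isolated two-node tubules; alpha := 0 when there are no tips.
    """

    n1: int
    n3: int
    E: int
    V: int
    C: int
    F: int
    chi: int
    alpha: float
    circuit_rank: int


def validate_mlg(graph: MLGraph) -> ValidationReport:
    """Check membership in the mitochondria-like class.

    Violations are named rules: "simple" (self-loop/multi-edge cannot occur
    through the MLGraph constructor but malformed networkx input can),
    "degree" (a node of degree other than 1 or 3), "parity" (odd node
    count; implied by odd degrees but reported separately), and
    "planarity".  The empty graph is vacuously valid.
    """
    g = graph.nx
    violations: list[str] = []
    if any(u == v for u, v in g.edges):
        violations.append("simple")
    bad_deg = [v for v, d in g.degree if d not in (1, 3)]
    if bad_deg:
        violations.append("degree")
    if g.number_of_nodes() % 2 != 0:
        violations.append("parity")
    is_planar, _ = nx.check_planarity(g)
    if not is_planar:
        violations.append("planarity")
    return ValidationReport(valid=not violations, violations=violations)


def graph_statistics(graph: MLGraph) -> GraphStats:
    g = graph.nx
    degs = dict(g.degree)
    n1 = sum(1 for d in degs.values() if d == 1)
    n3 = sum(1 for d in degs.values() if d == 3)
    V = g.number_of_nodes()
    E = g.number_of_edges()
    C = nx.number_connected_components(g)
    F = 1 + C + E - V
    chi = V - E + F
    if n1 == 0:
        alpha = 0.0
    else:
        on_isolated = sum(
            1
            for v, d in degs.items()
            if d == 1 and degs[next(iter(g.neighbors(v)))] == 1
        )
        alpha = on_isolated / n1
    return GraphStats(
        n1=n1,
        n3=n3,
        E=E,
        V=V,
        C=C,
        F=F,
        chi=chi,
        alpha=alpha,
        circuit_rank=E - V + C,
    )


def canonical_certificate(graph: MLGraph) -> str:
    """Text token equal across relabelings, distinct across isomorphism classes."""
    return _certificate(graph.nodes(), graph.edges())


def dispersion_alpha(graph: MLGraph) -> float:
    return graph_statistics(graph).alpha


def isolated_tubule_components(graph: MLGraph) -> list[set[NodeId]]:
    """Components that are a single edge between two tips (mitophagy targets)."""
    out = []
    for comp in graph.components():
        if len(comp) == 2 and all(graph.degree(v) == 1 for v in comp):
            out.append(comp)
    return out
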