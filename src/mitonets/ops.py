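"""The seven morphological operations on mitochondria-like graphs.

Each operation is a guarded rewriting rule: it either *applies*, returning
a new graph that is again mitochondria-like, or is *rejected* with a named
reason.  The guards (no self-loops, no parallel edges, planarity preserved)
encode the physical constraints of cortex-tethered mitochondria: a fusion
event whose product could not be drawn on the cell surface is simply not
available to the network.

Subtypes follow the component-count convention: Type 1 keeps the number of
connected components, Type 2 changes it by one (fission splits, fusion
joins).  Fission and tip-tip fusion are mutually inverse, as are outgrowth
and resorption; mitophagy (removal of an isolated two-tip tubule) has no
single-step inverse.

Length bookkeeping (all lengths in um):

* fission splits the broken edge at a configurable fraction (default the
  midpoint) between the two daughter tip edges;
* tip-tip fusion concatenates the two consumed tip edges;
* tip-side fusion splits the target edge at the new junction;
* outgrowth subdivides the mother edge and attaches a new tip edge of
  configurable length (default 0.5 um, the minimal tubule unit);
* resorption absorbs the pendant edge into the smoothed through-edge, so
  total length is conserved;
* mitophagy removes the component's length from the network.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import networkx as nx

from .graph import MLGraph, NodeId, canonical_certificate

__all__ = [
    "OperationResult",
    "MoveSet",
    "OP_LABELS",
    "fission",
    "tt_fusion",
    "ts_fusion",
    "outgrowth",
    "resorption",
    "mitophagy",
    "vertex_flip",
    "enumerate_moves",
    "legal_moves",
    "DEFAULT_TIP_LENGTH",
]

OpLabel = Literal[
    "fission", "tt_fusion", "ts_fusion", "outgrowth", "resorption", "mitophagy", "vertex_flip"
]
OP_LABELS: tuple[OpLabel, ...] = (
    "fission",
    "tt_fusion",
    "ts_fusion",
    "outgrowth",
    "resorption",
    "mitophagy",
    "vertex_flip",
)

#: default length of a freshly grown tip tubule, um (minimal tubule unit)
DEFAULT_TIP_LENGTH = 0.5

_LEN = MLGraph.LENGTH_KEY


@dataclass(frozen=True)
class OperationResult:
    status: Literal["applied", "rejected"]
    op_label: OpLabel
    reason: str = ""
    subtype: Literal["Type1", "Type2", "n/a"] = "n/a"
    result: MLGraph | None = None
    #: description of the rewriting target (edge, tip pair, ...)
    target: tuple = ()

    @property
    def applied(self) -> bool:
        return self.status == "applied"


def _rejected(op: OpLabel, reason: str, target: tuple = ()) -> OperationResult:
    return OperationResult(status="rejected", op_label=op, reason=reason, target=target)


def _applied(op: OpLabel, g: MLGraph, subtype: str, target: tuple = ()) -> OperationResult:
    return OperationResult(
        status="applied", op_label=op, subtype=subtype, result=g, target=target
    )


def _is_planar(g: nx.Graph) -> bool:
    ok, _ = nx.check_planarity(g)
    return ok


def fission(graph: MLGraph, edge: tuple[NodeId, NodeId], fraction: float = 0.5) -> OperationResult:
    """Sever an edge, capping both stumps with new tips.

    Type 2 iff the edge was a bridge (the component splits); otherwise the
    component survives with one more independent-cycle removed.
    """
    u, v = edge
    if not graph.has_edge(u, v):
        return _rejected("fission", "no such edge", (u, v))
    if not 0.0 < fraction < 1.0:
        raise ValueError("fission fraction must lie strictly between 0 and 1")
    bridges = set(nx.bridges(graph.nx))
    was_bridge = (u, v) in bridges or (v, u) in bridges
    g = graph.nx.copy()
    w = g.edges[u, v].get(_LEN)
    g.remove_edge(u, v)
    out = MLGraph.from_networkx(g)
    a = out.fresh_node()
    b = a + 1
    attrs_a = {_LEN: w * fraction} if w is not None else {}
    attrs_b = {_LEN: w * (1.0 - fraction)} if w is not None else {}
    out.nx.add_edge(u, a, **attrs_a)
    out.nx.add_edge(v, b, **attrs_b)
    subtype = "Type2" if was_bridge else "Type1"
    return _applied("fission", out, subtype, (u, v))


def tt_fusion(graph: MLGraph, tip_a: NodeId, tip_b: NodeId) -> OperationResult:
    """Fuse two tips: both tip nodes vanish and their anchors become joined.

    Rejected when the tips are adjacent (the product would be a self-loop -
    the excluded toroidal "donut"), when the anchors are already joined
    (parallel edge), or when the fused graph loses planarity.
    """
    target = (tip_a, tip_b)
    if tip_a == tip_b:
        return _rejected("tt_fusion", "identical tips", target)
    for t in (tip_a, tip_b):
        if t not in graph.nx:
            return _rejected("tt_fusion", "no such node", target)
        if graph.degree(t) != 1:
            return _rejected("tt_fusion", "degree != 1", target)
    u = next(iter(graph.neighbors(tip_a)))
    v = next(iter(graph.neighbors(tip_b)))
    if u == tip_b or v == tip_a:
        return _rejected("tt_fusion", "self-loop", target)
    if u == v:
        return _rejected("tt_fusion", "self-loop", target)
    if graph.has_edge(u, v):
        return _rejected("tt_fusion", "parallel edge", target)
    same_component = nx.has_path(graph.nx, tip_a, tip_b)
    g = graph.nx.copy()
    wa = g.edges[tip_a, u].get(_LEN)
    wb = g.edges[tip_b, v].get(_LEN)
    g.remove_node(tip_a)
    g.remove_node(tip_b)
    attrs = {_LEN: wa + wb} if (wa is not None and wb is not None) else {}
    g.add_edge(u, v, **attrs)
    if not _is_planar(g):
        return _rejected("tt_fusion", "planarity", target)
    subtype = "Type1" if same_component else "Type2"
    return _applied("tt_fusion", MLGraph.from_networkx(g), subtype, target)


def ts_fusion(graph: MLGraph, tip: NodeId, edge: tuple[NodeId, NodeId]) -> OperationResult:
    """Fuse a tip into the side of an edge, turning the tip into a junction.

    The target edge may be neither the tip's own edge nor any edge incident
    to the tip's anchor (either would create a loop or parallel edge: the
    |E|-1 / |E|-3 eligible-edge accounting of the mass-action rate).
    """
    x, y = edge
    target = (tip, (x, y))
    if tip not in graph.nx:
        return _rejected("ts_fusion", "no such node", target)
    if graph.degree(tip) != 1:
        return _rejected("ts_fusion", "degree != 1", target)
    if not graph.has_edge(x, y):
        return _rejected("ts_fusion", "no such edge", target)
    u = next(iter(graph.neighbors(tip)))
    if {x, y} == {tip, u}:
        return _rejected("ts_fusion", "own edge", target)
    if tip in (x, y):
        return _rejected("ts_fusion", "adjacent edge", target)
    if u in (x, y):
        return _rejected("ts_fusion", "adjacent edge", target)
    same_component = nx.has_path(graph.nx, tip, x)
    g = graph.nx.copy()
    w = g.edges[x, y].get(_LEN)
    g.remove_edge(x, y)
    half = {} if w is None else {_LEN: w / 2.0}
    g.add_edge(x, tip, **half)
    g.add_edge(y, tip, **half)
    if not _is_planar(g):
        return _rejected("ts_fusion", "planarity", target)
    subtype = "Type1" if same_component else "Type2"
    return _applied("ts_fusion", MLGraph.from_networkx(g), subtype, target)


def outgrowth(
    graph: MLGraph, edge: tuple[NodeId, NodeId], tip_length: float = DEFAULT_TIP_LENGTH
) -> OperationResult:
    """Grow a new pendant tubule from the side of an edge.

    The mother edge is subdivided by a new junction carrying a new tip.
    Subdivision and pendant attachment preserve planarity, so the move is
    always legal on an existing edge.
    """
    x, y = edge
    if not graph.has_edge(x, y):
        return _rejected("outgrowth", "no such edge", (x, y))
    g = graph.nx.copy()
    w = g.edges[x, y].get(_LEN)
    g.remove_edge(x, y)
    out = MLGraph.from_networkx(g)
    m = out.fresh_node()
    t = m + 1
    half = {} if w is None else {_LEN: w / 2.0}
    tip_attrs = {} if w is None else {_LEN: float(tip_length)}
    out.nx.add_edge(x, m, **half)
    out.nx.add_edge(y, m, **half)
    out.nx.add_edge(m, t, **tip_attrs)
    return _applied("outgrowth", out, "Type1", (x, y))


def resorption(graph: MLGraph, tip: NodeId) -> OperationResult:
    """Absorb a pendant tubule into its adjoining tubule, smoothing the junction.

    The pendant tip and its edge vanish; the junction (now degree 2) is
    smoothed into a single through-edge whose length absorbs all three
    former edges.  Rejected when smoothing would close a 2-cycle (parallel
    edge, e.g. a pendant on a triangle) and when the neighbor is itself a
    tip (an isolated tubule - that removal is mitophagy's domain).
    """
    if tip not in graph.nx:
        return _rejected("resorption", "no such node", (tip,))
    if graph.degree(tip) != 1:
        return _rejected("resorption", "degree != 1", (tip,))
    m = next(iter(graph.neighbors(tip)))
    if graph.degree(m) == 1:
        return _rejected("resorption", "isolated tubule", (tip,))
    if graph.degree(m) != 3:
        return _rejected("resorption", "neighbor not a junction", (tip,))
    x, y = [w for w in graph.neighbors(m) if w != tip]
    if graph.has_edge(x, y):
        return _rejected("resorption", "parallel edge", (tip,))
    g = graph.nx.copy()
    wt = g.edges[m, tip].get(_LEN)
    wx = g.edges[x, m].get(_LEN)
    wy = g.edges[m, y].get(_LEN)
    g.remove_node(tip)
    g.remove_node(m)
    if None not in (wt, wx, wy):
        g.add_edge(x, y, **{_LEN: wx + wy + wt})
    else:
        g.add_edge(x, y)
    return _applied("resorption", MLGraph.from_networkx(g), "Type1", (tip,))


def mitophagy(graph: MLGraph, node: NodeId) -> OperationResult:
    """Degrade an isolated two-tip tubule component."""
    if node not in graph.nx:
        return _rejected("mitophagy", "no such node", (node,))
    comp = nx.node_connected_component(graph.nx, node)
    if len(comp) != 2 or any(graph.degree(v) != 1 for v in comp):
        return _rejected("mitophagy", "not an isolated tubule", (node,))
    g = graph.nx.copy()
    g.remove_nodes_from(comp)
    return _applied("mitophagy", MLGraph.from_networkx(g), "Type2", (node,))


def vertex_flip(graph: MLGraph, edge: tuple[NodeId, NodeId]) -> list[OperationResult]:
    """T1 transition: two adjacent junctions exchange one neighbor each.

    With u's other neighbors {a, b} and v's {c, d}, the two candidate
    re-equilibrations are u:{a,c} v:{b,d} and u:{a,d} v:{b,c}.  Each is
    guarded for simplicity and planarity.  Node counts are unchanged by
    every applied candidate.
    """
    u, v = edge
    target = (u, v)
    if not graph.has_edge(u, v):
        return [_rejected("vertex_flip", "no such edge", target)]
    if graph.degree(u) != 3 or graph.degree(v) != 3:
        return [_rejected("vertex_flip", "requires two degree-3 nodes", target)]
    a, b = [w for w in graph.neighbors(u) if w != v]
    c, d = [w for w in graph.neighbors(v) if w != u]
    results: list[OperationResult] = []
    # candidate exchanges: u keeps a and takes c (v takes b), or u keeps a and
    # takes d (v takes b); the third pairing {a,b}|{c,d} is the identity.
    for incoming_u in (c, d):
        if graph.has_edge(u, incoming_u) or graph.has_edge(v, b):
            results.append(_rejected("vertex_flip", "parallel edge", target))
            continue
        g = graph.nx.copy()
        w_ub = g.edges[u, b].get(_LEN)
        w_vin = g.edges[v, incoming_u].get(_LEN)
        g.remove_edge(u, b)
        g.remove_edge(v, incoming_u)
        g.add_edge(u, incoming_u, **({} if w_vin is None else {_LEN: w_vin}))
        g.add_edge(v, b, **({} if w_ub is None else {_LEN: w_ub}))
        if not _is_planar(g):
            results.append(_rejected("vertex_flip", "planarity", target))
            continue
        results.append(_applied("vertex_flip", MLGraph.from_networkx(g), "Type1", target))
    return results


# -- exhaustive move listing ---------------------------------------------


def legal_moves(
    graph: MLGraph, allowed_ops: Iterable[OpLabel] = OP_LABELS
) -> list[OperationResult]:
    """Every applied result of every allowed operation on every legal target.

    Each distinct application is listed once: fission/outgrowth per edge,
    tip-tip fusion per unordered tip pair, tip-side fusion per (tip, edge),
    resorption per pendant tip, mitophagy per isolated component, vertex
    flip per junction-junction edge and candidate exchange.
    """
    allowed = set(allowed_ops)
    out: list[OperationResult] = []
    edges = graph.edges()
    tips = graph.leaves()
    if "fission" in allowed:
        for e in edges:
            r = fission(graph, e)
            if r.applied:
                out.append(r)
    if "tt_fusion" in allowed:
        for i in range(len(tips)):
            for j in range(i + 1, len(tips)):
                r = tt_fusion(graph, tips[i], tips[j])
                if r.applied:
                    out.append(r)
    if "ts_fusion" in allowed:
        for t in tips:
            for e in edges:
                r = ts_fusion(graph, t, e)
                if r.applied:
                    out.append(r)
    if "outgrowth" in allowed:
        for e in edges:
            r = outgrowth(graph, e)
            if r.applied:
                out.append(r)
    if "resorption" in allowed:
        for t in tips:
            r = resorption(graph, t)
            if r.applied:
                out.append(r)
    if "mitophagy" in allowed:
        for comp in nx.connected_components(graph.nx):
            rep = min(comp, key=repr)
            r = mitophagy(graph, rep)
            if r.applied:
                out.append(r)
    if "vertex_flip" in allowed:
        for u, v in edges:
            if graph.degree(u) == 3 and graph.degree(v) == 3:
                for r in vertex_flip(graph, (u, v)):
                    if r.applied:
                        out.append(r)
    return out


@dataclass(frozen=True)
class MoveSet:
    """Legal applications aggregated by resulting isomorphism class."""

    entries: list[tuple[OpLabel, str, int]] = field(default_factory=list)
    # (op_label, resulting certificate, multiplicity)

    def total_multiplicity(self, op: OpLabel | None = None) -> int:
        return sum(m for lbl, _, m in self.entries if op is None or lbl == op)

    def by_op(self) -> dict[OpLabel, list[tuple[str, int]]]:
        out: dict[OpLabel, list[tuple[str, int]]] = {}
        for lbl, cert, m in self.entries:
            out.setdefault(lbl, []).append((cert, m))
        return out


def enumerate_moves(
    graph: MLGraph, allowed_ops: Iterable[OpLabel] = OP_LABELS
) -> MoveSet:
    """Aggregate :func:`legal_moves` by (operation, resulting certificate).

    The multiplicity of an entry counts distinct legal applications of the
    operation that land in the same isomorphism class (e.g. fission on the
    six equivalent edges of K4).
    """
    counts: dict[tuple[OpLabel, str], int] = {}
    for r in legal_moves(graph, allowed_ops):
        assert r.result is not None
        cert = canonical_certificate(r.result)
        key = (r.op_label, cert)
        counts[key] = counts.get(key, 0) + 1
    entries = sorted(
        [(lbl, cert, m) for (lbl, cert), m in counts.items()],
        key=lambda t: (t[0], t[1]),
    )
    return MoveSet(entries=entries)
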