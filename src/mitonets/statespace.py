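"""Operation-labeled state space over canonical graphs.

States are isomorphism classes of mitochondria-like graphs (canonical
certificates); a directed transition connects two states when a single
morphological operation converts a representative of one into a member of
the other.  Operations are not their own inverses, so the space is
directed.  Parallel applications landing in the same class are aggregated:
a transition carries its operation label, the number of distinct legal
applications (multiplicity), and a rate weight = rate constant x
multiplicity.  Rates that depend on graph structure are evaluated on the
source state's representative.

The full space is infinite; construction is a breadth-first closure from
seed graphs truncated at a maximum node count, with moves that would leave
the truncation excluded from the generator (and counted as boundary hits).
Stationary distributions come from the continuous-time generator Q
(off-diagonal = rate weight, diagonal = minus the row sum) via a dense
null-space solve; reducible chains are restricted to a recurrent class.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

from .graph import MLGraph, canonical_certificate
from .ops import OP_LABELS, OpLabel, legal_moves

__all__ = ["StateSpace", "Transition", "build_state_space", "stationary_distribution"]


@dataclass(frozen=True)
class Transition:
    source: str
    target: str
    op_label: OpLabel
    multiplicity: int
    rate_weight: float


@dataclass
class StateSpace:
    states: list[str]
    representatives: dict[str, MLGraph]
    transitions: list[Transition]
    max_nodes: int
    seeds: list[str]
    truncated: bool = False
    boundary_hits: int = 0

    def out_transitions(self, cert: str) -> list[Transition]:
        return [t for t in self.transitions if t.source == cert]

    def is_strongly_connected(self) -> bool:
        """Ergodicity diagnostic over the truncated reachable space."""
        g = nx.DiGraph()
        g.add_nodes_from(self.states)
        g.add_edges_from((t.source, t.target) for t in self.transitions)
        return nx.is_strongly_connected(g) if len(self.states) > 0 else True


def build_state_space(
    seeds: Iterable[MLGraph],
    max_nodes: int,
    allowed_ops: Iterable[OpLabel] = OP_LABELS,
    rates: Mapping[OpLabel, float] | None = None,
    max_states: int = 10_000,
) -> StateSpace:
    """Breadth-first closure of the allowed operations from the seeds.

    ``rates`` maps operation labels to rate constants (default 1.0 for
    every allowed operation - the class has no canonical constants; users
    override).  Results exceeding ``max_nodes`` nodes are excluded; if the
    frontier exceeds ``max_states`` states the result is flagged truncated.
    """
    allowed = tuple(allowed_ops)
    if rates is None:
        rates = {op: 1.0 for op in allowed}
    seed_list = list(seeds)
    if not seed_list:
        raise ValueError("at least one seed graph required")
    if any(s.n_nodes > max_nodes for s in seed_list):
        raise ValueError("max_nodes smaller than a seed graph")

    reps: dict[str, MLGraph] = {}
    order: list[str] = []
    queue: list[str] = []
    for s in seed_list:
        cert = canonical_certificate(s)
        if cert not in reps:
            reps[cert] = s
            order.append(cert)
            queue.append(cert)
    seed_certs = list(order)

    transitions: list[Transition] = []
    truncated = False
    boundary = 0
    while queue:
        if len(reps) > max_states:
            truncated = True
            break
        cert = queue.pop(0)
        g = reps[cert]
        agg: dict[tuple[str, OpLabel], int] = {}
        for move in legal_moves(g, allowed):
            assert move.result is not None
            if move.result.n_nodes > max_nodes:
                boundary += 1
                continue
            tgt = canonical_certificate(move.result)
            agg[(tgt, move.op_label)] = agg.get((tgt, move.op_label), 0) + 1
            if tgt not in reps:
                reps[tgt] = move.result
                order.append(tgt)
                queue.append(tgt)
        for (tgt, op), mult in sorted(agg.items()):
            transitions.append(
                Transition(
                    source=cert,
                    target=tgt,
                    op_label=op,
                    multiplicity=mult,
                    rate_weight=float(rates.get(op, 1.0)) * mult,
                )
            )
    return StateSpace(
        states=order,
        representatives=reps,
        transitions=transitions,
        max_nodes=max_nodes,
        seeds=seed_certs,
        truncated=truncated,
        boundary_hits=boundary,
    )


def _generator_matrix(space: StateSpace) -> np.ndarray:
    idx = {c: i for i, c in enumerate(space.states)}
    n = len(space.states)
    Q = np.zeros((n, n))
    for t in space.transitions:
        if t.source == t.target:
            continue  # self-transitions do not move probability
        Q[idx[t.source], idx[t.target]] += t.rate_weight
    np.fill_diagonal(Q, 0.0)
    Q[np.diag_indices(n)] = -Q.sum(axis=1)
    return Q


@dataclass(frozen=True)
class StationaryResult:
    pi: dict[str, float]
    reducible: bool
    recurrent_class: list[str]
    residual: float


def stationary_distribution(space: StateSpace) -> StationaryResult:
    """Stationary law pi solving pi Q = 0, sum pi = 1.

    If the transition digraph is not strongly connected the chain is
    reducible; probability then concentrates on a recurrent (terminal
    strongly-connected) class and the solve is restricted to the class
    containing the first seed - or, if the seed is transient, to the
    unique terminal class reachable from it.
    """
    if not space.states:
        raise ValueError("empty state space")
    weights = [t.rate_weight for t in space.transitions]
    if not any(w > 0 for w in weights):
        raise ValueError("degenerate generator: all rate weights zero")

    dg = nx.DiGraph()
    dg.add_nodes_from(space.states)
    dg.add_edges_from(
        (t.source, t.target) for t in space.transitions if t.rate_weight > 0
    )
    sccs = list(nx.strongly_connected_components(dg))
    cond = nx.condensation(dg, scc=sccs)
    terminal = [c for c in cond.nodes if cond.out_degree(c) == 0]
    reducible = len(sccs) > 1

    seed = space.seeds[0]
    member = {v: c for c in cond.nodes for v in cond.nodes[c]["members"]}
    seed_comp = member[seed]
    if seed_comp in terminal:
        chosen = seed_comp
    else:
        reach = [c for c in terminal if nx.has_path(cond, seed_comp, c)]
        if len(reach) != 1:
            raise ValueError(
                "seed is transient and multiple recurrent classes are "
                f"reachable ({len(reach)}); stationary law is not unique"
            )
        chosen = reach[0]
    members = sorted(cond.nodes[chosen]["members"], key=space.states.index)

    sub = StateSpace(
        states=members,
        representatives={c: space.representatives[c] for c in members},
        transitions=[
            t
            for t in space.transitions
            if t.source in set(members) and t.target in set(members)
        ],
        max_nodes=space.max_nodes,
        seeds=[members[0]],
    )
    Q = _generator_matrix(sub)
    n = Q.shape[0]
    # solve pi Q = 0 with normalization: replace one column by ones
    A = Q.T.copy()
    A[-1, :] = 1.0
    b = np.zeros(n)
    b[-1] = 1.0
    pi = np.linalg.lstsq(A, b, rcond=None)[0]
    pi = np.clip(pi, 0.0, None)
    pi /= pi.sum()
    residual = float(np.abs(pi @ Q).max())
    full_pi = {c: 0.0 for c in space.states}
    for c, p in zip(members, pi):
        full_pi[c] = float(p)
    return StationaryResult(
        pi=full_pi, reducible=reducible, recurrent_class=members, residual=residual
    )
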