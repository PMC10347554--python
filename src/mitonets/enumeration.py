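"""Exhaustive enumeration and counting of mitochondria-like graphs.

The class - simple planar graphs with all degrees in {1, 3} - has no known
closed-form count, so connected representatives are generated exhaustively:
for each admissible split of n nodes into tips (degree 1) and junctions
(degree 3), all labeled simple graphs realizing the degree sequence are
built by recursive edge augmentation, then filtered for connectivity and
planarity and deduplicated by canonical certificate.

Totals over possibly-disconnected graphs follow from the connected counts
through a partition sum: a graph on n nodes is an unordered multiset of
connected pieces, so each partition K of n contributes the product over its
distinct part sizes k of multichoose(connected(k), multiplicity of k)
combinations (identical smaller networks may appear in duplicate).  The
partition sum is validated against direct exhaustive generation of the
disconnected graphs at small n.

Printed growth bounds: the per-vertex upper bound 30.061^n from
information-theoretic planar-graph counting, and a two-term lower
expression 1.255*2.48^n/n^2.5 + 0.009099*7.5036^n/n^2.5 assembled from
asymptotics of cubic outerplanar graphs and of unrooted degree-1/3 trees
("boron trees").  Both are asymptotic statements: the upper bound holds at
every n we can test, while the lower expression overshoots the true counts
at small n and is reported as printed, not asserted (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator

import networkx as nx

from .canon import certificate as _certificate
from .graph import MLGraph

__all__ = [
    "CountTable",
    "enumerate_connected_mlg",
    "enumerate_all_mlg",
    "count_mlg_recursive",
    "count_bounds",
    "build_count_table",
    "MAX_NODES_DEFAULT",
]

#: refusal threshold for exhaustive generation (combinatorial explosion)
MAX_NODES_DEFAULT = 12

LOWER_C1, LOWER_G1 = 1.255, 2.48
LOWER_C2, LOWER_G2 = 0.009099, 7.5036
UPPER_GROWTH = 30.061


def _labeled_graphs_with_degrees(degrees: list[int]) -> Iterator[list[tuple[int, int]]]:
    """All labeled simple graphs on 0..n-1 realizing the degree sequence.

    Recursive saturation of the lowest-index node with remaining stubs,
    pairing it with strictly later partners; each labeled graph is produced
    exactly once.
    """
    n = len(degrees)
    remaining = list(degrees)
    edges: list[tuple[int, int]] = []
    adjacency = [set() for _ in range(n)]

    def rec(lo: int) -> Iterator[list[tuple[int, int]]]:
        while lo < n and remaining[lo] == 0:
            lo += 1
        if lo == n:
            yield list(edges)
            return
        # feasibility: enough stubs among later nodes to saturate lo
        candidates = [
            v
            for v in range(lo + 1, n)
            if remaining[v] > 0 and v not in adjacency[lo]
        ]
        need = remaining[lo]
        if len(candidates) < need:
            return

        def choose(idx: int, left: int) -> Iterator[list[tuple[int, int]]]:
            if left == 0:
                yield from rec(lo + 1)
                return
            if len(candidates) - idx < left:
                return
            for i in range(idx, len(candidates)):
                v = candidates[i]
                if remaining[v] == 0:
                    continue
                remaining[lo] -= 1
                remaining[v] -= 1
                edges.append((lo, v))
                adjacency[lo].add(v)
                adjacency[v].add(lo)
                yield from choose(i + 1, left - 1)
                adjacency[lo].discard(v)
                adjacency[v].discard(lo)
                edges.pop()
                remaining[lo] += 1
                remaining[v] += 1

        yield from choose(0, need)

    yield from rec(0)


def _degree_splits(n: int) -> Iterator[list[int]]:
    """Degree sequences (n1 ones then n3 threes) with an even stub total."""
    for n3 in range(n + 1):
        n1 = n - n3
        if (n1 + 3 * n3) % 2 == 0:
            yield [3] * n3 + [1] * n1  # junctions first: saturates faster


def _enumerate(n: int, connected_only: bool, max_nodes: int) -> dict[str, MLGraph]:
    if n < 0:
        raise ValueError("node count must be non-negative")
    if n > max_nodes:
        raise ValueError(
            f"exhaustive enumeration refused for n={n} > {max_nodes} "
            "(combinatorial explosion); raise max_nodes explicitly to override"
        )
    found: dict[str, MLGraph] = {}
    if n == 0:
        if not connected_only:
            found["0:"] = MLGraph()
        return found
    for degrees in _degree_splits(n):
        for edges in _labeled_graphs_with_degrees(degrees):
            g = nx.Graph()
            g.add_nodes_from(range(n))
            g.add_edges_from(edges)
            if connected_only and not nx.is_connected(g):
                continue
            ok, _ = nx.check_planarity(g)
            if not ok:
                continue
            cert = _certificate(list(g.nodes), list(g.edges))
            if cert not in found:
                found[cert] = MLGraph.from_networkx(g)
    return found


@lru_cache(maxsize=32)
def _connected_cached(n: int, max_nodes: int) -> tuple[tuple[str, ...], tuple]:
    found = _enumerate(n, connected_only=True, max_nodes=max_nodes)
    certs = tuple(sorted(found))
    reps = tuple(tuple(found[c].edges()) for c in certs)
    return certs, reps


def enumerate_connected_mlg(
    n: int, max_nodes: int = MAX_NODES_DEFAULT
) -> list[tuple[str, MLGraph]]:
    """One representative per isomorphism class of connected n-node graphs.

    Deterministic order (sorted certificates).  Odd n yields an empty list
    (odd degrees force an even node count); n above ``max_nodes`` raises.
    """
    certs, reps = _connected_cached(n, max_nodes)
    return [
        (cert, MLGraph(edges=edges, nodes=range(n)))
        for cert, edges in zip(certs, reps)
    ]


def enumerate_all_mlg(
    n: int, max_nodes: int = MAX_NODES_DEFAULT
) -> list[tuple[str, MLGraph]]:
    """Exhaustive possibly-disconnected enumeration (direct, not recursive)."""
    found = _enumerate(n, connected_only=False, max_nodes=max_nodes)
    return [(c, found[c]) for c in sorted(found)]


def _partitions(n: int, max_part: int | None = None) -> Iterator[tuple[int, ...]]:
    if n == 0:
        yield ()
        return
    if max_part is None:
        max_part = n
    for part in range(min(n, max_part), 0, -1):
        for rest in _partitions(n - part, part):
            yield (part,) + rest


def _multichoose(m: int, k: int) -> int:
    """Combinations with replacement: C(m + k - 1, k)."""
    from math import comb

    return comb(m + k - 1, k)


def count_mlg_recursive(n: int, connected_counts: dict[int, int]) -> int:
    """Total (possibly disconnected) count via the partition sum.

    ``connected_counts[k]`` is the number of connected classes on k nodes
    for every k <= n.  For each partition K of n, the product over distinct
    parts k of multichoose(connected_counts[k], m(k, K)) counts the
    unordered multisets of connected pieces realizing K.
    """
    for k in range(1, n + 1):
        if k not in connected_counts:
            raise KeyError(f"connected count for k={k} missing")
    total = 0
    for K in _partitions(n):
        mult: dict[int, int] = {}
        for k in K:
            mult[k] = mult.get(k, 0) + 1
        prod = 1
        for k, m in mult.items():
            prod *= _multichoose(connected_counts[k], m)
            if prod == 0:
                break
        total += prod
    return total


def count_bounds(n: int) -> tuple[float, float]:
    """The printed growth expressions: (two-term lower, 30.061^n upper)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    lower = (LOWER_C1 * LOWER_G1**n + LOWER_C2 * LOWER_G2**n) / n**2.5
    upper = UPPER_GROWTH**n
    return lower, upper


@dataclass(frozen=True)
class CountTable:
    """Connected and total counts per node number with printed bounds."""

    rows: dict[int, dict[str, float]] = field(default_factory=dict)

    def connected(self, n: int) -> int:
        return int(self.rows[n]["connected_count"])

    def total(self, n: int) -> int:
        return int(self.rows[n]["total_count"])


def build_count_table(n_max: int, max_nodes: int = MAX_NODES_DEFAULT) -> CountTable:
    """Counts and bounds for every n from 1 to n_max (enumeration-backed)."""
    connected = {0: 1}
    for k in range(1, n_max + 1):
        connected[k] = len(enumerate_connected_mlg(k, max_nodes=max_nodes))
    rows: dict[int, dict[str, float]] = {}
    for n in range(1, n_max + 1):
        lower, upper = count_bounds(n)
        rows[n] = {
            "connected_count": connected[n],
            "total_count": count_mlg_recursive(n, connected),
            "lower_bound": lower,
            "upper_bound": upper,
        }
    return CountTable(rows=rows)
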