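"""Canonical labeling of small unlabeled graphs.

Mitochondria-like graphs are small (tens of nodes, max degree 3), so a
textbook individualization-refinement search is entirely adequate: colors
are refined by iterated neighbor-multiset recoloring (1-WL); whenever the
partition is not discrete, every vertex of the first non-singleton cell is
individualized in turn and the minimum adjacency code over all branches is
kept.  The certificate is exact - equal certificates if and only if the
unlabeled graphs are isomorphic - which 1-WL hashing alone cannot promise
for regular (e.g. cubic) graphs.

Certificates are computed on the unweighted graph only; edge lengths never
enter.  Disconnected graphs are certified component-wise and the sorted
component codes are joined, so the certificate is invariant under both
relabeling and component reordering.
"""

from __future__ import annotations

from typing import Hashable, Iterable, Sequence

__all__ = ["canonical_code", "certificate"]


def _refine(adj: Sequence[Sequence[int]], colors: tuple[int, ...]) -> tuple[int, ...]:
    """Stable 1-WL color refinement; returns colors as dense ranks."""
    n = len(colors)
    while True:
        sig = [
            (colors[i], tuple(sorted(colors[j] for j in adj[i])))
            for i in range(n)
        ]
        rank = {s: r for r, s in enumerate(sorted(set(sig)))}
        new = tuple(rank[s] for s in sig)
        if new == colors:
            return new
        colors = new


def _code_for_order(adj: Sequence[Sequence[int]], order: Sequence[int]) -> bytes:
    """Upper-triangle adjacency bitstring under the given vertex order."""
    n = len(order)
    pos = {v: i for i, v in enumerate(order)}
    bits = 0
    for u in order:
        for w in adj[u]:
            i, j = pos[u], pos[w]
            if i < j:
                bits |= 1 << (i * n + j)
    return bits.to_bytes((n * n + 7) // 8, "big")


def _search(adj: Sequence[Sequence[int]], colors: tuple[int, ...], best: list[bytes | None]) -> None:
    colors = _refine(adj, colors)
    n = len(colors)
    cells: dict[int, list[int]] = {}
    for v, c in enumerate(colors):
        cells.setdefault(c, []).append(v)
    target = None
    for c in sorted(cells):
        if len(cells[c]) > 1:
            target = cells[c]
            break
    if target is None:
        order = sorted(range(n), key=colors.__getitem__)
        code = _code_for_order(adj, order)
        if best[0] is None or code < best[0]:
            best[0] = code
        return
    for v in target:
        branched = tuple(
            2 * c - (1 if i == v else 0) for i, c in enumerate(colors)
        )
        _search(adj, branched, best)


def canonical_code(n: int, edges: Iterable[tuple[int, int]]) -> bytes:
    """Canonical adjacency code of a (connected or not) graph on vertices 0..n-1."""
    adj: list[list[int]] = [[] for _ in range(n)]
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    if n == 0:
        return b""
    best: list[bytes | None] = [None]
    _search(adj, (0,) * n, best)
    assert best[0] is not None
    return best[0]


def certificate(nodes: Sequence[Hashable], edges: Iterable[tuple[Hashable, Hashable]]) -> str:
    """Isomorphism-invariant text certificate of an arbitrary simple graph.

    Each connected component is canonized separately; component codes are
    sorted so the result is independent of labeling and component order.
    """
    index = {v: i for i, v in enumerate(nodes)}
    n = len(index)
    adj: list[set[int]] = [set() for _ in range(n)]
    for u, v in edges:
        iu, iv = index[u], index[v]
        adj[iu].add(iv)
        adj[iv].add(iu)
    # connected components by BFS
    seen = [False] * n
    comp_codes: list[str] = []
    for start in range(n):
        if seen[start]:
            continue
        comp = [start]
        seen[start] = True
        queue = [start]
        while queue:
            u = queue.pop()
            for w in adj[u]:
                if not seen[w]:
                    seen[w] = True
                    comp.append(w)
                    queue.append(w)
        local = {v: i for i, v in enumerate(sorted(comp))}
        local_edges = [
            (local[u], local[w]) for u in comp for w in adj[u] if u < w
        ]
        code = canonical_code(len(comp), local_edges)
        comp_codes.append(f"{len(comp)}:{code.hex()}")
    return "|".join(sorted(comp_codes)) if comp_codes else "0:"
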