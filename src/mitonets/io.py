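"""File formats: .gnet edge lists, GraphML, plain edge lists, CSV/JSON output.

The ``.gnet`` dialect is the skeleton-graph interchange format produced by
MitoGraph-style segmentation: whitespace- or tab-separated rows
``u v length`` with 0-based integer node indices and tubule lengths in um,
preceded by an optional single-integer header giving the node count
(auto-detected).  Parsing is deliberately tolerant of dialect variation
but strict about structure: self-loops, duplicate edges, non-positive
lengths and out-of-range indices are parse errors naming the line.

Validation of the mitochondria-like degree/planarity rules is *not*
applied automatically - raw skeletons can contain degree-2 artifacts -
pass ``strict=True`` to enforce it.

All writers are deterministic: rows sorted, floats at 9 significant
digits, essential persistence deaths serialized as the token ``inf``.
"""

from __future__ import annotations

import csv
import json
import math
from pathlib import Path
from typing import Literal

import networkx as nx
import pandas as pd

from .enumeration import CountTable
from .graph import MLGraph, validate_mlg
from .kinetics import SteadyStateResults
from .persistence import PersistenceDiagram

__all__ = [
    "read_graph",
    "write_graph",
    "write_diagram",
    "read_diagram",
    "write_distance_matrix",
    "read_distance_matrix",
    "write_count_table",
    "write_fit",
    "ParseError",
]

_LEN = MLGraph.LENGTH_KEY

FMT = Literal["gnet", "graphml", "edgelist"]


class ParseError(ValueError):
    pass


def _fmt_float(x: float) -> str:
    if math.isinf(x):
        return "inf"
    return format(float(x), ".9g")


def _detect_format(path: Path) -> FMT:
    suffix = path.suffix.lower()
    if suffix == ".gnet":
        return "gnet"
    if suffix in (".graphml", ".xml"):
        return "graphml"
    return "edgelist"


def read_graph(path: str | Path, format: FMT | None = None, strict: bool = False) -> MLGraph:
    """Read a graph; ``strict=True`` additionally enforces class membership."""
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt == "graphml":
        g = nx.read_graphml(path)
        h = nx.Graph()
        for v in g.nodes:
            h.add_node(v)
        for u, v, data in g.edges(data=True):
            attrs = {}
            if _LEN in data:
                attrs[_LEN] = float(data[_LEN])
            h.add_edge(u, v, **attrs)
        graph = MLGraph.from_networkx(h)
    else:
        graph = _read_gnet_like(path, with_header=(fmt == "gnet"))
    if strict:
        report = validate_mlg(graph)
        if not report.valid:
            raise ParseError(
                f"{path}: not a mitochondria-like graph (violations: "
                f"{', '.join(report.violations)})"
            )
    return graph


def _read_gnet_like(path: Path, with_header: bool) -> MLGraph:
    lines = path.read_text().splitlines()
    rows: list[tuple[int, list[str]]] = []
    for i, raw in enumerate(lines, start=1):
        s = raw.strip()
        if not s or s.startswith("#"):
            continue
        rows.append((i, s.split()))
    declared: int | None = None
    if with_header and rows and len(rows[0][1]) == 1:
        try:
            declared = int(rows[0][1][0])
        except ValueError as exc:
            raise ParseError(f"{path}:{rows[0][0]}: malformed header") from exc
        rows = rows[1:]
    g = nx.Graph()
    if declared is not None:
        g.add_nodes_from(range(declared))
    for lineno, parts in rows:
        if len(parts) not in (2, 3):
            raise ParseError(f"{path}:{lineno}: malformed row (expected 'u v [length]')")
        try:
            u, v = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer node index") from exc
        if u == v:
            raise ParseError(f"{path}:{lineno}: self-loop")
        if u < 0 or v < 0:
            raise ParseError(f"{path}:{lineno}: negative node index")
        if declared is not None and (u >= declared or v >= declared):
            raise ParseError(f"{path}:{lineno}: node index >= declared count {declared}")
        if g.has_edge(u, v):
            raise ParseError(f"{path}:{lineno}: duplicate edge")
        attrs = {}
        if len(parts) == 3:
            try:
                w = float(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed length") from exc
            if not w > 0:
                raise ParseError(f"{path}:{lineno}: non-positive length")
            attrs[_LEN] = w
        g.add_edge(u, v, **attrs)
    return MLGraph.from_networkx(g)


def write_graph(graph: MLGraph, path: str | Path, format: FMT | None = None) -> None:
    """Write a graph; nodes are relabeled to sorted 0-based indices."""
    path = Path(path)
    fmt = format or _detect_format(path)
    if fmt == "graphml":
        nx.write_graphml(graph.nx, path)
        return
    order = sorted(graph.nodes(), key=repr)
    index = {v: i for i, v in enumerate(order)}
    lines: list[str] = []
    if fmt == "gnet":
        lines.append(str(len(order)))
    edge_rows = sorted(
        (min(index[u], index[v]), max(index[u], index[v]), graph.length(u, v))
        for u, v in graph.edges()
    )
    for u, v, w in edge_rows:
        if w is None:
            lines.append(f"{u}\t{v}")
        else:
            lines.append(f"{u}\t{v}\t{_fmt_float(w)}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def write_diagram(diagram: PersistenceDiagram, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["dim", "birth", "death"])
        for dim, b, d in sorted(diagram.points):
            w.writerow([dim, _fmt_float(b), _fmt_float(d)])


def read_diagram(path: str | Path) -> PersistenceDiagram:
    points = []
    with Path(path).open() as fh:
        for row in csv.DictReader(fh):
            points.append(
                (int(row["dim"]), float(row["birth"]), float(row["death"]))
            )
    return PersistenceDiagram(points=tuple(points))


def write_distance_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    out = matrix.copy()
    out.index.name = "label"
    out.to_csv(path, float_format="%.9g")


def read_distance_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_count_table(table: CountTable, path: str | Path) -> None:
    payload = {
        str(n): {
            "connected_count": int(row["connected_count"]),
            "total_count": int(row["total_count"]),
            "lower_bound": float(row["lower_bound"]),
            "upper_bound": float(row["upper_bound"]),
        }
        for n, row in sorted(table.rows.items())
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def write_fit(results: SteadyStateResults, path: str | Path) -> None:
    f = results.fit
    payload = {
        "model": f.model,
        "r_squared": f.r_squared,
        "slope": f.slope,
        "intercept": f.intercept,
        "quadratic_coef": f.quadratic_coef,
        "a": [f.a0, f.a1, f.a2],
        "b": [f.b0, f.b1, f.b2],
        "pvalues": f.pvalues,
        "conf_int": {k: list(v) for k, v in f.conf_int.items()},
        "converged": f.converged,
        "n_obs": results.n_obs,
        "quadratic_coefficient_raw": results.quadratic_coefficient_raw,
        "quadratic_collapsed": results.quadratic_collapsed,
        "linear_r_squared": results.linear_r_squared,
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
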