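"""Reading and writing graphs, coordinates and result tables.

Two interchange formats are supported: a two-column edge-list CSV
(``source,target`` header optional, labels kept as strings) with an
optional companion coordinate CSV (``node,x,y`` in metres), and GraphML
(which carries coordinates as ``x``/``y`` node attributes).  All
parsers enforce the simple-graph contract — self-loops and duplicate
links are rejected with the offending line named.
"""

from __future__ import annotations

import csv
from pathlib import Path

import networkx as nx
import pandas as pd

from .graph_core import ordered_pair, validate_graph


class GraphFormatError(ValueError):
    """Raised when an input file violates the simple-graph contract."""


def read_graph(
    path: str | Path,
    fmt: str | None = None,
    coords_path: str | Path | None = None,
) -> nx.Graph:
    """Read a simple undirected graph from an edge-list CSV or GraphML.

    The format is inferred from the suffix when *fmt* is None
    (``.graphml`` → GraphML, anything else → edge list).
    """
    path = Path(path)
    if fmt is None:
        fmt = "graphml" if path.suffix.lower() == ".graphml" else "edgelist-csv"
    if fmt == "graphml":
        graph = nx.read_graphml(path)
        graph = nx.Graph(graph)  # collapse any attribute-only wrappers
        _reject_self_loops(graph, path)
    elif fmt == "edgelist-csv":
        graph = _read_edgelist_csv(path)
    else:
        raise ValueError(f"unknown graph format {fmt!r}")
    if coords_path is not None:
        attach_coordinates(graph, coords_path)
    return validate_graph(graph)


def _read_edgelist_csv(path: Path) -> nx.Graph:
    graph = nx.Graph()
    seen: set[tuple] = set()
    with open(path, newline="") as handle:
        rows = list(csv.reader(handle))
    rows = [r for r in rows if r and any(field.strip() for field in r)]
    if not rows:
        raise GraphFormatError(f"{path}: empty edge list")
    start = 1 if [c.strip().lower() for c in rows[0][:2]] == ["source", "target"] else 0
    for lineno, row in enumerate(rows[start:], start=start + 1):
        if len(row) < 2:
            raise GraphFormatError(f"{path}:{lineno}: expected two columns, got {row!r}")
        u, v = row[0].strip(), row[1].strip()
        if u == v:
            raise GraphFormatError(f"{path}:{lineno}: self-loop on {u!r}")
        pair = ordered_pair(u, v)
        if pair in seen:
            raise GraphFormatError(f"{path}:{lineno}: duplicate link {pair}")
        seen.add(pair)
        graph.add_edge(u, v)
    return graph


def _reject_self_loops(graph: nx.Graph, path: Path) -> None:
    loops = list(nx.selfloop_edges(graph))
    if loops:
        raise GraphFormatError(f"{path}: self-loops {loops[:3]}")


def attach_coordinates(graph: nx.Graph, coords_path: str | Path) -> nx.Graph:
    """Attach metric x/y coordinates from a ``node,x,y`` CSV."""
    table = pd.read_csv(coords_path, dtype={0: str})
    table.columns = [c.strip().lower() for c in table.columns]
    for col in ("node", "x", "y"):
        if col not in table.columns:
            raise GraphFormatError(f"{coords_path}: missing column {col!r}")
    for _, row in table.iterrows():
        node = row["node"]
        if node not in graph:
            raise GraphFormatError(f"{coords_path}: unknown node {node!r}")
        graph.nodes[node]["x"] = float(row["x"])
        graph.nodes[node]["y"] = float(row["y"])
    return graph


def write_graph(graph: nx.Graph, path: str | Path, fmt: str | None = None) -> None:
    """Write a graph as edge-list CSV or GraphML (suffix-inferred)."""
    path = Path(path)
    if fmt is None:
        fmt = "graphml" if path.suffix.lower() == ".graphml" else "edgelist-csv"
    validate_graph(graph)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "edgelist-csv":
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle)
            writer.writerow(["source", "target"])
            for u, v in sorted(ordered_pair(u, v) for u, v in graph.edges):
                writer.writerow([u, v])
    else:
        raise ValueError(f"unknown graph format {fmt!r}")


def write_coordinates(graph: nx.Graph, path: str | Path) -> None:
    """Write node coordinates as a ``node,x,y`` CSV."""
    records = []
    for node in sorted(graph.nodes, key=str):
        data = graph.nodes[node]
        if "x" not in data or "y" not in data:
            raise ValueError(f"node {node!r} has no coordinates")
        records.append({"node": node, "x": data["x"], "y": data["y"]})
    pd.DataFrame.from_records(records).to_csv(path, index=False)


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as CSV with a header and stable column order."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty result table")
    table.to_csv(path, index=False)
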