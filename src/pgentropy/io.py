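"""Readers and writers for the plain-text graph formats.

Three formats are supported:

* edge list — one ``u v [length]`` per line, whitespace- or
  comma-separated, ``#`` comments; an optional third column (a geometric
  edge length) is tolerated on input but geometry itself always comes
  from a coordinate table, the only way to know non-edge lengths too;
* adjacency matrix — a square CSV of 0/1 entries;
* coordinates — one ``id x y z`` row per vertex (TSV/CSV/whitespace).

Vertex ids may be 0-based in input files; they are normalized to the
package's 1-based convention when the smallest id seen is 0.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .graph import Graph, pairwise_distances

__all__ = [
    "read_edge_list",
    "read_adjacency",
    "read_coordinates",
    "write_edge_list",
    "write_coordinates",
    "attach_geometry",
]


def _tokens(line: str) -> list[str]:
    return line.replace(",", " ").split()


def read_edge_list(path: str | Path, n: int | None = None) -> Graph:
    """Read a graph from an edge-list file (no geometry).

    ``n`` fixes the vertex count; when omitted it is the largest id seen.
    """
    raw_edges: list[tuple[int, int]] = []
    max_id, min_id = 0, None
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line.startswith("# n="):  # header written by write_edge_list
            if n is None:
                n = int(line.removeprefix("# n="))
            continue
        if not line or line.startswith("#"):
            continue
        fields = _tokens(line)
        if len(fields) < 2:
            raise ValueError(f"malformed edge line: {line!r}")
        u, v = int(fields[0]), int(fields[1])
        raw_edges.append((u, v))
        max_id = max(max_id, u, v)
        min_id = min(u, v) if min_id is None else min(min_id, u, v)
    if min_id == 0:  # 0-based input: shift to 1-based
        raw_edges = [(u + 1, v + 1) for u, v in raw_edges]
        max_id += 1
    return Graph(n=n if n is not None else max_id, edges=frozenset(raw_edges))


def read_adjacency(path: str | Path) -> Graph:
    """Read a graph from a square 0/1 adjacency-matrix CSV."""
    rows = [
        _tokens(line)
        for line in Path(path).read_text().splitlines()
        if line.strip() and not line.startswith("#")
    ]
    a = np.array([[int(float(x)) for x in row] for row in rows])
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"adjacency matrix must be square, got {a.shape}")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency matrix must be symmetric")
    n = a.shape[0]
    edges = [(i + 1, j + 1) for i in range(n) for j in range(i + 1, n) if a[i, j]]
    return Graph(n=n, edges=frozenset(edges))


def read_coordinates(path: str | Path) -> np.ndarray:
    """Read a per-vertex coordinate table (id, x, y, z) into an (n, 3) array."""
    entries: dict[int, tuple[float, ...]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = _tokens(line)
        entries[int(fields[0])] = tuple(float(x) for x in fields[1:])
    if not entries:
        raise ValueError(f"no coordinates found in {path}")
    ids = sorted(entries)
    offset = 1 if ids[0] == 0 else 0
    n = ids[-1] + offset
    dims = {len(v) for v in entries.values()}
    if len(dims) != 1:
        raise ValueError("inconsistent coordinate dimensionality")
    out = np.full((n, dims.pop()), np.nan)
    for vid, xyz in entries.items():
        out[vid + offset - 1] = xyz
    if np.isnan(out).any():
        missing = np.where(np.isnan(out).any(axis=1))[0] + 1
        raise ValueError(f"missing coordinates for vertices {list(missing)}")
    return out


def attach_geometry(graph: Graph, points: np.ndarray) -> Graph:
    """Return the same graph with geometry derived from vertex coordinates."""
    if points.shape[0] != graph.n:
        raise ValueError(
            f"coordinate table has {points.shape[0]} rows for a {graph.n}-vertex graph"
        )
    return Graph(n=graph.n, edges=graph.edges, geometry=pairwise_distances(points))


def write_edge_list(graph: Graph, path: str | Path) -> None:
    """Write the canonical edge list: sorted endpoint pairs, one per line."""
    lines = [f"{u} {v}" for u, v in graph.sorted_edges()]
    Path(path).write_text(f"# n={graph.n}\n" + "\n".join(lines) + "\n")


def write_coordinates(points: np.ndarray, path: str | Path) -> None:
    """Write a coordinate table as TSV rows of id, x, y, z."""
    lines = [
        "\t".join([str(i + 1)] + [f"{x:.6f}" for x in row])
        for i, row in enumerate(np.atleast_2d(points))
    ]
    Path(path).write_text("\n".join(lines) + "\n")
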