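"""Immutable simple undirected graphs with optional geometry.

Vertices are the integers ``1..n`` (matching the v_1..v_n convention used
throughout the protein-graph literature).  A :class:`Graph` may carry a
*geometry*: a full symmetric table of pairwise inter-vertex distances, in
the units of the source coordinates (angstroms for protein graphs).  Hop
distance (shortest-path length, :func:`bfs_distances`) and geometric
distance (:meth:`Graph.length`) are deliberately kept distinct.

Graphs are values: edge-adjustment operations return new graphs instead of
mutating, so entropy triples can be computed side-effect-free.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterator, Mapping, Sequence

import numpy as np

Edge = tuple[int, int]

__all__ = [
    "Graph",
    "NeighborhoodProfile",
    "bfs_distances",
    "neighborhood_profile",
    "is_connected",
    "density",
]


def _normalize_edge(u: int, v: int) -> Edge:
    if u == v:
        raise ValueError(f"self-loop at vertex {u} is not allowed")
    return (u, v) if u < v else (v, u)


@dataclass(frozen=True)
class Graph:
    """A simple undirected graph on vertices ``1..n``.

    Parameters
    ----------
    n
        Number of vertices (positive).
    edges
        Unordered distinct vertex pairs; normalized to sorted tuples.
    geometry
        Optional ``(n, n)`` symmetric matrix of pairwise distances with a
        zero diagonal and strictly positive off-diagonal entries.  Excluded
        from equality and hashing: two graphs are equal iff they have the
        same vertex count and edge set.
    """

    n: int
    edges: frozenset[Edge]
    geometry: np.ndarray | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("graph needs at least one vertex")
        normalized = frozenset(_normalize_edge(u, v) for u, v in self.edges)
        for u, v in normalized:
            if not (1 <= u <= self.n and 1 <= v <= self.n):
                raise ValueError(f"edge ({u}, {v}) has an endpoint outside 1..{self.n}")
        object.__setattr__(self, "edges", normalized)
        if self.geometry is not None:
            geo = np.asarray(self.geometry, dtype=float)
            if geo.shape != (self.n, self.n):
                raise ValueError(f"geometry must be {self.n}x{self.n}, got {geo.shape}")
            if not np.allclose(geo, geo.T, atol=1e-9):
                raise ValueError("geometry must be symmetric")
            if not np.allclose(np.diag(geo), 0.0, atol=1e-9):
                raise ValueError("geometry diagonal must be zero")
            off = geo[~np.eye(self.n, dtype=bool)]
            if off.size and off.min() <= 0:
                raise ValueError("off-diagonal geometric distances must be positive")
            geo = geo.copy()
            geo.setflags(write=False)
            object.__setattr__(self, "geometry", geo)

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        n: int,
        edges: Sequence[tuple[int, int]],
        *,
        points: np.ndarray | Sequence[Sequence[float]] | None = None,
        geometry: np.ndarray | None = None,
    ) -> "Graph":
        """Build a graph, optionally deriving geometry from coordinates.

        ``points`` is an ``(n, d)`` array of vertex coordinates (row ``i``
        is vertex ``i+1``); the geometry table is the matrix of pairwise
        Euclidean distances.
        """
        if points is not None:
            if geometry is not None:
                raise ValueError("give either points or geometry, not both")
            geometry = pairwise_distances(points)
        return cls(n=n, edges=frozenset(tuple(e) for e in edges), geometry=geometry)

    @classmethod
    def from_points(cls, points: np.ndarray, threshold: float) -> "Graph":
        """Distance-threshold graph: edge iff pairwise distance <= threshold."""
        geo = pairwise_distances(points)
        n = geo.shape[0]
        edges = [(i + 1, j + 1) for i, j in combinations(range(n), 2) if geo[i, j] <= threshold]
        return cls(n=n, edges=frozenset(edges), geometry=geo)

    # -- basic queries ----------------------------------------------------

    @property
    def vertices(self) -> range:
        return range(1, self.n + 1)

    @property
    def m(self) -> int:
        """Edge count |E|."""
        return len(self.edges)

    def has_edge(self, u: int, v: int) -> bool:
        return _normalize_edge(u, v) in self.edges

    def degree(self, u: int) -> int:
        return len(self.neighbors(u))

    def neighbors(self, u: int) -> tuple[int, ...]:
        return self._adjacency().get(u, ())

    def non_edges(self) -> Iterator[Edge]:
        """Unordered vertex pairs not joined by an edge, in lexicographic order."""
        for pair in combinations(self.vertices, 2):
            if pair not in self.edges:
                yield pair

    def is_complete(self) -> bool:
        return self.m == self.n * (self.n - 1) // 2

    def length(self, u: int, v: int) -> float:
        """Geometric distance between two vertices (requires geometry)."""
        if self.geometry is None:
            raise ValueError("graph has no geometry")
        return float(self.geometry[u - 1, v - 1])

    def _adjacency(self) -> dict[int, tuple[int, ...]]:
        try:
            return object.__getattribute__(self, "_adj_cache")
        except AttributeError:
            adj: dict[int, list[int]] = {v: [] for v in self.vertices}
            for u, v in self.edges:
                adj[u].append(v)
                adj[v].append(u)
            frozen = {v: tuple(sorted(nb)) for v, nb in adj.items()}
            object.__setattr__(self, "_adj_cache", frozen)
            return frozen

    # -- edge editing (returns new graphs) --------------------------------

    def add_edge(self, u: int, v: int) -> "Graph":
        e = _normalize_edge(u, v)
        if e in self.edges:
            raise ValueError(f"edge {e} already present")
        return Graph(self.n, self.edges | {e}, self.geometry)

    def remove_edge(self, u: int, v: int) -> "Graph":
        e = _normalize_edge(u, v)
        if e not in self.edges:
            raise ValueError(f"edge {e} not present")
        return Graph(self.n, self.edges - {e}, self.geometry)

    # -- interop ----------------------------------------------------------

    def to_networkx(self):
        """Export as a :class:`networkx.Graph` (vertex labels preserved)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.vertices)
        g.add_edges_from(self.edges)
        return g

    def sorted_edges(self) -> list[Edge]:
        return sorted(self.edges)


@dataclass(frozen=True)
class NeighborhoodProfile:
    """Sizes of the k-spheres around one vertex.

    ``sphere_sizes[i-1]`` is ``|N_i(u)|``, the number of vertices at
    shortest-path distance exactly ``i`` from ``u``, for ``i`` up to the
    eccentricity of ``u``.  For a connected graph the sizes sum to ``n-1``.
    """

    vertex: int
    sphere_sizes: tuple[int, ...]

    @property
    def eccentricity(self) -> int:
        return len(self.sphere_sizes)


def pairwise_distances(points: np.ndarray | Sequence[Sequence[float]]) -> np.ndarray:
    """Full symmetric Euclidean distance table for a point set."""
    from scipy.spatial.distance import pdist, squareform

    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 2:
        return np.zeros((pts.shape[0], pts.shape[0]))
    return squareform(pdist(pts))


def bfs_distances(graph: Graph, u: int) -> dict[int, int]:
    """Shortest-path hop distances from ``u`` to every reachable vertex.

    ``d(u, u) = 0``; vertices in other components are absent from the map.
    """
    if not (1 <= u <= graph.n):
        raise ValueError(f"unknown vertex id {u} (graph has vertices 1..{graph.n})")
    adj = graph._adjacency()
    dist = {u: 0}
    queue = deque([u])
    while queue:
        w = queue.popleft()
        dw = dist[w]
        for nb in adj[w]:
            if nb not in dist:
                dist[nb] = dw + 1
                queue.append(nb)
    return dist


def neighborhood_profile(graph: Graph, u: int) -> NeighborhoodProfile:
    """Count the k-distance neighborhoods (k-spheres) around ``u``.

    On a disconnected graph the profile covers only ``u``'s component.
    """
    dist = bfs_distances(graph, u)
    ecc = max(dist.values())
    sizes = [0] * ecc
    for v, d in dist.items():
        if d > 0:
            sizes[d - 1] += 1
    return NeighborhoodProfile(vertex=u, sphere_sizes=tuple(sizes))


def is_connected(graph: Graph) -> bool:
    """True iff a single component spans all vertices."""
    return len(bfs_distances(graph, 1)) == graph.n


def density(graph: Graph) -> float:
    """Graph density 2|E| / (|V| (|V|-1)), in [0, 1]."""
    if graph.n < 2:
        raise ValueError("density requires at least two vertices")
    return 2.0 * graph.m / (graph.n * (graph.n - 1))
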