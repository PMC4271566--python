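"""Reference graphs and seeded synthetic generators.

The named fixtures are the small worked examples that recur throughout
the method's derivation: the 4-vertex cycle, clique, path and star; X,
the clique on four vertices with one edge deleted; and Y, the 5-vertex
crambin-derived protein graph with edges {(1,2),(1,3),(1,4),(2,3),(3,5)}.
Each carries a canonical planar embedding so the geometric adjustment
operations have lengths to rank.

The synthetic generators supply test substrates: seeded random geometric
graphs (a stand-in for real protein graphs) and an exhaustive stream of
all connected labeled graphs on up to six vertices (the oracle substrate
for property tests).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterator

import numpy as np

from .graph import Graph

__all__ = ["NamedFixture", "named", "fixture_names", "random_geometric", "all_connected_graphs"]


@dataclass(frozen=True)
class NamedFixture:
    name: str
    graph: Graph
    provenance: str
    #: canonical embedding used to derive the geometry (row i = vertex i+1)
    points: np.ndarray | None = None


def _unit_square() -> np.ndarray:
    return np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


def _fixture_table() -> dict[str, NamedFixture]:
    square = _unit_square()
    line = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]])
    star = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [-1.0, 0.0]])
    y_pts = np.array(
        [[0.0, 0.0], [1.0, 0.0], [0.5, 0.9], [-1.0, 0.1], [0.6, 1.9]]
    )
    table = {
        "C4": NamedFixture(
            "C4",
            Graph.from_edges(4, [(1, 2), (2, 3), (3, 4), (1, 4)], points=square),
            "cycle of four vertices (unit-square embedding)",
            points=square,
        ),
        "K4": NamedFixture(
            "K4",
            Graph.from_edges(4, list(combinations(range(1, 5), 2)), points=square),
            "clique of four vertices (unit-square embedding)",
            points=square,
        ),
        "P4": NamedFixture(
            "P4",
            Graph.from_edges(4, [(1, 2), (2, 3), (3, 4)], points=line),
            "path of four vertices (unit-spaced line embedding)",
            points=line,
        ),
        "S4": NamedFixture(
            "S4",
            Graph.from_edges(4, [(1, 2), (1, 3), (1, 4)], points=star),
            "star of four vertices: center v1, three leaves",
            points=star,
        ),
        "X": NamedFixture(
            "X",
            Graph.from_edges(4, [(1, 2), (1, 3), (1, 4), (2, 3), (3, 4)], points=square),
            "K4 with edge (2,4) removed",
            points=square,
        ),
        "Y": NamedFixture(
            "Y",
            Graph.from_edges(5, [(1, 2), (1, 3), (1, 4), (2, 3), (3, 5)], points=y_pts),
            "5-vertex crambin protein graph",
            points=y_pts,
        ),
    }
    return table


def fixture_names() -> tuple[str, ...]:
    return tuple(sorted(_fixture_table()))


def named(name: str) -> NamedFixture:
    """Fetch a named reference graph; raises with the valid names listed."""
    table = _fixture_table()
    try:
        return table[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; valid names: {', '.join(sorted(table))}"
        ) from None


def random_geometric(n: int, radius_multiplier: float, seed: int) -> Graph:
    """Seeded random geometric graph in the unit cube.

    ``n`` points are drawn uniformly; the distance-threshold edge rule
    joins pairs at distance at most ``radius_multiplier`` times the mean
    pairwise distance (so multiplier 1.0 mimics the AVG rule used for
    protein graphs).  Identical seeds give identical graphs.
    """
    if n < 2:
        raise ValueError("need at least two vertices")
    rng = np.random.default_rng(seed)
    points = rng.random((n, 3))
    from .graph import pairwise_distances

    geo = pairwise_distances(points)
    mean_dist = geo[np.triu_indices(n, k=1)].mean()
    threshold = radius_multiplier * mean_dist
    edges = [
        (i + 1, j + 1) for i, j in combinations(range(n), 2) if geo[i, j] <= threshold
    ]
    return Graph(n=n, edges=frozenset(edges), geometry=geo)


def all_connected_graphs(n: int) -> Iterator[Graph]:
    """Every connected simple graph on n labeled vertices, exactly once.

    Guarded at n <= 6 (26,704 graphs); the stream exists to back
    exhaustive oracle checks, not open-ended enumeration.
    """
    if n > 6:
        raise ValueError("exhaustive enumeration is guarded at n <= 6")
    if n < 1:
        raise ValueError("need at least one vertex")
    pairs = list(combinations(range(n), 2))
    for mask in range(1 << len(pairs)):
        chosen = [pairs[i] for i in range(len(pairs)) if mask >> i & 1]
        if _connected_bitset(n, chosen):
            yield Graph(n=n, edges=frozenset((u + 1, v + 1) for u, v in chosen))


def _connected_bitset(n: int, edges: list[tuple[int, int]]) -> bool:
    if n == 1:
        return True
    if len(edges) < n - 1:
        return False
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    components = n
    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            components -= 1
    return components == 1
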