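"""Independent brute-force oracles for the test suite.

Everything here deliberately avoids the package's own traversal code:
shortest-path distances come from boolean adjacency-matrix powers, and
the entropy formulas are evaluated by literal summation over those
distances.  The oracles only need to be correct, not fast.
"""

from __future__ import annotations

import math

import numpy as np

from pgentropy.graph import Graph


def adjacency_matrix(graph: Graph) -> np.ndarray:
    a = np.zeros((graph.n, graph.n), dtype=bool)
    for u, v in graph.edges:
        a[u - 1, v - 1] = a[v - 1, u - 1] = True
    return a


def matrix_power_distances(graph: Graph) -> np.ndarray:
    """All-pairs hop distances via reachability under repeated A-multiplication.

    Entry (i, j) is the smallest k with (A^k)[i, j] != 0, 0 on the diagonal,
    and -1 for unreachable pairs.
    """
    n = graph.n
    a = adjacency_matrix(graph)
    dist = np.full((n, n), -1, dtype=int)
    np.fill_diagonal(dist, 0)
    reach = a.copy()
    for k in range(1, n):
        newly = reach & (dist == -1)
        dist[newly] = k
        if (dist != -1).all():
            break
        reach = reach @ a
    return dist


def brute_impact(graph: Graph, u: int) -> float:
    """Literal Formula-2 summation over explicit k-sphere counts."""
    n = graph.n
    dist = matrix_power_distances(graph)[u - 1]
    if (dist == -1).any():
        raise ValueError("disconnected")
    total = 0.0
    for i in range(1, n):
        sphere = int((dist == i).sum())
        total += sphere / (n - i + 1)
    return total


def brute_extended_entropy(graph: Graph) -> float:
    f = [brute_impact(graph, u) for u in graph.vertices]
    fv = sum(f)
    return -sum((x / fv) * math.log2(x / fv) for x in f)


def brute_degree_entropy(graph: Graph) -> float:
    degs = adjacency_matrix(graph).sum(axis=1)
    total = degs.sum()
    return -sum(d / total * math.log2(d / total) for d in degs if d)


def relabel(graph: Graph, perm: dict[int, int]) -> Graph:
    """Apply a vertex permutation {old: new}, carrying geometry along."""
    geometry = None
    if graph.geometry is not None:
        idx = np.argsort([perm[v] for v in graph.vertices])
        geometry = graph.geometry[np.ix_(idx, idx)]
    edges = frozenset((perm[u], perm[v]) for u, v in graph.edges)
    return Graph(n=graph.n, edges=edges, geometry=geometry)
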