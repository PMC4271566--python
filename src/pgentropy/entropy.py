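"""Graph entropies: classic degree entropy and the extended k-sphere entropy.

Two Shannon entropies over vertex distributions, both in bits:

* classic entropy ``I(G)``: probabilities proportional to vertex degree,
  ``p_i = deg(v_i) / sum_j deg(v_j)``;
* extended entropy ``I'(G)``: probabilities proportional to the *impact*

  .. math:: f(u) = \\sum_{i=1}^{ecc(u)} \\frac{|N_i(u)|}{n - i + 1},

  where ``N_i(u)`` is the i-sphere of ``u`` — every other vertex contributes,
  with nearer vertices weighted more heavily.  The distribution is
  ``q_i = f(v_i) / f(V)`` with ``f(V) = sum_v f(v)``.

The extended entropy is only defined on connected graphs; disconnected input
raises :class:`DisconnectedGraphError`, which carries the ``NaC``
("not a connected graph") label so report writers can print the sentinel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .graph import Graph, bfs_distances, density

__all__ = [
    "DisconnectedGraphError",
    "EntropyResult",
    "degree_entropy",
    "impact",
    "impacts",
    "q_distribution",
    "extended_entropy",
    "analyze",
]

NAC = "NaC"


class DisconnectedGraphError(ValueError):
    """Extended entropy is undefined on a disconnected graph."""

    label = NAC


@dataclass(frozen=True)
class EntropyResult:
    """Per-vertex impact scores and distribution plus both entropies (bits).

    ``classic_entropy`` is ``None`` for an edgeless graph, where the degree
    distribution is undefined.
    """

    f_values: dict[int, float]
    q_values: dict[int, float]
    extended_entropy: float
    classic_entropy: float | None


def _shannon(probabilities) -> float:
    return -sum(p * math.log2(p) for p in probabilities if p > 0.0)


def degree_entropy(graph: Graph) -> float:
    """Classic graph entropy: Shannon entropy of the degree distribution.

    Vertices of degree zero carry probability zero and contribute nothing
    (the usual 0 log 0 = 0 convention).
    """
    degrees = [graph.degree(v) for v in graph.vertices]
    total = sum(degrees)
    if total == 0:
        raise ValueError("degree entropy is undefined on an edgeless graph")
    return _shannon(d / total for d in degrees)


def impact(graph: Graph, u: int) -> float:
    """Impact score f(u) = sum_i |N_i(u)| / (n - i + 1).

    The sum runs over i = 1 .. ecc(u); the denominator is largest for the
    1-sphere, so a vertex whose neighbors are spread across distant spheres
    accumulates a larger score than one with everything adjacent.
    """
    if graph.n < 2:
        raise ValueError("impact requires at least two vertices")
    dist = bfs_distances(graph, u)
    if len(dist) != graph.n:
        raise DisconnectedGraphError(
            f"vertex {u} does not reach every vertex: extended entropy is {NAC}"
        )
    n = graph.n
    score = 0.0
    for d in dist.values():
        if d > 0:
            score += 1.0 / (n - d + 1)
    return score


def impacts(graph: Graph) -> dict[int, float]:
    """Impact score for every vertex (connected graphs only)."""
    return {v: impact(graph, v) for v in graph.vertices}


def q_distribution(graph: Graph) -> dict[int, float]:
    """Normalized impact distribution q_i = f(v_i) / f(V); sums to 1."""
    f = impacts(graph)
    total = sum(f.values())
    return {v: fv / total for v, fv in f.items()}


def extended_entropy(graph: Graph) -> float:
    """Extended entropy I'(G): Shannon entropy of the q-distribution, in bits."""
    return _shannon(q_distribution(graph).values())


def analyze(graph: Graph) -> EntropyResult:
    """Impacts, q-distribution and both entropies in one pass."""
    f = impacts(graph)
    total = sum(f.values())
    q = {v: fv / total for v, fv in f.items()}
    classic = degree_entropy(graph) if graph.m > 0 else None
    return EntropyResult(
        f_values=f,
        q_values=q,
        extended_entropy=_shannon(q.values()),
        classic_entropy=classic,
    )


def summary(graph: Graph) -> dict[str, float | None]:
    """Convenience: classic entropy, extended entropy and density."""
    result = analyze(graph)
    return {
        "classic_entropy": result.classic_entropy,
        "extended_entropy": result.extended_entropy,
        "density": density(graph),
    }
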