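"""Entropy-guided edge adjustment for geometric graphs.

Given a connected graph with geometry, write ``x = I'(G)``,
``y = I'(G - e)`` where ``G - e`` removes the geometrically longest edge,
and ``z = I'(G + e)`` where ``G + e`` adds the geometrically shortest
non-edge.  The ordering of the triple decides the action:

* case 1 — removing the longest edge disconnects the graph; ``y`` is the
  ``NaC`` sentinel and no further removal is attempted;
* case 2 — ``z > x > y``: adding the edge makes the graph more stable;
* case 3 — ``x > z > y``: the graph is stable as it is;
* case 4 — ``y > x > z``: removing the edge makes the graph more stable.

Orderings outside these four (for example ``z > y > x``, or exact ties)
are classified ``uncovered`` and left untouched.  On a complete graph
``z`` is unavailable (the report sentinel is ``NaN``) and the decision is
made from ``x`` and ``y`` alone.

The density sweep (:func:`sweep`) cumulatively removes the k longest
edges, or adds the k shortest non-edges, ranked once from the input
graph, tracking extended entropy and density at every offset.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .entropy import DisconnectedGraphError, extended_entropy
from .graph import Edge, Graph, density, is_connected

__all__ = [
    "Action",
    "AdjustmentDecision",
    "SweepRow",
    "longest_edge",
    "shortest_nonedge",
    "evaluate",
    "iterate",
    "sweep",
]


class Action(str, Enum):
    NONE = "none"
    ADD = "add"
    REMOVE = "remove"
    STOP_DISCONNECTED = "stop-disconnected"


@dataclass(frozen=True)
class AdjustmentDecision:
    """One evaluation of the edge-adjustment rule.

    ``y`` is ``None`` when removal disconnects the graph (reported NaC);
    ``z`` is ``None`` when the graph is complete (reported NaN).
    """

    x: float
    y: float | None
    z: float | None
    case_label: str
    action: Action
    removed_edge: Edge | None = None
    added_edge: Edge | None = None


@dataclass(frozen=True)
class SweepRow:
    """One offset of the +/-ke sweep.

    status is "ok" (entropy set), "NaC" (graph disconnected) or "NaN"
    (no candidate edge left to add or remove at this offset).
    """

    offset: int
    entropy: float | None
    status: str
    density: float | None


def _require_geometry(graph: Graph) -> None:
    if graph.geometry is None:
        raise ValueError("operation requires a graph with geometry")


def longest_edge(graph: Graph) -> Edge:
    """The existing edge with maximal geometric length.

    Ties break to the lexicographically smallest endpoint pair.
    """
    _require_geometry(graph)
    if graph.m == 0:
        raise ValueError("graph has no edges")
    return min(graph.edges, key=lambda e: (-graph.length(*e), e))


def shortest_nonedge(graph: Graph) -> Edge:
    """The non-adjacent pair with minimal geometric length.

    Ties break to the lexicographically smallest pair.  A complete graph
    has no candidate; report writers print the NaN sentinel in that case.
    """
    _require_geometry(graph)
    candidates = list(graph.non_edges())
    if not candidates:
        raise ValueError("graph is complete: no non-edge to add (NaN)")
    return min(candidates, key=lambda e: (graph.length(*e), e))


def evaluate(graph: Graph) -> AdjustmentDecision:
    """Classify the (x, y, z) entropy triple and recommend an action."""
    _require_geometry(graph)
    if not is_connected(graph):
        raise DisconnectedGraphError("cannot evaluate a disconnected graph")
    x = extended_entropy(graph)

    e_rm = longest_edge(graph)
    reduced = graph.remove_edge(*e_rm)
    y: float | None
    if is_connected(reduced):
        y = extended_entropy(reduced)
    else:
        y = None

    e_add: Edge | None
    z: float | None
    if graph.is_complete():
        e_add, z = None, None
    else:
        e_add = shortest_nonedge(graph)
        z = extended_entropy(graph.add_edge(*e_add))

    if y is None:
        # Case 1: the longest edge is a bridge; the graph cannot shed it.
        return AdjustmentDecision(x, None, z, "case1", Action.STOP_DISCONNECTED,
                                  removed_edge=e_rm, added_edge=e_add)
    if z is None:
        # Complete graph: only the remove direction exists.
        if y > x:
            return AdjustmentDecision(x, y, None, "case4", Action.REMOVE,
                                      removed_edge=e_rm)
        if x > y:
            return AdjustmentDecision(x, y, None, "case3", Action.NONE,
                                      removed_edge=e_rm)
        return AdjustmentDecision(x, y, None, "uncovered", Action.NONE,
                                  removed_edge=e_rm)
    if z > x > y:
        return AdjustmentDecision(x, y, z, "case2", Action.ADD,
                                  removed_edge=e_rm, added_edge=e_add)
    if x > z > y:
        return AdjustmentDecision(x, y, z, "case3", Action.NONE,
                                  removed_edge=e_rm, added_edge=e_add)
    if y > x > z:
        return AdjustmentDecision(x, y, z, "case4", Action.REMOVE,
                                  removed_edge=e_rm, added_edge=e_add)
    return AdjustmentDecision(x, y, z, "uncovered", Action.NONE,
                              removed_edge=e_rm, added_edge=e_add)


def iterate(graph: Graph, max_steps: int) -> tuple[Graph, list[AdjustmentDecision]]:
    """Repeatedly apply :func:`evaluate`, performing add/remove actions.

    Stops at case 1, case 3, an uncovered ordering, or after ``max_steps``
    decisions.  Returns the final graph and the decision trail.
    """
    trail: list[AdjustmentDecision] = []
    current = graph
    for _ in range(max_steps):
        decision = evaluate(current)
        trail.append(decision)
        if decision.action is Action.ADD:
            current = current.add_edge(*decision.added_edge)
        elif decision.action is Action.REMOVE:
            current = current.remove_edge(*decision.removed_edge)
        else:
            break
    return current, trail


def _ranked_candidates(graph: Graph) -> tuple[list[Edge], list[Edge]]:
    """Removal candidates by descending length, addition by ascending."""
    removals = sorted(graph.edges, key=lambda e: (-graph.length(*e), e))
    additions = sorted(graph.non_edges(), key=lambda e: (graph.length(*e), e))
    return removals, additions


def sweep(graph: Graph, k_max: int) -> list[SweepRow]:
    """The +/-ke protocol: entropy and density across edge offsets.

    Offsets run from ``-k_max`` (the k longest edges removed) through 0
    (the input graph) to ``+k_max`` (the k shortest non-edges added).
    Candidates are ranked once from the input graph, so the rows are
    cumulative and path-independent.  When fewer than k candidates exist
    the row carries the NaN status and the density of the exhausted graph;
    a disconnected intermediate carries NaC.
    """
    _require_geometry(graph)
    if k_max < 1:
        raise ValueError("k_max must be a positive integer")
    removals, additions = _ranked_candidates(graph)

    def row(offset: int, g: Graph, exhausted: bool) -> SweepRow:
        dens = density(g)
        if exhausted:
            return SweepRow(offset, None, "NaN", dens)
        if not is_connected(g):
            return SweepRow(offset, None, "NaC", dens)
        return SweepRow(offset, extended_entropy(g), "ok", dens)

    rows: list[SweepRow] = []
    current = graph
    for k in range(1, k_max + 1):  # leftward: -1e, -2e, ...
        if k <= len(removals):
            current = current.remove_edge(*removals[k - 1])
            rows.insert(0, row(-k, current, exhausted=False))
        else:
            rows.insert(0, row(-k, current, exhausted=True))
    rows.append(row(0, graph, exhausted=False))
    current = graph
    for k in range(1, k_max + 1):  # rightward: +1e, +2e, ...
        if k <= len(additions):
            current = current.add_edge(*additions[k - 1])
            rows.append(row(k, current, exhausted=False))
        else:
            rows.append(row(k, current, exhausted=True))
    return rows
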