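"""Layered top-to-bottom layout with side-by-side edge lanes.

The drawing flows from top to bottom, matching the direction of the
reaction relationships wherever possible.  Cycles make a fully
consistent downward flow impossible; a small set of *feedback* edges is
chosen with the greedy Eades linear-arrangement heuristic and those
edges point upward.  Layers come from longest-path layering of the
acyclic remainder; horizontal positions are refined by barycenter
sweeps (kept only when they do not increase the straight-line crossing
count) followed by a seeded force relaxation within layers and a final
overlap-removal pass that restores the minimum node separation.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import networkx as nx

from .model import EdgeGroup, PathwayGraph

__all__ = [
    "LayoutParams",
    "LayerAssignment",
    "LanePolyline",
    "LayoutResult",
    "assign_layers",
    "refine_positions",
    "crossing_count",
    "edge_geometry",
    "compute_layout",
]


@dataclass(frozen=True)
class LayoutParams:
    """Geometry knobs, in abstract units (y grows downward, SVG-style)."""

    layer_gap: float = 60.0
    min_separation: float = 40.0
    lane_spacing: float = 6.0
    barycenter_sweeps: int = 4
    force_iterations: int = 30
    force_step: float = 0.3
    jitter: float = 0.5


@dataclass
class LayerAssignment:
    layers: dict[str, int]
    feedback_edges: frozenset[tuple[str, str]]


@dataclass(frozen=True)
class LanePolyline:
    """One drawable lane of an edge group.

    ``points`` run from pair[0] to pair[1]; ``tips`` name the polyline
    ends carrying a sharp tip ("start", "end", or both for a pathway
    with edges in both directions).
    """

    pathway_id: str
    direction: str
    points: tuple[tuple[float, float], ...]
    offset: float
    tips: tuple[str, ...]


@dataclass
class LayoutResult:
    positions: dict[str, tuple[float, float]]
    lanes: dict[tuple[str, str], tuple[LanePolyline, ...]]
    layers: dict[str, int] = field(default_factory=dict)
    feedback_edges: frozenset[tuple[str, str]] = frozenset()

    def to_dict(self) -> dict:
        return {
            "positions": {k: list(v) for k, v in sorted(self.positions.items())},
            "layers": dict(sorted(self.layers.items())),
            "feedback_edges": sorted(list(e) for e in self.feedback_edges),
            "lanes": {
                "|".join(pair): [asdict(lane) for lane in lanes]
                for pair, lanes in sorted(self.lanes.items())
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"


# ---------------------------------------------------------------------------
# layer assignment


def _arcs(graph: PathwayGraph) -> list[tuple[str, str]]:
    return sorted({(e.source, e.target) for e in graph.edges})


def _eades_order(nodes: Sequence[str], arcs: Sequence[tuple[str, str]]) -> list[str]:
    """Greedy linear arrangement minimizing backward arcs (heuristically).

    Repeatedly peels sinks to the right and sources to the left; when
    neither exists, moves the vertex with the largest out-degree minus
    in-degree leftward.  Ties break by ascending id, so the order — and
    hence the feedback set — is deterministic.
    """
    out_adj: dict[str, set[str]] = {n: set() for n in nodes}
    in_adj: dict[str, set[str]] = {n: set() for n in nodes}
    for u, v in arcs:
        if u != v:
            out_adj[u].add(v)
            in_adj[v].add(u)
    remaining = set(nodes)
    left: list[str] = []
    right: list[str] = []

    def remove(n: str) -> None:
        remaining.discard(n)
        for m in out_adj[n]:
            in_adj[m].discard(n)
        for m in in_adj[n]:
            out_adj[m].discard(n)
        out_adj[n].clear()
        in_adj[n].clear()

    while remaining:
        moved = True
        while moved:
            moved = False
            sinks = sorted(n for n in remaining if not out_adj[n])
            for n in sinks:
                right.append(n)
                remove(n)
                moved = True
            sources = sorted(n for n in remaining if n not in right and not in_adj[n])
            for n in sources:
                left.append(n)
                remove(n)
                moved = True
        if remaining:
            best = None
            best_delta = 0
            for n in sorted(remaining):  # strict > keeps the smallest id on ties
                delta = len(out_adj[n]) - len(in_adj[n])
                if best is None or delta > best_delta:
                    best, best_delta = n, delta
            left.append(best)
            remove(best)
    return left + list(reversed(right))


def assign_layers(graph: PathwayGraph) -> LayerAssignment:
    """Top-to-bottom layer indices; 0 is the top.

    Acyclic graphs get a pure downward flow (empty feedback set).  On
    cyclic graphs the Eades-order backward arcs become feedback edges
    and are reversed for the longest-path layering, so every
    non-feedback edge still points downward.
    """
    nodes = sorted(graph.entities)
    arcs = _arcs(graph)
    dg = nx.DiGraph()
    dg.add_nodes_from(nodes)
    dg.add_edges_from(arcs)

    if nx.is_directed_acyclic_graph(dg):
        feedback: frozenset[tuple[str, str]] = frozenset()
    else:
        order = _eades_order(nodes, arcs)
        pos = {n: i for i, n in enumerate(order)}
        feedback = frozenset((u, v) for u, v in arcs if pos[u] > pos[v])

    acyclic = nx.DiGraph()
    acyclic.add_nodes_from(nodes)
    for u, v in arcs:
        if (u, v) in feedback:
            acyclic.add_edge(v, u)
        else:
            acyclic.add_edge(u, v)
    # self-reversal can produce a 2-cycle only if both directions existed,
    # in which case only one of them is backward in the order; still a DAG
    layers: dict[str, int] = {n: 0 for n in nodes}
    for n in nx.topological_sort(acyclic):
        for m in acyclic.successors(n):
            layers[m] = max(layers[m], layers[n] + 1)
    return LayerAssignment(layers=layers, feedback_edges=feedback)


# ---------------------------------------------------------------------------
# crossings


def _proper_cross(
    p1: tuple[float, float],
    p2: tuple[float, float],
    p3: tuple[float, float],
    p4: tuple[float, float],
) -> bool:
    def orient(a, b, c) -> float:
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1 = orient(p3, p4, p1)
    d2 = orient(p3, p4, p2)
    d3 = orient(p1, p2, p3)
    d4 = orient(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0) and d1 != 0 and d2 != 0) and (
        (d3 > 0) != (d4 > 0) and d3 != 0 and d4 != 0
    )


def crossing_count(
    positions: Mapping[str, tuple[float, float]] | "LayoutResult",
    graph: PathwayGraph,
) -> int:
    """Straight-line crossings between edge-group centerlines.

    Pairs sharing an endpoint never count; side-by-side lanes of one
    node pair are parallel and count as a single segment.
    """
    if isinstance(positions, LayoutResult):
        positions = positions.positions
    pairs = sorted({
        (e.source, e.target) if e.source < e.target else (e.target, e.source)
        for e in graph.edges
    })
    count = 0
    for i in range(len(pairs)):
        a, b = pairs[i]
        for j in range(i + 1, len(pairs)):
            c, d = pairs[j]
            if {a, b} & {c, d}:
                continue
            if _proper_cross(positions[a], positions[b], positions[c], positions[d]):
                count += 1
    return count


# ---------------------------------------------------------------------------
# horizontal refinement


def refine_positions(
    assignment: LayerAssignment,
    graph: PathwayGraph,
    params: LayoutParams = LayoutParams(),
    seed: int = 0,
) -> LayoutResult:
    """Fix y by layer, refine x, and attach lane geometry.

    Barycenter sweeps reorder each layer toward the mean x of its graph
    neighbours and are rolled back whenever they would increase the
    measured crossing count.  The force phase nudges nodes toward their
    neighbourhood barycenter with a small seeded jitter (nodes without
    neighbours never move, so a lone node stays at the origin).  A final
    pass restores the minimum within-layer separation.
    """
    layers = assignment.layers
    by_layer: dict[int, list[str]] = {}
    for n in sorted(layers):
        by_layer.setdefault(layers[n], []).append(n)

    neighbors: dict[str, set[str]] = {n: set() for n in layers}
    for u, v in _arcs(graph):
        if u != v:
            neighbors[u].add(v)
            neighbors[v].add(u)

    x: dict[str, float] = {}
    for layer_nodes in by_layer.values():
        for i, n in enumerate(layer_nodes):
            x[n] = i * params.min_separation

    def positions_now() -> dict[str, tuple[float, float]]:
        return {n: (x[n], layers[n] * params.layer_gap) for n in layers}

    # barycenter sweeps, alternating direction, rolled back if crossings rise
    layer_keys = sorted(by_layer)
    for sweep in range(params.barycenter_sweeps):
        keys = layer_keys if sweep % 2 == 0 else list(reversed(layer_keys))
        before_x = dict(x)
        before_cross = crossing_count(positions_now(), graph)
        for k in keys:
            nodes_k = by_layer[k]
            bary = {
                n: (
                    sum(x[m] for m in neighbors[n]) / len(neighbors[n])
                    if neighbors[n]
                    else x[n]
                )
                for n in nodes_k
            }
            nodes_k.sort(key=lambda n: (bary[n], n))
            for i, n in enumerate(nodes_k):
                x[n] = i * params.min_separation
        if crossing_count(positions_now(), graph) > before_cross:
            x = before_x
            for k in layer_keys:
                by_layer[k].sort(key=lambda n: (x[n], n))

    # seeded force relaxation within layers (x only)
    rng = random.Random(seed)
    for _ in range(params.force_iterations):
        for n in sorted(layers):
            if not neighbors[n]:
                continue
            target = sum(x[m] for m in neighbors[n]) / len(neighbors[n])
            target += params.jitter * (rng.random() * 2 - 1)
            x[n] += params.force_step * (target - x[n])

    # overlap removal: enforce min separation left-to-right, keep centroid
    for k in layer_keys:
        nodes_k = sorted(by_layer[k], key=lambda n: (x[n], n))
        if not nodes_k:
            continue
        centroid = sum(x[n] for n in nodes_k) / len(nodes_k)
        for i in range(1, len(nodes_k)):
            lo = x[nodes_k[i - 1]] + params.min_separation
            if x[nodes_k[i]] < lo:
                x[nodes_k[i]] = lo
        new_centroid = sum(x[n] for n in nodes_k) / len(nodes_k)
        shift = centroid - new_centroid
        for n in nodes_k:
            x[n] += shift

    positions = positions_now()
    from .model import edge_groups  # local import avoids a cycle at import time

    lanes = edge_geometry(positions, edge_groups(graph), params)
    return LayoutResult(
        positions=positions,
        lanes=lanes,
        layers=dict(layers),
        feedback_edges=assignment.feedback_edges,
    )


def edge_geometry(
    positions: Mapping[str, tuple[float, float]],
    groups: Sequence[EdgeGroup],
    params: LayoutParams = LayoutParams(),
) -> dict[tuple[str, str], tuple[LanePolyline, ...]]:
    """Side-by-side lane polylines for every edge group.

    Lanes sit at symmetric lateral offsets (i - (k-1)/2)·spacing about
    the centerline; the sharp tip goes at the target end for forward
    lanes, the source end for backward, and both ends when one pathway
    has edges in both directions.
    """
    out: dict[tuple[str, str], tuple[LanePolyline, ...]] = {}
    for group in groups:
        a, b = group.pair
        pa, pb = positions[a], positions[b]
        dx, dy = pb[0] - pa[0], pb[1] - pa[1]
        length = (dx * dx + dy * dy) ** 0.5
        if length == 0:
            nxv, nyv = 1.0, 0.0
        else:
            nxv, nyv = -dy / length, dx / length  # unit normal
        k = len(group.lanes)
        lane_objs = []
        for i, lane in enumerate(group.lanes):
            off = (i - (k - 1) / 2) * params.lane_spacing
            points = (
                (pa[0] + off * nxv, pa[1] + off * nyv),
                (pb[0] + off * nxv, pb[1] + off * nyv),
            )
            tips = {
                "forward": ("end",),
                "backward": ("start",),
                "both": ("start", "end"),
            }[lane.direction]
            lane_objs.append(
                LanePolyline(
                    pathway_id=lane.pathway_id,
                    direction=lane.direction,
                    points=points,
                    offset=off,
                    tips=tips,
                )
            )
        out[group.pair] = tuple(lane_objs)
    return out


def compute_layout(
    graph: PathwayGraph,
    params: LayoutParams = LayoutParams(),
    seed: int = 0,
) -> LayoutResult:
    """assign_layers + refine_positions in one call."""
    return refine_positions(assign_layers(graph), graph, params, seed)
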