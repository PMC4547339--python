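"""Static SVG renderer for the line-set pathway view.

Visual encodings: circles are proteins and squares are complexes; a node
in k visible pathways gets k concentric colored borders; edges are drawn
as side-by-side lanes in their pathway's color with sharp-pointed tips
showing direction (both ends tipped when one pathway runs both ways);
hovering desaturates everything outside the hovered element's pathways
and labels only the same-pathway nodes; nodes with unrevealed
upstream/downstream steps carry up/down triangle markers; enlarged
complexes are drawn as their packed symbolic overview with neighbouring
nodes pushed away; the legend lists every pathway, hidden ones in gray.
"""

from __future__ import annotations

import logging
import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Optional

import yaml

from .hierarchy import Dot, PackedOverview, PrunedTreeView, pack_overview
from .layout import LayoutParams, LayoutResult, edge_geometry
from .model import (
    COMPLEX,
    PathwayGraph,
    PathwayModel,
    RelationshipEdge,
    edge_groups,
    memberships,
)
from .query import ViewState, hidden_step_markers, highlight_context, visible_elements

logger = logging.getLogger("pathlines.render")

__all__ = ["StyleConfig", "render_svg", "render_pruned_tree_svg"]

_DEFAULT_PALETTE = (
    "#4e79a7",  # blue
    "#f28e2b",  # orange
    "#59a14f",  # green
    "#e15759",  # red
    "#b07aa1",  # purple
    "#76b7b2",  # teal
    "#edc948",  # yellow
    "#9c755f",  # brown
)


@dataclass(frozen=True)
class StyleConfig:
    """Colors and glyph metrics; defaults give a readable desk-scale plot."""

    palette: tuple[str, ...] = _DEFAULT_PALETTE
    desaturated_color: str = "#c8c8c8"
    node_radius: float = 9.0
    node_side: float = 16.0
    ring_width: float = 3.0
    tip_length: float = 8.0
    tip_width: float = 5.0
    hierarchy_fill_outer: str = "#cfe2f3"  # one hue, two intensities
    hierarchy_fill_inner: str = "#9fc5e8"
    selected_gray: str = "#9e9e9e"
    marker_size: float = 6.0
    label_font_size: float = 10.0
    enlarged_size: float = 90.0
    always_label: bool = False
    margin: float = 40.0

    @classmethod
    def from_yaml(cls, path: str) -> "StyleConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        known = {k: v for k, v in doc.items() if k in cls.__dataclass_fields__}
        if "palette" in known:
            known["palette"] = tuple(known["palette"])
        return cls(**known)


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def _pathway_color(
    graph: PathwayGraph, pathway_id: str, style: StyleConfig
) -> str:
    idx = graph.pathways[pathway_id].color_index
    return style.palette[idx % len(style.palette)]


def _tip_polygon(
    parent: ET.Element,
    at: tuple[float, float],
    toward: tuple[float, float],
    color: str,
    style: StyleConfig,
    extra: dict[str, str],
) -> None:
    """Sharp tip at ``at``, pointing away from ``toward``."""
    dx, dy = at[0] - toward[0], at[1] - toward[1]
    norm = math.hypot(dx, dy) or 1.0
    ux, uy = dx / norm, dy / norm
    px, py = -uy, ux
    base_x, base_y = at[0] - style.tip_length * ux, at[1] - style.tip_length * uy
    points = [
        (at[0], at[1]),
        (base_x + style.tip_width / 2 * px, base_y + style.tip_width / 2 * py),
        (base_x - style.tip_width / 2 * px, base_y - style.tip_width / 2 * py),
    ]
    ET.SubElement(
        parent,
        "polygon",
        {
            "class": "tip",
            "points": " ".join(f"{_fmt(x)},{_fmt(y)}" for x, y in points),
            "fill": color,
            **extra,
        },
    )


def _overview_group(
    overview: PackedOverview, style: StyleConfig, scale: float
) -> ET.Element:
    g = ET.Element("g", {"class": "overview"})
    for item in overview.items:
        if isinstance(item.geometry, Dot):
            d = item.geometry
            ET.SubElement(
                g,
                "circle",
                {
                    "class": "overview-dot",
                    "data-entity": item.entity_id,
                    "cx": _fmt(d.cx * scale),
                    "cy": _fmt(d.cy * scale),
                    "r": _fmt(max(d.r * scale, 1.0)),
                    "fill": "#ffffff",
                    "stroke": "#666666",
                    "stroke-width": "0.5",
                },
            )
        else:
            r = item.geometry
            fill = (
                style.hierarchy_fill_outer
                if item.depth % 2 == 0
                else style.hierarchy_fill_inner
            )
            ET.SubElement(
                g,
                "rect",
                {
                    "class": "overview-complex",
                    "data-entity": item.entity_id,
                    "x": _fmt(r.x * scale),
                    "y": _fmt(r.y * scale),
                    "width": _fmt(r.w * scale),
                    "height": _fmt(r.h * scale),
                    "fill": fill,
                    "stroke": "#666666",
                    "stroke-width": "0.5",
                },
            )
    return g


def render_svg(
    graph: PathwayGraph,
    layout: LayoutResult,
    view: ViewState,
    overviews: Optional[dict[str, PackedOverview]] = None,
    style: StyleConfig = StyleConfig(),
    params: LayoutParams = LayoutParams(),
) -> str:
    """Render one view state to a standalone SVG document (byte-stable)."""
    model = PathwayModel(
        pathways=graph.pathways, entities=graph.entities, reactions={}
    )
    nodes, edges = visible_elements(graph, view)

    # palette exhaustion: warn once, colors recycle via modulo
    n_top_visible = sum(
        1
        for pid in view.visible_pathways
        if pid in graph.pathways and graph.pathways[pid].parent_id is None
    )
    if n_top_visible > len(style.palette):
        logger.warning(
            "palette has %d colors for %d visible top-level pathways; recycling",
            len(style.palette),
            n_top_visible,
        )

    positions = dict(layout.positions)

    # enlarged complexes push their neighbours radially outward
    enlarged = sorted(
        e for e in view.enlarged_complexes
        if e in nodes and graph.entities[e].kind == COMPLEX
    )
    if overviews is None:
        overviews = {eid: pack_overview(eid, model) for eid in enlarged}
    for eid in enlarged:
        cx, cy = positions[eid]
        clearance = style.enlarged_size / 2 + params.min_separation
        for other in sorted(nodes):
            if other == eid:
                continue
            ox, oy = positions[other]
            d = math.hypot(ox - cx, oy - cy)
            if d < clearance:
                if d == 0:
                    ox, d = cx + 1.0, 1.0
                f = clearance / d
                positions[other] = (cx + (ox - cx) * f, cy + (oy - cy) * f)

    # hover context
    context = None
    if view.hover_target is not None and view.hover_target in nodes:
        context = highlight_context(graph, view.hover_target, view)

    def is_desaturated(element) -> bool:
        return context is not None and element in context.desaturated

    # visible edge groups and their lane geometry at displaced positions
    vis_graph = PathwayGraph(
        entities=graph.entities, edges=frozenset(edges), pathways=graph.pathways
    )
    groups = edge_groups(vis_graph)
    lanes = edge_geometry(positions, groups, params)

    xs = [p[0] for p in positions.values()] or [0.0]
    ys = [p[1] for p in positions.values()] or [0.0]
    legend_w = 180.0
    min_x = min(xs) - style.margin - legend_w
    min_y = min(ys) - style.margin
    width = (max(xs) - min(xs)) + 2 * style.margin + legend_w
    height = max((max(ys) - min(ys)) + 2 * style.margin, 40.0 + 16.0 * max(len(graph.pathways), 1))

    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "viewBox": f"{_fmt(min_x)} {_fmt(min_y)} {_fmt(width)} {_fmt(height)}",
        },
    )

    # legend: every loaded pathway; hidden names in gray
    legend = ET.SubElement(svg, "g", {"class": "legend"})
    sorted_pathways = sorted(
        graph.pathways.values(), key=lambda p: (p.color_index, p.id)
    )
    for i, p in enumerate(sorted_pathways):
        y = min_y + 20.0 + 16.0 * i
        visible = p.id in view.visible_pathways
        ET.SubElement(
            legend,
            "rect",
            {
                "class": "legend-swatch",
                "x": _fmt(min_x + 10),
                "y": _fmt(y - 8),
                "width": "10",
                "height": "10",
                "fill": _pathway_color(graph, p.id, style)
                if visible
                else style.desaturated_color,
            },
        )
        label = ET.SubElement(
            legend,
            "text",
            {
                "class": "legend-name",
                "x": _fmt(min_x + 26),
                "y": _fmt(y),
                "font-size": _fmt(style.label_font_size),
                "fill": "#000000" if visible else style.selected_gray,
            },
        )
        label.text = p.name

    # edge lanes with sharp tips
    edges_g = ET.SubElement(svg, "g", {"class": "edges"})
    for pair in sorted(lanes):
        for lane in lanes[pair]:
            edge_repr = RelationshipEdge(
                pair[0] if lane.direction != "backward" else pair[1],
                pair[1] if lane.direction != "backward" else pair[0],
                lane.pathway_id,
            )
            color = (
                style.desaturated_color
                if is_desaturated(edge_repr)
                else _pathway_color(graph, lane.pathway_id, style)
            )
            (x1, y1), (x2, y2) = lane.points
            attrs = {
                "class": "lane",
                "data-pair": f"{pair[0]}|{pair[1]}",
                "data-pathway": lane.pathway_id,
                "data-direction": lane.direction,
            }
            ET.SubElement(
                edges_g,
                "line",
                {
                    **attrs,
                    "x1": _fmt(x1),
                    "y1": _fmt(y1),
                    "x2": _fmt(x2),
                    "y2": _fmt(y2),
                    "stroke": color,
                    "stroke-width": "1.5",
                },
            )
            tip_extra = {"data-pair": attrs["data-pair"], "data-pathway": lane.pathway_id}
            if "end" in lane.tips:
                _tip_polygon(edges_g, (x2, y2), (x1, y1), color, style, tip_extra)
            if "start" in lane.tips:
                _tip_polygon(edges_g, (x1, y1), (x2, y2), color, style, tip_extra)

    # nodes with concentric membership borders
    nodes_g = ET.SubElement(svg, "g", {"class": "nodes"})
    markers = hidden_step_markers(graph, view)
    for n in sorted(nodes):
        e = graph.entities[n]
        x, y = positions[n]
        mems = sorted(
            memberships(graph, n) & view.visible_pathways,
            key=lambda pid: (graph.pathways[pid].color_index, pid),
        )
        node_g = ET.SubElement(
            nodes_g, "g", {"class": "node", "data-entity": n, "data-kind": e.kind}
        )
        if n in enlarged:
            ov = overviews[n]
            scale = style.enlarged_size / max(ov.root.w, ov.root.h, 1e-9)
            holder = ET.SubElement(
                node_g,
                "g",
                {
                    "class": "enlarged",
                    "transform": (
                        f"translate({_fmt(x - ov.root.w * scale / 2)},"
                        f"{_fmt(y - ov.root.h * scale / 2)})"
                    ),
                },
            )
            holder.append(_overview_group(ov, style, scale))
            continue
        desat = is_desaturated(n)
        for i, pid in enumerate(mems):
            color = (
                style.desaturated_color
                if desat
                else _pathway_color(graph, pid, style)
            )
            common = {
                "class": "ring",
                "data-entity": n,
                "data-pathway": pid,
                "fill": "#ffffff" if i == 0 else "none",
                "stroke": color,
                "stroke-width": _fmt(style.ring_width - 1.0),
            }
            if e.kind == COMPLEX:
                side = style.node_side + 2 * i * style.ring_width
                ET.SubElement(
                    node_g,
                    "rect",
                    {
                        **common,
                        "x": _fmt(x - side / 2),
                        "y": _fmt(y - side / 2),
                        "width": _fmt(side),
                        "height": _fmt(side),
                    },
                )
            else:
                ET.SubElement(
                    node_g,
                    "circle",
                    {
                        **common,
                        "cx": _fmt(x),
                        "cy": _fmt(y),
                        "r": _fmt(style.node_radius + i * style.ring_width),
                    },
                )
        # hidden-step markers
        up, down = markers.get(n, (False, False))
        half = max(style.node_radius, style.node_side / 2)
        m = style.marker_size
        if up:
            ET.SubElement(
                node_g,
                "polygon",
                {
                    "class": "marker-up",
                    "data-entity": n,
                    "points": (
                        f"{_fmt(x)},{_fmt(y - half - m)} "
                        f"{_fmt(x - m / 2)},{_fmt(y - half - 1)} "
                        f"{_fmt(x + m / 2)},{_fmt(y - half - 1)}"
                    ),
                    "fill": "#444444",
                },
            )
        if down:
            ET.SubElement(
                node_g,
                "polygon",
                {
                    "class": "marker-down",
                    "data-entity": n,
                    "points": (
                        f"{_fmt(x)},{_fmt(y + half + m)} "
                        f"{_fmt(x - m / 2)},{_fmt(y + half + 1)} "
                        f"{_fmt(x + m / 2)},{_fmt(y + half + 1)}"
                    ),
                    "fill": "#444444",
                },
            )

    # labels: hidden by default, shown for hover context or --always-label
    labels_g = ET.SubElement(svg, "g", {"class": "labels"})
    if context is not None:
        to_label = sorted(context.labeled & nodes)
    elif style.always_label:
        to_label = sorted(nodes)
    else:
        to_label = []
    for n in to_label:
        x, y = positions[n]
        half = max(style.node_radius, style.node_side / 2)
        t = ET.SubElement(
            labels_g,
            "text",
            {
                "class": "label",
                "data-entity": n,
                "x": _fmt(x + half + 3),
                "y": _fmt(y + style.label_font_size / 3),
                "font-size": _fmt(style.label_font_size),
            },
        )
        t.text = graph.entities[n].name

    return (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        + ET.tostring(svg, encoding="unicode")
        + "\n"
    )


def render_pruned_tree_svg(
    ptv: PrunedTreeView,
    model: PathwayModel,
    style: StyleConfig = StyleConfig(),
) -> str:
    """The labeled pruned-tree panel: chain left-to-right, children in a
    column at the right, the selected element underlined and gray."""
    cell_w, cell_h, gap = 110.0, 26.0, 14.0
    n_chain = len(ptv.chain)
    width = (n_chain + 1) * (cell_w + gap) + 2 * style.margin
    height = max(len(ptv.children), 1) * (cell_h + 6) + 2 * style.margin

    svg = ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "version": "1.1",
            "viewBox": f"0 0 {_fmt(width)} {_fmt(height)}",
        },
    )
    g = ET.SubElement(svg, "g", {"class": "pruned-tree"})

    def glyph(eid: str, x: float, y: float, cls: str) -> None:
        e = model.entities.get(eid)
        name = e.name if e is not None else eid
        selected = eid == ptv.selected
        ET.SubElement(
            g,
            "rect",
            {
                "class": cls,
                "data-entity": eid,
                "x": _fmt(x),
                "y": _fmt(y),
                "width": _fmt(cell_w),
                "height": _fmt(cell_h),
                "fill": style.selected_gray
                if selected
                else style.hierarchy_fill_outer,
                "stroke": "#555555",
            },
        )
        t = ET.SubElement(
            g,
            "text",
            {
                "class": "tree-label",
                "data-entity": eid,
                "x": _fmt(x + 6),
                "y": _fmt(y + cell_h / 2 + style.label_font_size / 3),
                "font-size": _fmt(style.label_font_size),
            },
        )
        t.text = name
        if selected:
            ET.SubElement(
                g,
                "line",
                {
                    "class": "underline",
                    "data-entity": eid,
                    "x1": _fmt(x + 6),
                    "y1": _fmt(y + cell_h - 4),
                    "x2": _fmt(x + cell_w - 6),
                    "y2": _fmt(y + cell_h - 4),
                    "stroke": "#333333",
                    "stroke-width": "1.5",
                },
            )

    mid_y = height / 2 - cell_h / 2
    for i, eid in enumerate(ptv.chain):
        glyph(eid, style.margin + i * (cell_w + gap), mid_y, "chain")
    col_x = style.margin + n_chain * (cell_w + gap)
    for j, eid in enumerate(ptv.children):
        glyph(eid, col_x, style.margin + j * (cell_h + 6), "child")

    return (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        + ET.tostring(svg, encoding="unicode")
        + "\n"
    )
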