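"""SVG output: glyph conservation, borders, tips, labels, determinism."""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import replace

from pathlines.fixtures import FixtureConfig, generate
from pathlines.hierarchy import prune_tree
from pathlines.layout import compute_layout
from pathlines.model import graph_from_model, memberships
from pathlines.query import initial_view, visible_elements
from pathlines.render import StyleConfig, render_pruned_tree_svg, render_svg

from conftest import make_model


def _svg(graph, view=None, seed=0, style=StyleConfig()):
    view = view if view is not None else initial_view(graph)
    layout = compute_layout(graph, seed=seed)
    return render_svg(graph, layout, view, style=style)


def _elements(svg_text, cls):
    root = ET.fromstring(svg_text)
    return [
        el for el in root.iter()
        if el.attrib.get("class") == cls
    ]


class TestRenderSvg:
    def test_empty_visible_set_is_legend_only_valid_svg(self, two_pathway_graph):
        view = replace(
            initial_view(two_pathway_graph), visible_pathways=frozenset()
        )
        text = _svg(two_pathway_graph, view)
        ET.fromstring(text)  # well-formed
        assert _elements(text, "node") == []
        assert len(_elements(text, "legend-name")) == 2

    def test_node_glyph_count_equals_visible_nodes(self):
        model = generate(FixtureConfig(seed=21, cycle_probability=0.1))
        g = graph_from_model(model)
        view = replace(
            initial_view(g),
            visible_pathways=frozenset(sorted(g.pathways)[:3]),
        )
        text = _svg(g, view)
        nodes, _ = visible_elements(g, view)
        assert len(_elements(text, "node")) == len(nodes)

    def test_lane_path_count_matches_edge_groups(self):
        model = generate(FixtureConfig(seed=22, cycle_probability=0.2))
        g = graph_from_model(model)
        view = initial_view(g)
        text = _svg(g, view)
        from pathlines.model import PathwayGraph, edge_groups

        _, edges = visible_elements(g, view)
        vis = PathwayGraph(entities=g.entities, edges=frozenset(edges), pathways=g.pathways)
        total_lanes = sum(len(grp.lanes) for grp in edge_groups(vis))
        assert len(_elements(text, "lane")) == total_lanes

    def test_membership_count_draws_that_many_rings(self, two_pathway_graph):
        text = _svg(two_pathway_graph)
        root = ET.fromstring(text)
        rings_x = [
            el for el in root.iter()
            if el.attrib.get("class") == "ring" and el.attrib.get("data-entity") == "X"
        ]
        assert len(rings_x) == len(memberships(two_pathway_graph, "X")) == 2
        rings_z = [
            el for el in root.iter()
            if el.attrib.get("class") == "ring" and el.attrib.get("data-entity") == "Z"
        ]
        assert len(rings_z) == 1

    def test_complexes_are_squares_proteins_circles(self, two_pathway_graph):
        root = ET.fromstring(_svg(two_pathway_graph))
        kinds = {
            el.attrib["data-entity"]: el.tag.split("}")[-1]
            for el in root.iter()
            if el.attrib.get("class") == "ring"
        }
        assert kinds["K"] == "rect"  # complex
        assert kinds["X"] == "circle"  # protein

    def test_both_direction_lane_has_two_tip_markers(self):
        model = make_model(
            entities=[("A", "A"), ("B", "B")],
            reactions=[
                ("r1", {"A"}, {"B"}, {"P"}),
                ("r2", {"B"}, {"A"}, {"P"}),
            ],
            pathways=[("P", "P", None, {"A", "B"}, {"r1", "r2"})],
        )
        g = graph_from_model(model)
        text = _svg(g)
        assert len(_elements(text, "lane")) == 1
        assert len(_elements(text, "tip")) == 2

    def test_hidden_pathway_name_grayed_in_legend(self, two_pathway_graph):
        style = StyleConfig()
        view = replace(
            initial_view(two_pathway_graph), visible_pathways=frozenset({"P1"})
        )
        root = ET.fromstring(_svg(two_pathway_graph, view, style=style))
        fills = {
            el.text: el.attrib["fill"]
            for el in root.iter()
            if el.attrib.get("class") == "legend-name"
        }
        assert fills["Assembly"] == "#000000"
        assert fills["Activation"] == style.selected_gray

    def test_labels_hidden_by_default_shown_on_hover(self, two_pathway_graph):
        assert _elements(_svg(two_pathway_graph), "label") == []
        view = replace(initial_view(two_pathway_graph), hover_target="Z")
        labels = _elements(_svg(two_pathway_graph, view), "label")
        # Z is only in P2: exactly the P2 members get labels
        labeled = {el.attrib["data-entity"] for el in labels}
        assert labeled == {"X", "Y", "K", "Z"}

    def test_hover_desaturates_other_pathways(self):
        model = make_model(
            entities=[("A", "A"), ("B", "B"), ("C", "C"), ("D", "D")],
            reactions=[
                ("r1", {"A"}, {"B"}, {"P1"}),
                ("r2", {"C"}, {"D"}, {"P2"}),
            ],
            pathways=[
                ("P1", "P1", None, {"A", "B"}, {"r1"}),
                ("P2", "P2", None, {"C", "D"}, {"r2"}),
            ],
        )
        g = graph_from_model(model)
        style = StyleConfig()
        view = replace(initial_view(g), hover_target="A")
        root = ET.fromstring(_svg(g, view, style=style))
        ring_colors = {
            el.attrib["data-entity"]: el.attrib["stroke"]
            for el in root.iter()
            if el.attrib.get("class") == "ring"
        }
        assert ring_colors["C"] == style.desaturated_color
        assert ring_colors["A"] != style.desaturated_color

    def test_always_label_flag(self, two_pathway_graph):
        style = StyleConfig(always_label=True)
        labels = _elements(_svg(two_pathway_graph, style=style), "label")
        assert len(labels) == len(two_pathway_graph.entities)

    def test_marker_triangles_for_hidden_steps(self, diamond_graph):
        from pathlines.model import RelationshipEdge

        view = replace(
            initial_view(diamond_graph),
            revealed_edges=frozenset({RelationshipEdge("A", "B", "P")}),
        )
        root = ET.fromstring(_svg(diamond_graph, view))
        down_markers = {
            el.attrib["data-entity"]
            for el in root.iter()
            if el.attrib.get("class") == "marker-down"
        }
        assert "A" in down_markers  # A->C not yet revealed

    def test_enlarged_complex_rendered_as_overview(self, two_pathway_graph):
        view = replace(
            initial_view(two_pathway_graph), enlarged_complexes=frozenset({"K"})
        )
        text = _svg(two_pathway_graph, view)
        root = ET.fromstring(text)
        enlarged = [el for el in root.iter() if el.attrib.get("class") == "enlarged"]
        assert len(enlarged) == 1
        dots = [el for el in root.iter() if el.attrib.get("class") == "overview-dot"]
        assert len(dots) == 2  # X and Y inside K

    def test_byte_stable_output(self):
        model = generate(FixtureConfig(seed=23, cycle_probability=0.2))
        g = graph_from_model(model)
        view = replace(initial_view(g), hover_target=sorted(g.entities)[0])
        assert _svg(g, view, seed=5) == _svg(g, view, seed=5)

    def test_every_svg_is_well_formed(self):
        for seed in range(3):
            model = generate(FixtureConfig(seed=seed, cycle_probability=0.3))
            g = graph_from_model(model)
            ET.fromstring(_svg(g, seed=seed))


class TestPrunedTreeSvg:
    def test_worked_example_glyph_and_label_counts(self, nested_complex_model):
        ptv = prune_tree("A", "G", nested_complex_model)
        text = render_pruned_tree_svg(ptv, nested_complex_model)
        root = ET.fromstring(text)
        chains = [el for el in root.iter() if el.attrib.get("class") == "chain"]
        children = [el for el in root.iter() if el.attrib.get("class") == "child"]
        labels = [el for el in root.iter() if el.attrib.get("class") == "tree-label"]
        assert len(chains) == 3 and len(children) == 4
        assert len(labels) == len(chains) + len(children)

    def test_selected_child_emphasized(self, nested_complex_model):
        style = StyleConfig()
        ptv = prune_tree("A", "G", nested_complex_model)
        root = ET.fromstring(render_pruned_tree_svg(ptv, nested_complex_model, style))
        g_rects = [
            el for el in root.iter()
            if el.attrib.get("class") in ("chain", "child")
            and el.attrib.get("data-entity") == "G"
        ]
        assert g_rects[0].attrib["fill"] == style.selected_gray
        underlines = [el for el in root.iter() if el.attrib.get("class") == "underline"]
        assert len(underlines) == 1

    def test_degenerate_root_selection_single_glyph(self, nested_complex_model):
        ptv = prune_tree("A", "A", nested_complex_model)
        root = ET.fromstring(render_pruned_tree_svg(ptv, nested_complex_model))
        glyphs = [
            el for el in root.iter() if el.attrib.get("class") in ("chain", "child")
        ]
        assert len(glyphs) == 1
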