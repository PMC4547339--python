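"""Interaction semantics: filters, expansion steps, intermediates, hover."""

from __future__ import annotations

import random
from dataclasses import replace

import networkx as nx
import pytest

from pathlines.fixtures import FixtureConfig, generate
from pathlines.model import (
    RelationshipEdge,
    UnknownIdError,
    graph_from_model,
    memberships,
)
from pathlines.query import (
    ViewState,
    downstream_step,
    hidden_step_markers,
    highlight_context,
    initial_view,
    intermediate_subgraph,
    match_keywords,
    upstream_step,
    visible_elements,
)

from conftest import make_model


def rel(s, t, p="P"):
    return RelationshipEdge(s, t, p)


class TestMatchKeywords:
    def test_protein_substring_match(self, two_pathway_model):
        orc1 = two_pathway_model.entities["X"]  # named ORC1
        assert match_keywords(orc1, ["ORC"], two_pathway_model)

    def test_empty_keyword_list_matches_everything(self, two_pathway_model):
        for e in two_pathway_model.entities.values():
            assert match_keywords(e, [], two_pathway_model)

    def test_complex_matches_via_contained_protein_case_insensitive(
        self, two_pathway_model
    ):
        prerc = two_pathway_model.entities["K"]  # contains CDC6
        assert match_keywords(prerc, ["cdc6"], two_pathway_model)

    def test_complex_matches_its_own_name(self, two_pathway_model):
        prerc = two_pathway_model.entities["K"]
        assert match_keywords(prerc, ["prerc"], two_pathway_model)

    def test_no_match(self, two_pathway_model):
        orc1 = two_pathway_model.entities["X"]
        assert not match_keywords(orc1, ["Ubiquitin"], two_pathway_model)


class TestVisibleElements:
    def test_all_pathways_hidden_empty_sets(self, two_pathway_graph):
        view = replace(initial_view(two_pathway_graph), visible_pathways=frozenset())
        nodes, edges = visible_elements(two_pathway_graph, view)
        assert nodes == frozenset() and edges == frozenset()

    def test_hiding_one_pathway_keeps_at_least_one_rule(self, two_pathway_graph):
        view = replace(
            initial_view(two_pathway_graph), visible_pathways=frozenset({"P2"})
        )
        nodes, edges = visible_elements(two_pathway_graph, view)
        # oracle: exactly the elements whose membership meets {P2}
        expected = {
            n for n in two_pathway_graph.entities
            if memberships(two_pathway_graph, n) & {"P2"}
        }
        assert nodes == expected
        assert all(e.pathway_id == "P2" for e in edges)

    def test_multi_membership_node_survives_single_hide(self, two_pathway_graph):
        view = replace(
            initial_view(two_pathway_graph), visible_pathways=frozenset({"P1"})
        )
        nodes, _ = visible_elements(two_pathway_graph, view)
        assert "X" in nodes  # X is in P1 and P2: at-least-one-visible rule

    def test_monotone_under_hiding(self):
        model = generate(FixtureConfig(seed=11, cycle_probability=0.1))
        g = graph_from_model(model)
        view = initial_view(g)
        prev_nodes, prev_edges = visible_elements(g, view)
        for pid in sorted(g.pathways):
            view = replace(
                view, visible_pathways=view.visible_pathways - {pid}
            )
            nodes, edges = visible_elements(g, view)
            assert nodes <= prev_nodes and edges <= prev_edges
            prev_nodes, prev_edges = nodes, edges
        assert prev_nodes == frozenset()


class TestSteps:
    def test_downstream_adds_out_edges_and_targets(self, diamond_graph):
        view = replace(
            initial_view(diamond_graph),
            revealed_nodes=frozenset({"A"}),
            revealed_edges=frozenset(),
        )
        delta = downstream_step(diamond_graph, "A", view)
        assert delta.added_nodes == {"B", "C"}
        assert delta.added_edges == {rel("A", "B"), rel("A", "C")}

    def test_sink_node_empty_delta(self, diamond_graph):
        view = initial_view(diamond_graph)
        assert not downstream_step(diamond_graph, "D", view)

    def test_hidden_pathway_edges_excluded(self, two_pathway_graph):
        view = replace(
            initial_view(two_pathway_graph), visible_pathways=frozenset({"P1"})
        )
        delta = downstream_step(two_pathway_graph, "K", view)
        assert not delta  # K's only out-edge (K->Z) lives in hidden P2

    def test_source_node_empty_upstream(self, diamond_graph):
        view = initial_view(diamond_graph)
        assert not upstream_step(diamond_graph, "A", view)

    def test_upstream_counts_in_edges(self, diamond_graph):
        view = initial_view(diamond_graph)
        delta = upstream_step(diamond_graph, "D", view)
        assert delta.added_edges == {rel("B", "D"), rel("C", "D")}

    def test_upstream_is_downstream_on_reversed_graph(self):
        model = generate(FixtureConfig(seed=13, cycle_probability=0.2))
        g = graph_from_model(model)
        rev_model = generate(FixtureConfig(seed=13, cycle_probability=0.2))
        for rid, r in list(rev_model.reactions.items()):
            rev_model.reactions[rid] = type(r)(
                id=r.id, inputs=r.outputs, outputs=r.inputs,
                pathway_ids=r.pathway_ids,
            )
        rg = graph_from_model(rev_model)
        view = initial_view(g)
        rview = initial_view(rg)
        for n in sorted(g.entities)[:10]:
            up = upstream_step(g, n, view)
            down = downstream_step(rg, n, rview)
            assert {(e.source, e.target, e.pathway_id) for e in up.added_edges} == {
                (e.target, e.source, e.pathway_id) for e in down.added_edges
            }

    def test_unknown_node_raises(self, diamond_graph):
        with pytest.raises(UnknownIdError):
            downstream_step(diamond_graph, "nope", initial_view(diamond_graph))


class TestHiddenStepMarkers:
    def test_fully_expanded_node_has_no_markers(self, diamond_graph):
        view = initial_view(diamond_graph)
        markers = hidden_step_markers(diamond_graph, view)
        assert all(m == (False, False) for m in markers.values())

    def test_partially_revealed_node_flags_downstream(self, diamond_graph):
        view = replace(
            initial_view(diamond_graph),
            revealed_edges=frozenset({rel("A", "B")}),  # A->C unrevealed
        )
        markers = hidden_step_markers(diamond_graph, view)
        assert markers["A"] == (False, True)

    def test_applying_downstream_clears_the_flag(self, diamond_graph):
        view = replace(
            initial_view(diamond_graph),
            revealed_edges=frozenset({rel("A", "B")}),
        )
        delta = downstream_step(diamond_graph, "A", view)
        view2 = delta.apply(view)
        assert hidden_step_markers(diamond_graph, view2)["A"] == (False, False)


class TestIntermediateSubgraph:
    def test_diamond_keeps_both_routes_drops_dangling(self, diamond_graph):
        view = initial_view(diamond_graph)
        delta = intermediate_subgraph(diamond_graph, "A", "D", view)
        assert delta.added_nodes == {"A", "B", "C", "D"}  # X excluded
        assert delta.added_edges == {
            rel("A", "B"), rel("A", "C"), rel("B", "D"), rel("C", "D")
        }

    def test_no_path_empty_delta(self, diamond_graph):
        view = initial_view(diamond_graph)
        assert not intermediate_subgraph(diamond_graph, "D", "A", view)

    def test_hidden_pathway_edges_do_not_carry_paths(self, two_pathway_graph):
        view = replace(
            initial_view(two_pathway_graph), visible_pathways=frozenset({"P1"})
        )
        # X -> K exists in P1 but K -> Z only in hidden P2
        delta = intermediate_subgraph(two_pathway_graph, "X", "Z", view)
        assert not delta

    @pytest.mark.parametrize("seed", range(20))
    def test_equals_union_of_simple_paths_on_random_dags(self, seed):
        rng = random.Random(seed)
        n = rng.randint(4, 12)
        nodes = [f"n{i:02d}" for i in range(n)]
        arcs = sorted(
            (nodes[i], nodes[j])
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < 0.3
        )
        rxns = [(f"r{k}", {a}, {b}, {"P"}) for k, (a, b) in enumerate(arcs)]
        model = make_model(
            entities=[(x, x) for x in nodes],
            reactions=rxns,
            pathways=[("P", "P", None, set(nodes), {r[0] for r in rxns})],
        )
        g = graph_from_model(model)
        view = initial_view(g)
        s, t = nodes[0], nodes[-1]
        delta = intermediate_subgraph(g, s, t, view)
        # oracle: exhaustive simple-path enumeration
        dg = nx.DiGraph(arcs)
        dg.add_nodes_from(nodes)
        path_nodes: set[str] = set()
        path_edges: set[tuple[str, str]] = set()
        for path in nx.all_simple_paths(dg, s, t):
            path_nodes.update(path)
            path_edges.update(zip(path, path[1:]))
        assert delta.added_nodes == path_nodes
        assert {(e.source, e.target) for e in delta.added_edges} == path_edges


class TestHighlightContext:
    def test_single_pathway_everything_highlighted(self, diamond_graph):
        view = initial_view(diamond_graph)
        ctx = highlight_context(diamond_graph, "A", view)
        assert ctx.desaturated == frozenset()
        nodes, edges = visible_elements(diamond_graph, view)
        assert ctx.highlighted == nodes | edges

    def test_disjoint_pathway_elements_desaturate(self):
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
        ctx = highlight_context(g, "A", initial_view(g))
        assert ctx.desaturated == {"C", "D", rel("C", "D", "P2")}
        assert ctx.labeled == {"A", "B"}

    def test_shared_element_highlights_union_of_its_pathways(self, two_pathway_graph):
        ctx = highlight_context(two_pathway_graph, "X", initial_view(two_pathway_graph))
        # X is in P1 and P2, so every element of either pathway pops
        assert frozenset(ctx.desaturated) == frozenset()


class TestClosureProperty:
    def test_repeated_downstream_reaches_visible_fixpoint(self):
        model = generate(
            FixtureConfig(n_pathways=3, n_entities=20, n_reactions=25,
                          cycle_probability=0.2, seed=17)
        )
        g = graph_from_model(model)
        full = initial_view(g)
        view = replace(full, revealed_edges=frozenset())
        changed = True
        while changed:
            changed = False
            for n in sorted(view.revealed_nodes):
                delta = downstream_step(g, n, view)
                new = delta.apply(view)
                if new != view:
                    view = new
                    changed = True
        # upstream sweep for edges not reachable forward from the seeds
        for n in sorted(g.entities):
            view = upstream_step(g, n, view).apply(view)
        assert visible_elements(g, view) == visible_elements(g, full)


class TestViewStateSerialization:
    def test_roundtrip(self, diamond_graph):
        view = replace(
            initial_view(diamond_graph),
            keywords=("orc",),
            hover_target="A",
            enlarged_complexes=frozenset(),
        )
        back = ViewState.from_dict(view.to_dict())
        assert back == view
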