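"""Interaction semantics as pure functions over (graph, view state).

Every interaction the prototype supports — hiding pathways, keyword
filtering, stepwise upstream/downstream expansion, revealing the
intermediate steps between two nodes, hover highlighting — is a pure
function from the merged graph and the current :class:`ViewState` to a
new state or an element set.  State changes travel as explicit
:class:`Delta` value objects, so an undo stack can be layered on later
without redesign.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import networkx as nx

from .model import (
    COMPLEX,
    Entity,
    PathwayGraph,
    PathwayModel,
    RelationshipEdge,
    UnknownIdError,
    containment_closure,
    memberships,
    pathway_ancestors,
)

__all__ = [
    "ViewState",
    "Delta",
    "HighlightContext",
    "match_keywords",
    "visible_elements",
    "downstream_step",
    "upstream_step",
    "hidden_step_markers",
    "intermediate_subgraph",
    "highlight_context",
    "initial_view",
]


@dataclass(frozen=True)
class ViewState:
    """What is currently drawn; fully determines the rendered picture."""

    visible_pathways: frozenset[str] = frozenset()
    keywords: tuple[str, ...] = ()
    revealed_nodes: frozenset[str] = frozenset()
    revealed_edges: frozenset[RelationshipEdge] = frozenset()
    enlarged_complexes: frozenset[str] = frozenset()
    hover_target: Optional[str] = None

    def to_dict(self) -> dict:
        return {
            "visible_pathways": sorted(self.visible_pathways),
            "keywords": list(self.keywords),
            "revealed_nodes": sorted(self.revealed_nodes),
            "revealed_edges": sorted(
                [e.source, e.target, e.pathway_id] for e in self.revealed_edges
            ),
            "enlarged_complexes": sorted(self.enlarged_complexes),
            "hover_target": self.hover_target,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "ViewState":
        return cls(
            visible_pathways=frozenset(doc.get("visible_pathways", [])),
            keywords=tuple(doc.get("keywords", [])),
            revealed_nodes=frozenset(doc.get("revealed_nodes", [])),
            revealed_edges=frozenset(
                RelationshipEdge(*triple)
                for triple in doc.get("revealed_edges", [])
            ),
            enlarged_complexes=frozenset(doc.get("enlarged_complexes", [])),
            hover_target=doc.get("hover_target"),
        )


@dataclass(frozen=True)
class Delta:
    """Nodes and edges an interaction adds to the view."""

    added_nodes: frozenset[str] = frozenset()
    added_edges: frozenset[RelationshipEdge] = frozenset()

    def apply(self, view: ViewState) -> ViewState:
        return replace(
            view,
            revealed_nodes=view.revealed_nodes | self.added_nodes,
            revealed_edges=view.revealed_edges | self.added_edges,
        )

    def __bool__(self) -> bool:
        return bool(self.added_nodes or self.added_edges)


@dataclass(frozen=True)
class HighlightContext:
    """Hover result: same-pathway elements stand out, the rest gray out."""

    highlighted: frozenset  # node ids and edges sharing a pathway
    desaturated: frozenset  # remaining visible elements
    labeled: frozenset  # node ids that get labels


def initial_view(graph: PathwayGraph) -> ViewState:
    """Everything loaded, revealed, and visible; no filters."""
    return ViewState(
        visible_pathways=frozenset(graph.pathways),
        revealed_nodes=frozenset(graph.entities),
        revealed_edges=graph.edges,
    )


# ---------------------------------------------------------------------------
# filtering


def match_keywords(
    entity: Entity, keywords: tuple[str, ...] | list[str], model: PathwayModel
) -> bool:
    """Case-insensitive substring keyword filter.

    An empty keyword list matches everything (no filtering).  A protein
    matches on its own name; a complex matches on its own name or on the
    name of any transitively contained protein.
    """
    if not keywords:
        return True
    lowered = [k.lower() for k in keywords]

    def name_matches(name: str) -> bool:
        low = name.lower()
        return any(k in low for k in lowered)

    if name_matches(entity.name):
        return True
    if entity.kind == COMPLEX:
        for cid in containment_closure(model, entity.id):
            inner = model.entities.get(cid)
            if inner is not None and inner.kind != COMPLEX and name_matches(inner.name):
                return True
    return False


def _edge_visible(graph: PathwayGraph, edge: RelationshipEdge, view: ViewState) -> bool:
    # an edge of sub-pathway S also counts toward every visible ancestor
    return bool(
        pathway_ancestors(graph.pathways, edge.pathway_id) & view.visible_pathways
    )


def _model_of(graph: PathwayGraph) -> PathwayModel:
    return PathwayModel(pathways=graph.pathways, entities=graph.entities, reactions={})


def visible_elements(
    graph: PathwayGraph, view: ViewState
) -> tuple[frozenset[str], frozenset[RelationshipEdge]]:
    """The node and edge sets actually drawn.

    A node survives iff it is revealed, belongs to at least one visible
    pathway, and passes the keyword filter; an edge survives iff its
    pathway is visible and both endpoints survive.
    """
    model = _model_of(graph)
    nodes = frozenset(
        n
        for n in view.revealed_nodes
        if n in graph.entities
        and memberships(graph, n) & view.visible_pathways
        and match_keywords(graph.entities[n], view.keywords, model)
    )
    edges = frozenset(
        e
        for e in view.revealed_edges
        if e in graph.edges
        and _edge_visible(graph, e, view)
        and e.source in nodes
        and e.target in nodes
    )
    return nodes, edges


# ---------------------------------------------------------------------------
# stepwise expansion


def downstream_step(graph: PathwayGraph, node_id: str, view: ViewState) -> Delta:
    """One downstream step: every visible-pathway relationship that
    starts at the node, plus the targets it reaches."""
    if node_id not in graph.entities:
        raise UnknownIdError(f"unknown entity id {node_id!r}")
    edges = frozenset(
        e
        for e in graph.edges
        if e.source == node_id and _edge_visible(graph, e, view)
    )
    return Delta(
        added_nodes=frozenset(e.target for e in edges),
        added_edges=edges,
    )


def upstream_step(graph: PathwayGraph, node_id: str, view: ViewState) -> Delta:
    """One upstream step: every visible-pathway relationship that ends
    at the node, plus the sources they come from."""
    if node_id not in graph.entities:
        raise UnknownIdError(f"unknown entity id {node_id!r}")
    edges = frozenset(
        e
        for e in graph.edges
        if e.target == node_id and _edge_visible(graph, e, view)
    )
    return Delta(
        added_nodes=frozenset(e.source for e in edges),
        added_edges=edges,
    )


def hidden_step_markers(
    graph: PathwayGraph, view: ViewState
) -> dict[str, tuple[bool, bool]]:
    """(has_hidden_upstream, has_hidden_downstream) per visible node.

    True when at least one visible-pathway in/out edge of the node is
    not yet revealed — rendered as up/down triangle markers.
    """
    nodes, _ = visible_elements(graph, view)
    out: dict[str, tuple[bool, bool]] = {}
    for n in nodes:
        up = any(
            e.target == n and e not in view.revealed_edges and _edge_visible(graph, e, view)
            for e in graph.edges
        )
        down = any(
            e.source == n and e not in view.revealed_edges and _edge_visible(graph, e, view)
            for e in graph.edges
        )
        out[n] = (up, down)
    return out


# ---------------------------------------------------------------------------
# intermediate steps between two nodes


def intermediate_subgraph(
    graph: PathwayGraph, source_id: str, target_id: str, view: ViewState
) -> Delta:
    """All relationships on a route from source to target.

    Keeps exactly the nodes reachable from the source from which the
    target is still reachable, using visible-pathway edges only, plus
    every visible edge inside that node set.  On acyclic graphs this is
    the union of all directed simple paths from source to target; on
    cyclic graphs nodes on cycles lying between the endpoints are
    included too.  No path at all yields an empty delta.
    """
    for nid in (source_id, target_id):
        if nid not in graph.entities:
            raise UnknownIdError(f"unknown entity id {nid!r}")
    dg = nx.DiGraph()
    dg.add_nodes_from(graph.entities)
    visible_arcs = {
        (e.source, e.target)
        for e in graph.edges
        if _edge_visible(graph, e, view)
    }
    dg.add_edges_from(visible_arcs)

    fwd = {source_id} | nx.descendants(dg, source_id)
    if target_id not in fwd:
        return Delta()
    bwd = {target_id} | nx.ancestors(dg, target_id)
    between = fwd & bwd
    edges = frozenset(
        e
        for e in graph.edges
        if (e.source, e.target) in visible_arcs
        and e.source in between
        and e.target in between
    )
    return Delta(added_nodes=frozenset(between), added_edges=edges)


# ---------------------------------------------------------------------------
# hover highlighting


def highlight_context(
    graph: PathwayGraph, element_id: str, view: ViewState
) -> HighlightContext:
    """Hover semantics: same-pathway elements pop, the rest desaturate.

    Highlighted are the visible nodes and edges that share at least one
    pathway with the hovered element; only the highlighted nodes get
    labels, every other visible element is drawn in the desaturated
    color.
    """
    if element_id not in graph.entities:
        raise UnknownIdError(f"unknown entity id {element_id!r}")
    focus = memberships(graph, element_id) & view.visible_pathways
    nodes, edges = visible_elements(graph, view)

    highlighted: set = set()
    desaturated: set = set()
    for n in nodes:
        if memberships(graph, n) & focus:
            highlighted.add(n)
        else:
            desaturated.add(n)
    for e in edges:
        if pathway_ancestors(graph.pathways, e.pathway_id) & focus:
            highlighted.add(e)
        else:
            desaturated.add(e)
    labeled = frozenset(x for x in highlighted if isinstance(x, str))
    return HighlightContext(
        highlighted=frozenset(highlighted),
        desaturated=frozenset(desaturated),
        labeled=labeled,
    )
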