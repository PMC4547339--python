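"""Domain model for multi-pathway reaction-relationship graphs.

A biological pathway is treated as a *set* of entities (proteins and
protein complexes) and biochemical reactions.  Reactions are hyperedges:
any number of input entities are consumed and any number of output
entities produced.  For drawing and topological queries each reaction is
lowered to binary *reaction relationships*: a directed edge A -> B exists
in pathway P iff P owns at least one reaction with A among its inputs and
B among its outputs.  Merging several pathways never duplicates a node —
an entity that participates in many pathways is a single vertex whose set
memberships are carried on its incident edges and rendered as colored
borders and side-by-side edge lanes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "Entity",
    "Reaction",
    "Pathway",
    "RelationshipEdge",
    "PathwayModel",
    "PathwayGraph",
    "Lane",
    "EdgeGroup",
    "InvalidReactionError",
    "ResolutionError",
    "ModelValidationError",
    "UnknownIdError",
    "build_relationships",
    "build_graph",
    "memberships",
    "edge_groups",
    "validate_model",
    "containment_closure",
    "pathway_ancestors",
    "aggregated_entity_ids",
]

PROTEIN = "protein"
COMPLEX = "complex"


class InvalidReactionError(ValueError):
    """A reaction violates its structural preconditions (empty side)."""


class ResolutionError(ValueError):
    """A cross-reference names an id absent from the model."""


class ModelValidationError(ValueError):
    """A model invariant (containment acyclicity, kind rules) is broken."""


class UnknownIdError(KeyError):
    """A lookup named an id the graph does not contain."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep message plain
        return self.args[0] if self.args else ""


@dataclass(frozen=True)
class Entity:
    """A protein or a protein complex.

    ``components`` is the ordered list of direct component entity ids and
    is non-empty only for complexes.  ``source_class`` tags entities
    imported from a physical-entity class other than Protein/Complex
    (small molecules, RNA, DNA) that are modelled as protein-shaped nodes.
    """

    id: str
    name: str
    kind: str = PROTEIN
    components: tuple[str, ...] = ()
    source_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in (PROTEIN, COMPLEX):
            raise ModelValidationError(
                f"entity {self.id!r}: unknown kind {self.kind!r}"
            )
        if self.kind == PROTEIN and self.components:
            raise ModelValidationError(
                f"entity {self.id!r}: proteins cannot have components"
            )
        if not isinstance(self.components, tuple):
            object.__setattr__(self, "components", tuple(self.components))


@dataclass(frozen=True)
class Reaction:
    """A biochemical reaction: a hyperedge from ``inputs`` to ``outputs``.

    ``pathway_ids`` lists every pathway that owns the reaction.
    """

    id: str
    inputs: frozenset[str]
    outputs: frozenset[str]
    pathway_ids: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "inputs", frozenset(self.inputs))
        object.__setattr__(self, "outputs", frozenset(self.outputs))
        object.__setattr__(self, "pathway_ids", frozenset(self.pathway_ids))


@dataclass
class Pathway:
    """A named set of entities and reactions; may nest under a parent."""

    id: str
    name: str
    parent_id: Optional[str] = None
    entity_ids: frozenset[str] = frozenset()
    reaction_ids: frozenset[str] = frozenset()
    color_index: int = 0

    def __post_init__(self) -> None:
        self.entity_ids = frozenset(self.entity_ids)
        self.reaction_ids = frozenset(self.reaction_ids)


@dataclass(frozen=True, order=True)
class RelationshipEdge:
    """Directed reaction relationship in one pathway (the drawable edge)."""

    source: str
    target: str
    pathway_id: str


@dataclass
class PathwayModel:
    """The loaded field of interest: pathways, entities and reactions."""

    pathways: dict[str, Pathway] = field(default_factory=dict)
    entities: dict[str, Entity] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)

    @classmethod
    def from_lists(
        cls,
        pathways: Iterable[Pathway],
        entities: Iterable[Entity],
        reactions: Iterable[Reaction],
    ) -> "PathwayModel":
        return cls(
            pathways={p.id: p for p in pathways},
            entities={e.id: e for e in entities},
            reactions={r.id: r for r in reactions},
        )

    def is_empty(self) -> bool:
        return not (self.pathways or self.entities or self.reactions)


@dataclass
class PathwayGraph:
    """Merged, node-deduplicated directed graph over all loaded pathways.

    ``edge_reactions`` maps each relationship edge back to the reaction
    ids it was derived from — several reactions may collapse onto one
    edge and the provenance is kept as metadata.
    """

    entities: dict[str, Entity]
    edges: frozenset[RelationshipEdge]
    pathways: dict[str, Pathway]
    edge_reactions: dict[RelationshipEdge, frozenset[str]] = field(
        default_factory=dict
    )

    def entity(self, entity_id: str) -> Entity:
        try:
            return self.entities[entity_id]
        except KeyError:
            raise UnknownIdError(f"unknown entity id {entity_id!r}") from None


@dataclass(frozen=True)
class Lane:
    """One colored line drawn between a node pair, for one pathway."""

    pathway_id: str
    direction: str  # "forward" | "backward" | "both"


@dataclass(frozen=True)
class EdgeGroup:
    """All lanes between one unordered node pair, drawn side by side.

    ``pair`` is ordered ascending by id; ``forward`` means pair[0] ->
    pair[1].  A pathway with edges in both directions between the pair
    collapses to a single lane with direction ``both`` (a sharp tip on
    both extremities).
    """

    pair: tuple[str, str]
    lanes: tuple[Lane, ...]


# ---------------------------------------------------------------------------
# graph construction


def build_relationships(
    reaction: Reaction, pathway_id: str
) -> set[RelationshipEdge]:
    """Lower one reaction to its binary reaction relationships.

    Every input is linked to every output (a 2-in/2-out reaction yields
    four distinct directed edges).  Pairs where input and output are the
    same entity are dropped: a self-loop has no meaningful sharp-tip
    depiction.
    """
    if not reaction.inputs or not reaction.outputs:
        raise InvalidReactionError(
            f"reaction {reaction.id!r} has an empty "
            f"{'inputs' if not reaction.inputs else 'outputs'} set"
        )
    return {
        RelationshipEdge(i, o, pathway_id)
        for i, o in itertools.product(reaction.inputs, reaction.outputs)
        if i != o
    }


def build_graph(
    pathways: Sequence[Pathway] | Mapping[str, Pathway],
    reactions: Sequence[Reaction] | Mapping[str, Reaction],
    entities: Sequence[Entity] | Mapping[str, Entity],
) -> PathwayGraph:
    """Merge pathways into one node-deduplicated relationship graph.

    Entities sharing an identifier across pathways map onto a single
    node; edges are the union of :func:`build_relationships` over every
    (reaction, owning pathway) pair, deduplicated per
    (source, target, pathway) — "at least one reaction" semantics.
    """
    pmap = dict(pathways) if isinstance(pathways, Mapping) else {
        p.id: p for p in pathways
    }
    rmap = dict(reactions) if isinstance(reactions, Mapping) else {
        r.id: r for r in reactions
    }
    emap = dict(entities) if isinstance(entities, Mapping) else {
        e.id: e for e in entities
    }

    dangling: list[str] = []
    for r in rmap.values():
        for eid in sorted(r.inputs | r.outputs):
            if eid not in emap:
                dangling.append(f"reaction {r.id!r} references entity {eid!r}")
        for pid in sorted(r.pathway_ids):
            if pid not in pmap:
                dangling.append(f"reaction {r.id!r} references pathway {pid!r}")
    for p in pmap.values():
        for eid in sorted(p.entity_ids):
            if eid not in emap:
                dangling.append(f"pathway {p.id!r} references entity {eid!r}")
        for rid in sorted(p.reaction_ids):
            if rid not in rmap:
                dangling.append(f"pathway {p.id!r} references reaction {rid!r}")
        if p.parent_id is not None and p.parent_id not in pmap:
            dangling.append(f"pathway {p.id!r} references parent {p.parent_id!r}")
    for e in emap.values():
        for cid in e.components:
            if cid not in emap:
                dangling.append(f"entity {e.id!r} references component {cid!r}")
    if dangling:
        raise ResolutionError(
            "unresolved references: " + "; ".join(sorted(dangling))
        )

    edge_reactions: dict[RelationshipEdge, set[str]] = {}
    for r in rmap.values():
        for pid in r.pathway_ids:
            for edge in build_relationships(r, pid):
                edge_reactions.setdefault(edge, set()).add(r.id)

    return PathwayGraph(
        entities=emap,
        edges=frozenset(edge_reactions),
        pathways=pmap,
        edge_reactions={e: frozenset(v) for e, v in edge_reactions.items()},
    )


# ---------------------------------------------------------------------------
# memberships and the sub-pathway aggregation rule


def pathway_ancestors(
    pathways: Mapping[str, Pathway], pathway_id: str
) -> set[str]:
    """The pathway plus every ancestor along parent links."""
    out = set()
    cur: Optional[str] = pathway_id
    while cur is not None and cur in pathways and cur not in out:
        out.add(cur)
        cur = pathways[cur].parent_id
    return out


def aggregated_entity_ids(
    pathways: Mapping[str, Pathway], pathway_id: str
) -> set[str]:
    """Entity ids of a pathway and, transitively, of its sub-pathways.

    An entity belonging to sub-pathway S counts as a member of every
    ancestor of S, so collapsing S in the pathway list reassigns its
    elements to the visible ancestor.
    """
    children: dict[str, list[str]] = {}
    for p in pathways.values():
        if p.parent_id is not None:
            children.setdefault(p.parent_id, []).append(p.id)
    out: set[str] = set()
    stack = [pathway_id]
    seen = set()
    while stack:
        pid = stack.pop()
        if pid in seen or pid not in pathways:
            continue
        seen.add(pid)
        out |= pathways[pid].entity_ids
        stack.extend(children.get(pid, ()))
    return out


def memberships(graph: PathwayGraph, entity_id: str) -> set[str]:
    """Every pathway whose (sub-pathway-aggregated) entity set holds the entity.

    Each additional membership is rendered as another colored node border.
    """
    if entity_id not in graph.entities:
        raise UnknownIdError(f"unknown entity id {entity_id!r}")
    direct = {
        p.id for p in graph.pathways.values() if entity_id in p.entity_ids
    }
    out: set[str] = set()
    for pid in direct:
        out |= pathway_ancestors(graph.pathways, pid)
    return out


# ---------------------------------------------------------------------------
# edge grouping for side-by-side lanes


def edge_groups(graph: PathwayGraph) -> list[EdgeGroup]:
    """Group edges by unordered node pair into ordered, drawable lanes.

    Within a pair, a pathway with edges in both directions collapses to
    one ``both`` lane.  Lanes are ordered by (color_index, pathway id)
    and groups by node pair, so renders are byte-stable.
    """
    by_pair: dict[tuple[str, str], dict[str, set[str]]] = {}
    for e in graph.edges:
        pair = (e.source, e.target) if e.source < e.target else (
            e.target, e.source
        )
        direction = "forward" if e.source == pair[0] else "backward"
        by_pair.setdefault(pair, {}).setdefault(e.pathway_id, set()).add(
            direction
        )

    def lane_key(pid: str) -> tuple[int, str]:
        p = graph.pathways.get(pid)
        return (p.color_index if p else 0, pid)

    groups = []
    for pair in sorted(by_pair):
        lanes = []
        for pid in sorted(by_pair[pair], key=lane_key):
            dirs = by_pair[pair][pid]
            direction = "both" if len(dirs) == 2 else next(iter(dirs))
            lanes.append(Lane(pathway_id=pid, direction=direction))
        groups.append(EdgeGroup(pair=pair, lanes=tuple(lanes)))
    return groups


# ---------------------------------------------------------------------------
# validation


def validate_model(model: PathwayModel) -> list[str]:
    """Check model invariants; returns a list of problem strings.

    Raises :class:`ModelValidationError` for containment cycles (the one
    defect later stages cannot tolerate); other problems are reported.
    """
    problems: list[str] = []

    # containment acyclicity via iterative DFS over component links
    state: dict[str, int] = {}  # 1 = on stack, 2 = done

    def walk(eid: str) -> None:
        stack = [(eid, iter(model.entities[eid].components if eid in model.entities else ()))]
        state[eid] = 1
        while stack:
            cur, it = stack[-1]
            advanced = False
            for cid in it:
                if cid not in model.entities:
                    continue
                if state.get(cid) == 1:
                    raise ModelValidationError(
                        f"containment cycle through entity {cid!r}"
                    )
                if cid not in state:
                    state[cid] = 1
                    stack.append((cid, iter(model.entities[cid].components)))
                    advanced = True
                    break
            if not advanced:
                state[cur] = 2
                stack.pop()

    for eid in model.entities:
        if eid not in state:
            walk(eid)

    # pathway parent links form a forest
    for p in model.pathways.values():
        seen = {p.id}
        cur = p.parent_id
        while cur is not None:
            if cur in seen:
                problems.append(f"pathway parent cycle through {cur!r}")
                break
            seen.add(cur)
            cur = model.pathways[cur].parent_id if cur in model.pathways else None

    for r in model.reactions.values():
        if not r.inputs:
            problems.append(f"reaction {r.id!r} has empty inputs")
        if not r.outputs:
            problems.append(f"reaction {r.id!r} has empty outputs")
        for eid in sorted((r.inputs | r.outputs) - set(model.entities)):
            problems.append(f"reaction {r.id!r}: unknown entity {eid!r}")
        for pid in sorted(r.pathway_ids - set(model.pathways)):
            problems.append(f"reaction {r.id!r}: unknown pathway {pid!r}")
    for p in model.pathways.values():
        for eid in sorted(p.entity_ids - set(model.entities)):
            problems.append(f"pathway {p.id!r}: unknown entity {eid!r}")
        for rid in sorted(p.reaction_ids - set(model.reactions)):
            problems.append(f"pathway {p.id!r}: unknown reaction {rid!r}")
    for e in model.entities.values():
        for cid in e.components:
            if cid not in model.entities:
                problems.append(f"entity {e.id!r}: unknown component {cid!r}")
    return problems


def containment_closure(model: PathwayModel, root_id: str) -> set[str]:
    """All entity ids transitively contained in ``root_id`` (excl. root)."""
    out: set[str] = set()
    stack = list(model.entities[root_id].components) if root_id in model.entities else []
    while stack:
        cid = stack.pop()
        if cid in out:
            continue
        out.add(cid)
        if cid in model.entities:
            stack.extend(model.entities[cid].components)
    return out


def graph_from_model(model: PathwayModel) -> PathwayGraph:
    """Convenience: :func:`build_graph` straight from a loaded model."""
    return build_graph(model.pathways, model.reactions, model.entities)
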