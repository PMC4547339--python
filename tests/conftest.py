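from __future__ import annotations

import pytest

from pathlines.model import (
    Entity,
    Pathway,
    PathwayModel,
    Reaction,
    graph_from_model,
)
from pathlines.readwrite import assign_color_indices


def make_model(entities, reactions, pathways) -> PathwayModel:
    """Build a model from terse tuples.

    entities: (id, name, kind, components) or (id, name) for proteins;
    reactions: (id, inputs, outputs, pathway_ids);
    pathways: (id, name, parent, entity_ids, reaction_ids).
    """
    model = PathwayModel()
    for spec in entities:
        if len(spec) == 2:
            eid, name = spec
            model.entities[eid] = Entity(id=eid, name=name)
        else:
            eid, name, kind, comps = spec
            model.entities[eid] = Entity(
                id=eid, name=name, kind=kind, components=tuple(comps)
            )
    for rid, inputs, outputs, pids in reactions:
        model.reactions[rid] = Reaction(
            id=rid,
            inputs=frozenset(inputs),
            outputs=frozenset(outputs),
            pathway_ids=frozenset(pids),
        )
    for pid, name, parent, eids, rids in pathways:
        model.pathways[pid] = Pathway(
            id=pid,
            name=name,
            parent_id=parent,
            entity_ids=frozenset(eids),
            reaction_ids=frozenset(rids),
        )
    assign_color_indices(model)
    return model


@pytest.fixture
def two_by_two_model() -> PathwayModel:
    """One reaction with two inputs and two outputs in one pathway."""
    return make_model(
        entities=[("A", "A"), ("B", "B"), ("C", "C"), ("D", "D")],
        reactions=[("r1", {"A", "B"}, {"C", "D"}, {"P"})],
        pathways=[("P", "Pathway P", None, {"A", "B", "C", "D"}, {"r1"})],
    )


@pytest.fixture
def diamond_model() -> PathwayModel:
    """A -> B -> D and A -> C -> D, plus a dangling branch B -> X."""
    return make_model(
        entities=[(n, n) for n in "ABCDX"],
        reactions=[
            ("r1", {"A"}, {"B"}, {"P"}),
            ("r2", {"A"}, {"C"}, {"P"}),
            ("r3", {"B"}, {"D"}, {"P"}),
            ("r4", {"C"}, {"D"}, {"P"}),
            ("r5", {"B"}, {"X"}, {"P"}),
        ],
        pathways=[("P", "Pathway P", None, set("ABCDX"), {"r1", "r2", "r3", "r4", "r5"})],
    )


@pytest.fixture
def nested_complex_model() -> PathwayModel:
    """The worked hierarchy: A ⊃ B ⊃ C ⊃ {D, E, F, G}."""
    return make_model(
        entities=[
            ("D", "D"), ("E", "E"), ("F", "F"), ("G", "G"),
            ("C", "C", "complex", ["D", "E", "F", "G"]),
            ("B", "B", "complex", ["C"]),
            ("A", "A", "complex", ["B"]),
        ],
        reactions=[],
        pathways=[("P", "Pathway P", None, {"A"}, set())],
    )


@pytest.fixture
def two_pathway_model() -> PathwayModel:
    """Two overlapping pathways sharing protein X and complex K."""
    return make_model(
        entities=[
            ("X", "ORC1"), ("Y", "CDC6"), ("Z", "MCM10"),
            ("K", "preRC", "complex", ["X", "Y"]),
        ],
        reactions=[
            ("r1", {"X"}, {"K"}, {"P1"}),
            ("r2", {"Y"}, {"K"}, {"P2"}),
            ("r3", {"K"}, {"Z"}, {"P2"}),
        ],
        pathways=[
            ("P1", "Assembly", None, {"X", "Y", "K"}, {"r1"}),
            ("P2", "Activation", None, {"X", "K", "Y", "Z"}, {"r2", "r3"}),
        ],
    )


@pytest.fixture
def two_by_two_graph(two_by_two_model):
    return graph_from_model(two_by_two_model)


@pytest.fixture
def diamond_graph(diamond_model):
    return graph_from_model(diamond_model)


@pytest.fixture
def two_pathway_graph(two_pathway_model):
    return graph_from_model(two_pathway_model)
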