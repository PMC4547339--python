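"""JSON pathway dialect: the project's canonical serialization.

Top-level keys ``pathways``, ``entities``, ``reactions``.  Entities carry
``id``, ``name``, ``kind``, ``components``; reactions carry ``id``,
``inputs``, ``outputs``, ``pathways``; pathways carry ``id``, ``name``,
``parent``, ``entities``, ``reactions``.  Output is UTF-8 with sorted
keys and sorted id lists, so write is deterministic and read∘write is
the identity on models.
"""

from __future__ import annotations

import json
from typing import Any, IO, Union

from .model import (
    Entity,
    Pathway,
    PathwayModel,
    Reaction,
    validate_model,
)

__all__ = [
    "SchemaError",
    "read_pathway_json",
    "write_pathway_json",
    "model_to_dict",
    "model_from_dict",
    "assign_color_indices",
]


class SchemaError(ValueError):
    """The document does not match the dialect schema."""


def assign_color_indices(model: PathwayModel) -> None:
    """Assign stable pathway color indices at load time.

    Top-level pathways get the low indices (ascending id) so that colors
    are distinct among simultaneously visible top-level pathways;
    sub-pathways follow.
    """
    top = sorted(p.id for p in model.pathways.values() if p.parent_id is None)
    sub = sorted(p.id for p in model.pathways.values() if p.parent_id is not None)
    for i, pid in enumerate(top + sub):
        model.pathways[pid].color_index = i


def _require(obj: dict, key: str, typ, where: str):
    if key not in obj:
        raise SchemaError(f"{where}: missing field {key!r}")
    val = obj[key]
    if typ is not None and not isinstance(val, typ):
        raise SchemaError(
            f"{where}: field {key!r} has type {type(val).__name__}, "
            f"expected {typ.__name__}"
        )
    return val


def model_from_dict(doc: dict[str, Any]) -> PathwayModel:
    if not isinstance(doc, dict):
        raise SchemaError("document root must be an object")
    for key in ("pathways", "entities", "reactions"):
        _require(doc, key, list, "document")

    model = PathwayModel()
    for item in doc["entities"]:
        eid = _require(item, "id", str, "entity")
        model.entities[eid] = Entity(
            id=eid,
            name=_require(item, "name", str, f"entity {eid!r}"),
            kind=_require(item, "kind", str, f"entity {eid!r}"),
            components=tuple(item.get("components", [])),
            source_class=item.get("source_class"),
        )
    for item in doc["reactions"]:
        rid = _require(item, "id", str, "reaction")
        model.reactions[rid] = Reaction(
            id=rid,
            inputs=frozenset(_require(item, "inputs", list, f"reaction {rid!r}")),
            outputs=frozenset(_require(item, "outputs", list, f"reaction {rid!r}")),
            pathway_ids=frozenset(
                _require(item, "pathways", list, f"reaction {rid!r}")
            ),
        )
    for item in doc["pathways"]:
        pid = _require(item, "id", str, "pathway")
        parent = item.get("parent")
        if parent is not None and not isinstance(parent, str):
            raise SchemaError(f"pathway {pid!r}: field 'parent' must be a string or null")
        model.pathways[pid] = Pathway(
            id=pid,
            name=_require(item, "name", str, f"pathway {pid!r}"),
            parent_id=parent,
            entity_ids=frozenset(item.get("entities", [])),
            reaction_ids=frozenset(item.get("reactions", [])),
        )

    problems = validate_model(model)
    if problems:
        raise SchemaError("; ".join(sorted(problems)))
    assign_color_indices(model)
    return model


def model_to_dict(model: PathwayModel) -> dict[str, Any]:
    def entity(e: Entity) -> dict:
        d = {
            "id": e.id,
            "name": e.name,
            "kind": e.kind,
            "components": list(e.components),
        }
        if e.source_class is not None:
            d["source_class"] = e.source_class
        return d

    return {
        "entities": [entity(model.entities[k]) for k in sorted(model.entities)],
        "pathways": [
            {
                "id": p.id,
                "name": p.name,
                "parent": p.parent_id,
                "entities": sorted(p.entity_ids),
                "reactions": sorted(p.reaction_ids),
            }
            for p in (model.pathways[k] for k in sorted(model.pathways))
        ],
        "reactions": [
            {
                "id": r.id,
                "inputs": sorted(r.inputs),
                "outputs": sorted(r.outputs),
                "pathways": sorted(r.pathway_ids),
            }
            for r in (model.reactions[k] for k in sorted(model.reactions))
        ],
    }


def read_pathway_json(source: Union[str, IO[str], dict]) -> PathwayModel:
    """Read the JSON dialect from a path, an open file, or a parsed dict."""
    if isinstance(source, dict):
        doc = source
    elif hasattr(source, "read"):
        doc = json.load(source)
    else:
        with open(source, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    return model_from_dict(doc)


def write_pathway_json(model: PathwayModel, dest: Union[str, IO[str], None] = None) -> str:
    """Serialize a model to the canonical dialect text (sorted keys).

    Returns the text; if ``dest`` is a path or an open file, also writes it.
    """
    text = json.dumps(model_to_dict(model), indent=2, sort_keys=True, ensure_ascii=False) + "\n"
    if dest is None:
        return text
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(dest, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
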