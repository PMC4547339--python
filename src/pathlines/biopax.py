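"""BioPAX Level-3 import (subset).

Reads the classes the engine draws — Pathway, BiochemicalReaction,
Protein, Complex — from OWL/XML via an RDF parse.  Other physical
entities (SmallMolecule, Rna, Dna, ...) are imported as protein-shaped
nodes tagged with their source class so real exports stay loadable;
process classes outside the subset (Catalysis, Control, ...) are skipped
and reported, never fatal.  Reaction participants map left -> inputs and
right -> outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import IO, Union

import rdflib
from rdflib.namespace import RDF

from .model import (
    COMPLEX,
    PROTEIN,
    Entity,
    Pathway,
    PathwayModel,
    Reaction,
    validate_model,
    ModelValidationError,
)
from .readwrite import assign_color_indices

__all__ = ["BP", "BiopaxParseError", "ParseReport", "read_biopax"]

BP = rdflib.Namespace("http://www.biopax.org/release/biopax-level3.owl#")

# physical-entity classes tolerated as protein-shaped nodes
_PROTEIN_LIKE = {
    "Protein",
    "SmallMolecule",
    "Rna",
    "Dna",
    "RnaRegion",
    "DnaRegion",
    "PhysicalEntity",
}


class BiopaxParseError(ValueError):
    """The document is not well-formed XML/RDF."""


@dataclass
class ParseReport:
    """What a BioPAX read did: per-class counts, skips, dangling refs."""

    counts: dict[str, int] = field(
        default_factory=lambda: {
            "pathways": 0,
            "proteins": 0,
            "complexes": 0,
            "reactions": 0,
        }
    )
    skipped: list[tuple[str, str]] = field(default_factory=list)
    unresolved: list[str] = field(default_factory=list)


def _local_id(uri: rdflib.term.Node) -> str:
    text = str(uri)
    if "#" in text:
        return text.rsplit("#", 1)[1]
    return text.rstrip("/").rsplit("/", 1)[-1]


def _display_name(g: rdflib.Graph, node: rdflib.term.Node) -> str:
    for prop in (BP.displayName, BP.name, BP.standardName):
        for value in sorted(g.objects(node, prop), key=str):
            if str(value):
                return str(value)
    return _local_id(node)


def read_biopax(
    source: Union[str, bytes, IO]
) -> tuple[PathwayModel, ParseReport]:
    """Parse a BioPAX Level-3 OWL/XML document into a pathway model.

    ``source`` is a path, an open file, or the document text itself.
    Returns the model plus a :class:`ParseReport`.  Raises
    :class:`BiopaxParseError` on malformed XML (message carries the
    parser's line/column) and :class:`ModelValidationError` when complex
    containment is cyclic.
    """
    g = rdflib.Graph()
    try:
        if isinstance(source, bytes):
            g.parse(data=source, format="xml")
        elif isinstance(source, str) and source.lstrip().startswith("<"):
            g.parse(data=source, format="xml")
        else:
            g.parse(source, format="xml")
    except Exception as exc:  # SAXParseException carries line/column in str()
        raise BiopaxParseError(f"malformed BioPAX document: {exc}") from exc

    report = ParseReport()
    model = PathwayModel()

    # First pass: classify every typed bp resource, deterministically.
    typed: dict[str, tuple[rdflib.term.Node, str]] = {}
    for subj, cls in sorted(g.subject_objects(RDF.type), key=lambda t: (str(t[0]), str(t[1]))):
        cls_str = str(cls)
        if not cls_str.startswith(str(BP)):
            continue
        cls_name = cls_str[len(str(BP)):]
        sid = _local_id(subj)
        if sid not in typed:
            typed[sid] = (subj, cls_name)

    entity_ids: set[str] = set()
    for sid, (subj, cls_name) in typed.items():
        if cls_name in _PROTEIN_LIKE:
            model.entities[sid] = Entity(
                id=sid,
                name=_display_name(g, subj),
                kind=PROTEIN,
                source_class=None if cls_name == "Protein" else cls_name,
            )
            entity_ids.add(sid)
            report.counts["proteins"] += 1
        elif cls_name == "Complex":
            entity_ids.add(sid)
            report.counts["complexes"] += 1
        elif cls_name in ("Pathway", "BiochemicalReaction"):
            pass  # second pass
        else:
            report.skipped.append((sid, f"unsupported BioPAX class {cls_name}"))

    def resolve_entity(ref: rdflib.term.Node, ctx: str) -> str | None:
        rid = _local_id(ref)
        if rid in entity_ids:
            return rid
        report.unresolved.append(f"{ctx}: unresolved entity reference {rid!r}")
        return None

    # complexes need entity_ids complete before resolving components
    for sid, (subj, cls_name) in typed.items():
        if cls_name != "Complex":
            continue
        comps = []
        for ref in sorted(g.objects(subj, BP.component), key=str):
            cid = resolve_entity(ref, f"complex {sid!r}")
            if cid is not None:
                comps.append(cid)
        model.entities[sid] = Entity(
            id=sid, name=_display_name(g, subj), kind=COMPLEX,
            components=tuple(comps),
        )

    for sid, (subj, cls_name) in typed.items():
        if cls_name != "BiochemicalReaction":
            continue
        inputs = [
            e for ref in sorted(g.objects(subj, BP.left), key=str)
            if (e := resolve_entity(ref, f"reaction {sid!r}")) is not None
        ]
        outputs = [
            e for ref in sorted(g.objects(subj, BP.right), key=str)
            if (e := resolve_entity(ref, f"reaction {sid!r}")) is not None
        ]
        if not inputs or not outputs:
            report.skipped.append(
                (sid, "reaction with an empty participant side")
            )
            continue
        model.reactions[sid] = Reaction(
            id=sid,
            inputs=frozenset(inputs),
            outputs=frozenset(outputs),
            pathway_ids=frozenset(),
        )
        report.counts["reactions"] += 1

    reaction_owners: dict[str, set[str]] = {rid: set() for rid in model.reactions}
    for sid, (subj, cls_name) in typed.items():
        if cls_name != "Pathway":
            continue
        ents: set[str] = set()
        rids: set[str] = set()
        for ref in sorted(g.objects(subj, BP.pathwayComponent), key=str):
            cid = _local_id(ref)
            if cid in model.reactions:
                rids.add(cid)
                reaction_owners[cid].add(sid)
            elif cid in typed and typed[cid][1] == "Pathway":
                pass  # sub-pathway; parent link set below
            elif cid in entity_ids:
                ents.add(cid)  # lenient direct-membership extension
            else:
                report.unresolved.append(
                    f"pathway {sid!r}: unresolved component {cid!r}"
                )
        for rid in rids:
            ents |= model.reactions[rid].inputs | model.reactions[rid].outputs
        model.pathways[sid] = Pathway(
            id=sid,
            name=_display_name(g, subj),
            entity_ids=frozenset(ents),
            reaction_ids=frozenset(rids),
        )
        report.counts["pathways"] += 1

    # parent links: a sub-pathway referenced from several parents keeps the
    # lexicographically smallest so parent links stay a forest
    child_parents: dict[str, list[str]] = {}
    for sid, (subj, cls_name) in typed.items():
        if cls_name != "Pathway":
            continue
        for ref in sorted(g.objects(subj, BP.pathwayComponent), key=str):
            cid = _local_id(ref)
            if cid in model.pathways and cid != sid:
                child_parents.setdefault(cid, []).append(sid)
    for cid, parents in child_parents.items():
        model.pathways[cid].parent_id = sorted(parents)[0]

    for rid, owners in reaction_owners.items():
        model.reactions[rid] = Reaction(
            id=rid,
            inputs=model.reactions[rid].inputs,
            outputs=model.reactions[rid].outputs,
            pathway_ids=frozenset(owners),
        )

    problems = validate_model(model)  # raises on containment cycles
    for problem in problems:
        report.unresolved.append(problem)
    assign_color_indices(model)
    return model, report
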