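"""Deterministic synthetic pathway-set generator.

Emulates the shape of a cell-cycle "field of interest" — a handful of
top-level pathways whose entity sets overlap, protein complexes with
nested component trees, and reaction networks that are acyclic unless
back-reactions are injected — at any scale, so every stage of the engine
is testable without downloading pathway databases.  Generation is pure
in the seed: two runs with the same config serialize byte-identically.
"""

from __future__ import annotations

import random
import xml.etree.ElementTree as ET
from dataclasses import dataclass
from typing import Optional

from .model import COMPLEX, PROTEIN, Entity, Pathway, PathwayModel, Reaction
from .readwrite import assign_color_indices

__all__ = ["FixtureConfig", "FixtureConfigError", "generate", "write_fixture_biopax"]

_BASE_URI = "http://pathlines.example/fixture"

# a few recognizable DNA-replication names so keyword-filter tests read
# like real sessions; the rest fall back to PROT#### codes
_PROTEIN_NAMES = [
    "ORC1", "ORC2", "ORC3", "ORC4", "ORC5", "ORC6",
    "CDC6", "CDT1", "MCM10", "CDC45", "PCNA", "Ubiquitin",
    "CDK2", "CCNE1", "GMNN", "MCM8",
]
_COMPLEX_NAMES = [
    "preRC", "ORC:origin", "CDC6:ORC:origin", "MCM2-7",
    "Mcm10:preRC", "Mcm10:active preRC", "GINS", "CMG",
]
_PATHWAY_NAMES = [
    "M/G1 Transition",
    "Regulation of DNA Replication",
    "Mitotic G1-G1/S Phases",
    "S Phase",
    "G2/M Checkpoints",
    "M Phase",
]


class FixtureConfigError(ValueError):
    """A fixture parameter is outside its allowed range."""


@dataclass
class FixtureConfig:
    """Knobs for the synthetic field of interest.

    overlap_fraction is the fraction of entities shared by *all*
    pathways; complex_fraction the fraction of entities that are
    complexes; cycle_probability the chance a reaction gets a reversed
    twin, turning the otherwise-acyclic skeleton cyclic.
    """

    n_pathways: int = 6
    n_entities: int = 60
    overlap_fraction: float = 0.2
    complex_fraction: float = 0.25
    max_nesting_depth: int = 3
    n_reactions: int = 50
    max_participants: int = 3
    cycle_probability: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_pathways < 0:
            raise FixtureConfigError("n_pathways must be >= 0")
        if self.n_entities < 0:
            raise FixtureConfigError("n_entities must be >= 0")
        if self.n_reactions < 0:
            raise FixtureConfigError("n_reactions must be >= 0")
        for name in ("overlap_fraction", "complex_fraction", "cycle_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise FixtureConfigError(f"{name} must be in [0, 1], got {v}")
        if self.max_nesting_depth < 1:
            raise FixtureConfigError("max_nesting_depth must be >= 1")
        if self.max_participants < 1:
            raise FixtureConfigError("max_participants must be >= 1")


def generate(config: FixtureConfig) -> PathwayModel:
    """Generate a synthetic model satisfying all domain invariants."""
    config.validate()
    model = PathwayModel()
    if config.n_pathways == 0:
        return model
    rng = random.Random(config.seed)

    n_complexes = round(config.complex_fraction * config.n_entities)
    n_proteins = config.n_entities - n_complexes

    # entity index order doubles as the DAG skeleton's topological order
    depth: dict[int, int] = {}
    eids: list[str] = []
    for i in range(config.n_entities):
        eid = f"e{i:04d}"
        eids.append(eid)
        if i < n_proteins:
            name = (
                _PROTEIN_NAMES[i]
                if i < len(_PROTEIN_NAMES)
                else f"PROT{i:04d}"
            )
            model.entities[eid] = Entity(id=eid, name=name, kind=PROTEIN)
            depth[i] = 0
        else:
            j = i - n_proteins
            name = (
                _COMPLEX_NAMES[j]
                if j < len(_COMPLEX_NAMES)
                else f"CPLX{j:04d}"
            )
            # components come from lower indices only: containment stays a DAG
            pool = [
                k for k in range(i) if depth[k] <= config.max_nesting_depth - 1
            ]
            k_comp = min(len(pool), rng.randint(2, 4)) if pool else 0
            comps = sorted(rng.sample(pool, k_comp)) if k_comp else []
            model.entities[eid] = Entity(
                id=eid,
                name=name,
                kind=COMPLEX,
                components=tuple(eids[k] for k in comps),
            )
            depth[i] = 1 + max((depth[k] for k in comps), default=0)

    pids = [f"p{i:02d}" for i in range(config.n_pathways)]
    pathway_names = [
        _PATHWAY_NAMES[i] if i < len(_PATHWAY_NAMES) else f"Pathway {i}"
        for i in range(config.n_pathways)
    ]

    # membership: a shared core lives in every pathway; the rest are dealt
    # round-robin in a shuffled order so pathway sizes stay balanced
    n_shared = round(config.overlap_fraction * config.n_entities)
    indices = list(range(config.n_entities))
    shared = set(rng.sample(indices, n_shared))
    rest = [i for i in indices if i not in shared]
    rng.shuffle(rest)
    members: dict[str, set[int]] = {pid: set(shared) for pid in pids}
    for slot, i in enumerate(rest):
        members[pids[slot % len(pids)]].add(i)

    # reactions: inputs drawn below a random cut of the owning pathway's
    # entity list, outputs above it, so the skeleton respects index order
    reactions: list[Reaction] = []
    k = 0
    for r in range(config.n_reactions):
        pid = pids[r % len(pids)]
        pool = sorted(members[pid])
        if len(pool) < 2:
            continue
        cut = rng.randint(1, len(pool) - 1)
        lo, hi = pool[:cut], pool[cut:]
        n_in = min(len(lo), rng.randint(1, config.max_participants))
        n_out = min(len(hi), rng.randint(1, config.max_participants))
        inputs = frozenset(eids[i] for i in rng.sample(lo, n_in))
        outputs = frozenset(eids[i] for i in rng.sample(hi, n_out))
        reactions.append(
            Reaction(
                id=f"r{k:04d}",
                inputs=inputs,
                outputs=outputs,
                pathway_ids=frozenset({pid}),
            )
        )
        k += 1

    # cycle injection: reversed twins of existing reactions
    for rx in list(reactions):
        if rng.random() < config.cycle_probability:
            reactions.append(
                Reaction(
                    id=f"r{k:04d}",
                    inputs=rx.outputs,
                    outputs=rx.inputs,
                    pathway_ids=rx.pathway_ids,
                )
            )
            k += 1

    for rx in reactions:
        model.reactions[rx.id] = rx

    for i, pid in enumerate(pids):
        rids = frozenset(
            rx.id for rx in reactions if pid in rx.pathway_ids
        )
        model.pathways[pid] = Pathway(
            id=pid,
            name=pathway_names[i],
            entity_ids=frozenset(eids[j] for j in sorted(members[pid])),
            reaction_ids=rids,
        )

    assign_color_indices(model)
    return model


# ---------------------------------------------------------------------------
# BioPAX fixture writer


def _sub(parent: ET.Element, tag: str, **attrs: str) -> ET.Element:
    return ET.SubElement(parent, tag, dict(sorted(attrs.items())))


def write_fixture_biopax(
    model: PathwayModel, path: Optional[str] = None
) -> str:
    """Serialize a model as a small, valid BioPAX Level-3 OWL document.

    Emits only the supported subset (Protein, Complex,
    BiochemicalReaction, Pathway; displayName / component / left / right
    / pathwayComponent), in sorted-id order so output is byte-stable.
    Reading the result back reproduces the model restricted to that
    subset.
    """
    ET.register_namespace("rdf", "http://www.w3.org/1999/02/22-rdf-syntax-ns#")
    ET.register_namespace("bp", "http://www.biopax.org/release/biopax-level3.owl#")
    RDFNS = "{http://www.w3.org/1999/02/22-rdf-syntax-ns#}"
    BPNS = "{http://www.biopax.org/release/biopax-level3.owl#}"

    root = ET.Element(
        f"{RDFNS}RDF",
        {"{http://www.w3.org/XML/1998/namespace}base": _BASE_URI},
    )

    def name_prop(el: ET.Element, name: str) -> None:
        dn = _sub(el, f"{BPNS}displayName")
        dn.text = name

    for eid in sorted(model.entities):
        e = model.entities[eid]
        if e.kind == PROTEIN:
            el = _sub(root, f"{BPNS}Protein", **{f"{RDFNS}about": f"#{eid}"})
            name_prop(el, e.name)
        else:
            el = _sub(root, f"{BPNS}Complex", **{f"{RDFNS}about": f"#{eid}"})
            name_prop(el, e.name)
            for cid in e.components:
                _sub(el, f"{BPNS}component", **{f"{RDFNS}resource": f"#{cid}"})

    for rid in sorted(model.reactions):
        r = model.reactions[rid]
        el = _sub(
            root, f"{BPNS}BiochemicalReaction", **{f"{RDFNS}about": f"#{rid}"}
        )
        for eid in sorted(r.inputs):
            _sub(el, f"{BPNS}left", **{f"{RDFNS}resource": f"#{eid}"})
        for eid in sorted(r.outputs):
            _sub(el, f"{BPNS}right", **{f"{RDFNS}resource": f"#{eid}"})

    children: dict[str, list[str]] = {}
    for p in model.pathways.values():
        if p.parent_id is not None:
            children.setdefault(p.parent_id, []).append(p.id)

    for pid in sorted(model.pathways):
        p = model.pathways[pid]
        el = _sub(root, f"{BPNS}Pathway", **{f"{RDFNS}about": f"#{pid}"})
        name_prop(el, p.name)
        for rid in sorted(p.reaction_ids):
            _sub(el, f"{BPNS}pathwayComponent", **{f"{RDFNS}resource": f"#{rid}"})
        for cid in sorted(children.get(pid, [])):
            _sub(el, f"{BPNS}pathwayComponent", **{f"{RDFNS}resource": f"#{cid}"})
        # direct entity membership beyond reaction participants
        participants: set[str] = set()
        for rid in p.reaction_ids:
            rx = model.reactions[rid]
            participants |= rx.inputs | rx.outputs
        for eid in sorted(p.entity_ids - participants):
            _sub(el, f"{BPNS}pathwayComponent", **{f"{RDFNS}resource": f"#{eid}"})

    ET.indent(root)
    text = (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        + ET.tostring(root, encoding="unicode")
        + "\n"
    )
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text
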