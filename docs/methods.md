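# Methods

## Graph model

A pathway is a named set of entities and reactions, optionally nested
under a parent pathway.  Reactions are hyperedges; for drawing and
topology they are lowered to binary *reaction relationships*: edge
(A, B, P) exists iff pathway P owns at least one reaction with A among
its inputs and B among its outputs.  Consequences of that definition,
and the choices made where it is silent:

- **Cartesian lowering.** A reaction with m inputs and n outputs yields
  every input–output pair: m·n edges when the sides are disjoint.
- **Self-pairs dropped.** An entity appearing on both sides of a
  reaction produces no (A, A) edge; a self-loop has no meaningful
  sharp-tip depiction and the lowering is about flow between distinct
  participants.
- **Within-pathway deduplication.** "At least one reaction" makes the
  edge a predicate, so several reactions lowering to the same
  (source, target, pathway) triple collapse to one edge.  The map from
  each edge to its originating reaction ids is kept
  (`PathwayGraph.edge_reactions`) because distinct edges frequently
  share a biological reaction and downstream tools may want that
  provenance.
- **No node duplication.** Identifier equality is exact string equality
  of ids; an entity referenced by any number of pathways is one vertex.
  Name-based merging across databases is out of scope.
- **Sub-pathway aggregation.** An entity or edge belonging to
  sub-pathway S also counts as a member of every ancestor of S.  The
  rendered membership of an element is the set of *visible* pathways it
  belongs to under this closure, so collapsing a sub-pathway in the
  pathway list reassigns its elements to the visible ancestor's color.
  This mirrors expand/collapse behaviour in pathway lists; the
  alternative (sub-pathway elements disappear when only the parent is
  selected) would make parents look emptier than their own definition.

Edge lanes: edges between one unordered node pair group into
side-by-side lanes, one per pathway.  A pathway with edges in both
directions collapses to a single lane tipped at both ends.  Lanes are
ordered by (pathway color index, pathway id) — a deterministic order so
repeated renders are byte-identical.

## Serialization

The JSON dialect (top-level `pathways` / `entities` / `reactions`,
sorted keys and id lists) is the canonical format; write∘read is the
identity and the output is byte-stable.  BioPAX Level 3 is an import
path covering Pathway, BiochemicalReaction (left → inputs, right →
outputs), Protein and Complex with nested components.  Other physical
entities (SmallMolecule, Rna, Dna, …) import as protein-shaped nodes
tagged with their source class so real exports load; process classes
outside the subset (Catalysis, Control, …) are skipped and listed in
the parse report, never fatal.  Display names prefer `displayName`,
then `name`, then the RDF id fragment.  Since BioPAX has no direct
pathway→entity membership list, the reader derives a pathway's entity
set from its reactions' participants and additionally accepts
`pathwayComponent` references to physical entities (which the fixture
writer emits for members not witnessed by any reaction); standard files
simply never use that extension.  A sub-pathway referenced from several
parents keeps the lexicographically smallest parent so parent links
stay a forest.

## Layout

The paper-level requirement is a top-to-bottom flow matching edge
direction where possible, with cycles forcing some upward edges.  A
pure force simulation cannot guarantee that, so the layout is a layered
(Sugiyama-style) skeleton with a force phase inside layers:

1. **Feedback arcs.** The greedy Eades linear-arrangement heuristic
   (peel sinks right, sources left, otherwise move the vertex with
   maximal out-degree − in-degree) gives a vertex order whose backward
   arcs form the feedback set; the heuristic guarantees at most |E|/2
   backward arcs and is fully deterministic (ties break by ascending
   node id).  On a 3-cycle it finds the optimum, one feedback edge.
2. **Layers.** Longest-path layering of the graph with feedback arcs
   reversed; every non-feedback edge then points strictly downward.
3. **Horizontal refinement.** Barycenter sweeps (default 4, alternating
   direction) reorder each layer toward the mean x of graph
   neighbours; a sweep that would increase the measured straight-line
   crossing count is rolled back, so the phase never worsens crossings.
   A subsequent force relaxation (default 30 iterations, step 0.3)
   pulls nodes toward their neighbourhood barycenter with a small
   seeded jitter (±0.5 units) to escape ties; nodes without neighbours
   never move, so a lone node stays at the origin.  A final pass
   enforces the minimum within-layer separation (default 40 units,
   preserving each layer's centroid).
4. **Lanes.** Lane polylines sit at symmetric offsets
   (i − (k−1)/2)·spacing (default 6 units) about the pair's centerline;
   tips go at the target end (forward), source end (backward) or both.

Defaults: layer gap 60, node separation 40, lane spacing 6 abstract
units — chosen so default glyph sizes (radius 9, square side 16, ring
width 3) cannot collide at adjacent positions.  Crossing counting uses
proper segment intersection (orientation tests) over group centerlines,
excluding pairs that share an endpoint.  All randomness enters through
one seed; given (graph, params, seed) the serialized layout and the SVG
are byte-identical across runs.

## Complex hierarchy views

The symbolic overview packs a complex's containment tree with a
deterministic near-square grid ("shelf") layout per nesting level:
sizes are computed bottom-up (a protein is a fixed dot cell, a complex
a padded grid of its children), geometry placed top-down.  The
rectangle-packing requirement says nothing about the packing algorithm;
the grid was chosen for byte-stable output over aesthetic optimality.
Nested complexes use one hue at two alternating intensities and the
selected element turns gray; the overview carries no labels — labels
live in the pruned tree.

The pruned tree shows the chain from the root to the selected element's
parent plus all of that parent's components, in model (file) order —
the source order is the curator's order and any re-sorting would need a
criterion the data does not supply.  Selecting the root returns a
degenerate view (empty chain, root as sole child) rather than erroring,
so hover sweeps over every element are total.  An entity contained
along several paths is highlighted at every geometric instance in the
overview, but the pruned tree reports the lexicographically first
containment path — one canonical answer instead of an arbitrary one.

## Interaction queries

All queries are pure: (graph, view) → result, with state changes
returned as explicit deltas.  Notable semantics:

- **Keyword filter** is case-insensitive substring match — the loose
  queries these sessions use ("ORC1-6", "Ubiquitin") are substrings,
  not tokens or regexes.  A complex matches via its own name or any
  transitively contained *protein* name (not nested sub-complex names).
  An empty keyword list disables the filter; hiding everything on an
  empty query would make the initial state unusable.
- **Visibility** is "member of at least one visible pathway" under the
  sub-pathway closure, intersected with revealed elements and the
  keyword filter; edges additionally need both endpoints visible.
- **Upstream/downstream steps** add all visible-pathway edges ending
  at/starting from a node plus their far endpoints; triangle markers
  flag nodes that still have unrevealed steps.
- **Intermediate steps** between s and t keep exactly the nodes
  reachable from s from which t is still reachable, plus visible edges
  inside that set.  On DAGs this equals the union of all simple
  s→t paths (verified against exhaustive enumeration); on cyclic graphs
  it additionally includes cycle nodes lying between the endpoints —
  the inclusive reading, computable in linear time, whereas
  simple-path enumeration is exponential.

## Rendering

SVG 1.1 via the standard library XML tree, attributes and element
order fully determined by the model, so output is byte-stable.
Membership borders are concentric rings (innermost = first pathway by
color index) — unambiguous and order-stable where side-by-side arcs
would need an angular convention.  The default palette has 8
qualitative colors; more simultaneously visible top-level pathways than
colors logs a warning and recycles.  Desaturation is a fixed light
gray rather than per-color HSL manipulation, for determinism.  Labels
are hidden unless a hover target is set (then only same-pathway nodes
are labeled) or `always_label` / `--always-label` is on.  Labels are
placed right of their node with no collision avoidance.  Enlarged
complexes are drawn as their packed overview scaled to a fixed size;
neighbours within the clearance radius are pushed radially outward to
the clearance distance.

## Synthetic generator

The generator emulates a cell-cycle-style field of interest: defaults
of 6 top-level pathways, 60 entities (25 % complexes, nesting depth
≤ 3), 50 reactions with up to 3 participants per side, 20 % of entities
shared by all pathways, and a 5 % back-reaction rate — a desk-scale
version of a session with half a dozen related pathways.  Entity names
draw from a small DNA-replication vocabulary (ORC1–6, CDC6, preRC,
MCM2-7, …) then fall back to PROT####/CPLX#### codes, so keyword
sessions read naturally.  Entity index order doubles as a global
topological order: reaction inputs draw from below a random cut of the
owning pathway's entity list and outputs from above it, making the
skeleton provably acyclic; cycles are injected afterwards as reversed
twin reactions, so `cycle_probability=0` guarantees a DAG and the
expected number of back-reactions is directly controllable.  Generation
is pure in the seed.

What the generator does *not* emulate: realistic degree distributions,
stoichiometry, compartments, reaction reversibility flags, or the
actual content of any database.  Passing tests therefore demonstrate
the engine's graph/layout/query/render semantics, not fidelity to any
particular curated pathway.

## Known limitations

- BioPAX coverage is the four-class subset; Control/Catalysis semantics,
  cellular locations and stoichiometry are ignored (reported as
  skipped, never fatal).
- Crossing minimization is heuristic; optimal crossing minimization is
  NP-hard and out of scope.
- The intermediate-steps query can reveal large subgraphs on dense
  inputs; path-metric or shortest-path-only filtering is deliberately
  not implemented.
- The engine is static: it computes the *result* of each interaction as
  a new view state and renders it; live mouse handling, zoom/pan and
  undo belong to a front end built on top.

## Problem sizes

The test suite and the acceptance script run the pipeline at fixture
scale: up to 10 pathways and 200 entities for the merge/dedup checks
(30 random configurations), 100 random DAGs of ≤ 12 nodes for the
exhaustive path-enumeration oracle, 30 fixtures for serialization
round-trips, and 5 full render/layout runs for conservation and
determinism — sizes at which every brute-force oracle is exact and the
whole suite completes in a few seconds.
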