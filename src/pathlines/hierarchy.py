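"""Coordinated hierarchical views of a protein complex.

Two depictions work together: a *symbolic overview* — an unlabeled
rectangle-packed miniature in which squares are complexes and dots are
the proteins inside them — and a *pruned tree* that shows, for one
selected element, only the chain of containing complexes from the root
down to the selected element's parent plus all of that parent's
children, with labels.  The overview gives structure at a glance; the
pruned tree carries the names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .model import COMPLEX, PROTEIN, PathwayModel, UnknownIdError

__all__ = [
    "Rect",
    "Dot",
    "PackedItem",
    "PackedOverview",
    "PrunedTreeView",
    "pack_overview",
    "prune_tree",
    "occurrences",
]

# abstract units; the renderer scales to screen coordinates
DOT_RADIUS = 1.0
PADDING = 1.0
GAP = 0.5


@dataclass(frozen=True)
class Rect:
    x: float
    y: float
    w: float
    h: float

    def contains(self, other: "Rect", strict: bool = True) -> bool:
        eps = 1e-9
        return (
            self.x < other.x + eps
            and self.y < other.y + eps
            and other.x + other.w < self.x + self.w + eps
            and other.y + other.h < self.y + self.h + eps
        )

    def overlaps(self, other: "Rect") -> bool:
        return not (
            self.x + self.w <= other.x
            or other.x + other.w <= self.x
            or self.y + self.h <= other.y
            or other.y + other.h <= self.y
        )


@dataclass(frozen=True)
class Dot:
    cx: float
    cy: float
    r: float

    @property
    def bounds(self) -> Rect:
        return Rect(self.cx - self.r, self.cy - self.r, 2 * self.r, 2 * self.r)


@dataclass(frozen=True)
class PackedItem:
    """One geometric instance inside the overview.

    An entity contained along two paths appears as two items; ``parent``
    is the containing complex of this instance (None for the root).
    """

    entity_id: str
    kind: str
    geometry: object  # Rect for complexes, Dot for proteins
    depth: int
    parent: Optional[str]

    @property
    def bounds(self) -> Rect:
        return self.geometry.bounds if isinstance(self.geometry, Dot) else self.geometry


@dataclass
class PackedOverview:
    root: Rect
    items: list[PackedItem] = field(default_factory=list)


@dataclass(frozen=True)
class PrunedTreeView:
    """Chain from the root to the selected element's parent, plus that
    parent's children in model order, with the selection flagged."""

    chain: tuple[str, ...]
    children: tuple[str, ...]
    selected: str


def _grid_shape(n: int) -> tuple[int, int]:
    """Near-square (cols, rows) grid able to hold n cells."""
    if n == 0:
        return (0, 0)
    cols = 1
    while cols * cols < n:
        cols += 1
    rows = (n + cols - 1) // cols
    return cols, rows


def pack_overview(root_id: str, model: PathwayModel) -> PackedOverview:
    """Deterministic shelf packing of a complex's containment tree.

    Sizes are computed bottom-up (a protein occupies a fixed dot cell, a
    complex a padded near-square grid of its children) and geometry is
    placed top-down, so identical trees always pack identically.  Chosen
    for byte-stable output over aesthetic optimality.
    """
    if root_id not in model.entities:
        raise UnknownIdError(f"unknown entity id {root_id!r}")
    root = model.entities[root_id]
    if root.kind != COMPLEX:
        raise TypeError(
            f"pack_overview requires a complex root, got {root.kind} {root_id!r}"
        )

    def size_of(eid: str) -> tuple[float, float]:
        e = model.entities[eid]
        if e.kind == PROTEIN:
            d = 2 * DOT_RADIUS
            return (d, d)
        if not e.components:
            d = 2 * DOT_RADIUS + 2 * PADDING
            return (d, d)
        sizes = [size_of(cid) for cid in e.components]
        cols, rows = _grid_shape(len(sizes))
        col_w = [0.0] * cols
        row_h = [0.0] * rows
        for idx, (w, h) in enumerate(sizes):
            c, r = idx % cols, idx // cols
            col_w[c] = max(col_w[c], w)
            row_h[r] = max(row_h[r], h)
        width = sum(col_w) + GAP * (cols - 1) + 2 * PADDING
        height = sum(row_h) + GAP * (rows - 1) + 2 * PADDING
        return (width, height)

    overview = PackedOverview(root=Rect(0.0, 0.0, *size_of(root_id)))

    def place(eid: str, x: float, y: float, depth: int, parent: Optional[str]) -> None:
        e = model.entities[eid]
        w, h = size_of(eid)
        if e.kind == PROTEIN:
            geom: object = Dot(x + w / 2, y + h / 2, DOT_RADIUS)
        else:
            geom = Rect(x, y, w, h)
        overview.items.append(
            PackedItem(entity_id=eid, kind=e.kind, geometry=geom, depth=depth, parent=parent)
        )
        if e.kind == COMPLEX and e.components:
            sizes = [size_of(cid) for cid in e.components]
            cols, rows = _grid_shape(len(sizes))
            col_w = [0.0] * cols
            row_h = [0.0] * rows
            for idx, (cw, ch) in enumerate(sizes):
                c, r = idx % cols, idx // cols
                col_w[c] = max(col_w[c], cw)
                row_h[r] = max(row_h[r], ch)
            cy = y + PADDING
            for r in range(rows):
                cx = x + PADDING
                for c in range(cols):
                    idx = r * cols + c
                    if idx >= len(e.components):
                        break
                    place(e.components[idx], cx, cy, depth + 1, eid)
                    cx += col_w[c] + GAP
                cy += row_h[r] + GAP

    place(root_id, 0.0, 0.0, 0, None)
    return overview


def _paths_to(
    model: PathwayModel, root_id: str, target_id: str
) -> list[tuple[str, ...]]:
    """All containment paths root -> target, each including both ends."""
    out: list[tuple[str, ...]] = []

    def walk(eid: str, path: tuple[str, ...]) -> None:
        path = path + (eid,)
        if eid == target_id:
            # containment is acyclic, so the target never recurs below itself
            out.append(path)
            return
        e = model.entities.get(eid)
        if e is not None:
            for cid in e.components:
                walk(cid, path)

    walk(root_id, ())
    return sorted(out)


def prune_tree(
    root_id: str, selected_id: str, model: PathwayModel
) -> PrunedTreeView:
    """The labeled detail view for a selection inside a complex.

    ``chain`` runs from the root down to the *parent* of the selected
    element; ``children`` are every direct component of that parent in
    model order.  Selecting the root itself yields the degenerate view
    (empty chain, the root as sole child) so hover sweeps are total.
    When the selection is contained along several paths the
    lexicographically first one is reported.
    """
    if root_id not in model.entities:
        raise UnknownIdError(f"unknown entity id {root_id!r}")
    if selected_id == root_id:
        return PrunedTreeView(chain=(), children=(root_id,), selected=root_id)
    paths = _paths_to(model, root_id, selected_id)
    if not paths:
        raise UnknownIdError(
            f"entity {selected_id!r} is not contained in {root_id!r}"
        )
    path = paths[0]
    parent = path[-2]
    return PrunedTreeView(
        chain=path[:-1],
        children=tuple(model.entities[parent].components),
        selected=selected_id,
    )


def occurrences(
    enlarged_roots: list[str], component_id: str, model: PathwayModel
) -> list[tuple[str, tuple[str, ...]]]:
    """Find a component in every enlarged complex that contains it.

    Returns one (root id, witness path) record per containing root, the
    path being the lexicographically first containment chain from root
    to component.  Hovering a sub-complex thus highlights it in all
    enlarged complexes at once.
    """
    out = []
    for rid in enlarged_roots:
        if rid not in model.entities:
            continue
        paths = _paths_to(model, rid, component_id)
        if paths:
            out.append((rid, paths[0]))
    return out
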