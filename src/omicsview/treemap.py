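"""Nested-rectangle (treemap) layout for pathway and ontology hierarchies.

The view rectangle is subdivided into compartment rectangles, which are in
turn subdivided into pathway (or GO-term) rectangles whose areas are
proportional to the number of entities they hold.  Subdivision uses the
squarified heuristic: children are processed in descending weight order and
greedily packed into rows so that rectangle aspect ratios stay close to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chunking import (IconGroup, PackingPlan, compartment_capacity,
                       group_entities, place_icons, solve_group_size)
from .data_io import AnnotationCatalog, CellLayout, Rect
from .errors import ValidationError
from .values import ColorScale, ValueVector

DEFAULT_INNER_PAD = 4.0


@dataclass
class TreeNode:
    """A weighted hierarchy node; leaves may carry the entity ids they hold."""

    name: str
    weight: float
    children: list["TreeNode"] = field(default_factory=list)
    fill: str | None = None
    highlight: bool = False
    entities: tuple[str, ...] | None = None  # leaves only

    def __post_init__(self):
        if self.weight < 0:
            raise ValidationError(f"node {self.name!r} has negative weight")
        if self.children:
            s = sum(c.weight for c in self.children)
            if abs(s - self.weight) > 1e-9 * max(abs(s), 1.0):
                raise ValidationError(
                    f"node {self.name!r}: weight {self.weight} != child sum {s}"
                )


def internal(name: str, children: list[TreeNode], fill: str | None = None) -> TreeNode:
    """Internal node whose weight is the sum of its children."""
    return TreeNode(name, sum(c.weight for c in children), children=children, fill=fill)


@dataclass
class LaidOutNode:
    node: TreeNode
    rect: Rect
    depth: int


# ---------------------------------------------------------------------------
# tree construction
# ---------------------------------------------------------------------------

def build_pathway_tree(catalog: AnnotationCatalog, v: ValueVector,
                       layout: CellLayout | None = None) -> TreeNode:
    """Root -> compartments -> (pathway, compartment) leaves.

    A leaf's weight is the number of displayed entities annotated to its
    pathway; an entity in m pathways, each spanning k compartments, appears
    in all m*k leaves.  Pathways with no displayed entity are omitted.
    Compartment fills reuse the cell-layout palette so the two views read
    alike.
    """
    displayed = set(v.entity_ids)
    pathway_members: dict[str, list[str]] = {}
    for ent in v.entity_ids:  # keep vector order for determinism
        for pw in catalog.entity_pathways.get(ent, ()):  # may be unannotated
            pathway_members.setdefault(pw, []).append(ent)

    comp_children: dict[str, list[TreeNode]] = {}
    for pw in sorted(pathway_members):
        members = pathway_members[pw]
        for comp in sorted(catalog.pathway_compartments[pw]):
            comp_children.setdefault(comp, []).append(
                TreeNode(pw, float(len(members)), entities=tuple(members))
            )

    comp_order = list(layout.names) if layout is not None else []
    comp_order += sorted(set(comp_children) - set(comp_order))
    children = []
    for comp in comp_order:
        if comp not in comp_children:
            continue
        fill = None
        if layout is not None and comp in layout.names:
            fill = layout.fill(comp)
        children.append(internal(comp, comp_children[comp], fill=fill))
    return internal("pathways", children)


# ---------------------------------------------------------------------------
# squarified subdivision
# ---------------------------------------------------------------------------

def _worst(row: list[float], length: float) -> float:
    """Worst aspect ratio if ``row`` (areas) forms one strip of side length."""
    s = sum(row)
    return max((length * length * max(row)) / (s * s),
               (s * s) / (length * length * min(row)))


def _layout_row(row: list[float], free: Rect) -> tuple[list[Rect], Rect]:
    """Place one strip of areas along the shorter side of ``free``."""
    s = sum(row)
    rects = []
    if free.w >= free.h:  # vertical strip on the left
        strip_w = s / free.h
        y = free.y
        for a in row:
            h = a / strip_w
            rects.append(Rect(free.x, y, strip_w, h))
            y += h
        remaining = Rect(free.x + strip_w, free.y, free.w - strip_w, free.h)
    else:  # horizontal strip on top
        strip_h = s / free.w
        x = free.x
        for a in row:
            w = a / strip_h
            rects.append(Rect(x, free.y, w, strip_h))
            x += w
        remaining = Rect(free.x, free.y + strip_h, free.w, free.h - strip_h)
    return rects, remaining


def squarify(areas: list[float], rect: Rect) -> list[Rect]:
    """Tile ``rect`` with sub-rectangles of the given areas (already scaled
    to sum to rect.area), in order, using the squarified row heuristic."""
    if not areas:
        return []
    out: list[Rect] = []
    free = rect
    row: list[float] = []
    i = 0
    while i < len(areas):
        a = areas[i]
        length = min(free.w, free.h)
        if not row or _worst(row + [a], length) <= _worst(row, length):
            row.append(a)
            i += 1
        else:
            rects, free = _layout_row(row, free)
            out.extend(rects)
            row = []
    rects, _ = _layout_row(row, free)
    out.extend(rects)
    return out


def layout(root: TreeNode, canvas: Rect,
           inner_pad: float = DEFAULT_INNER_PAD) -> list[LaidOutNode]:
    """Recursive squarified layout of the whole tree.

    At each level children are sorted by descending weight (name tiebreak)
    and tile the parent's interior — the parent rectangle shrunk by
    ``inner_pad`` on every side — with areas proportional to weights.
    Zero-weight nodes must have been pruned before layout.
    """
    if root.weight <= 0:
        raise ValidationError("layout needs a tree with positive total weight")
    out: list[LaidOutNode] = []

    def recurse(node: TreeNode, rect: Rect, depth: int):
        out.append(LaidOutNode(node, rect, depth))
        if not node.children:
            return
        interior = rect.shrink(inner_pad)
        if interior.w <= 0 or interior.h <= 0:
            raise ValidationError(
                f"rectangle for {node.name!r} too small for inner padding "
                f"{inner_pad}; use a smaller --inner-pad"
            )
        kids = sorted(node.children, key=lambda c: (-c.weight, c.name))
        for c in kids:
            if c.weight <= 0:
                raise ValidationError(
                    f"zero-weight node {c.name!r} must be pruned before layout"
                )
        scale = interior.area / node.weight
        areas = [c.weight * scale for c in kids]
        rects = squarify(areas, interior)
        for child, r in zip(kids, rects):
            recurse(child, r, depth + 1)

    recurse(root, canvas, 0)
    return out


def slice_and_dice(areas: list[float], rect: Rect, depth: int = 0) -> list[Rect]:
    """Alternating-direction proportional slicing; the classic baseline the
    squarified heuristic is compared against."""
    out = []
    total = sum(areas)
    offset = 0.0
    for a in areas:
        frac = a / total
        if depth % 2 == 0:
            out.append(Rect(rect.x + offset * rect.w, rect.y, frac * rect.w, rect.h))
        else:
            out.append(Rect(rect.x, rect.y + offset * rect.h, rect.w, frac * rect.h))
        offset += frac
    return out


def worst_aspect(rects: list[Rect]) -> float:
    return max(max(r.w / r.h, r.h / r.w) for r in rects)


# ---------------------------------------------------------------------------
# icons inside leaves
# ---------------------------------------------------------------------------

def place_leaf_icons(leaves: list[LaidOutNode], v: ValueVector,
                     icon_size: float, padding: float,
                     scale: ColorScale | None = None,
                     max_per_icon: int | None = None,
                     ) -> tuple[dict[int, list[IconGroup]], "PackingPlan"]:
    """Chunk and place icons inside laid-out leaf rectangles.

    The entities of each leaf come from its TreeNode; a single view-wide
    group size is solved across all leaves exactly as across cell
    compartments.  Returns groups keyed by leaf index plus the solved plan.
    """
    displayed = set(v.entity_ids)
    leaf_entities: dict[int, list[str]] = {}
    counts: dict[str, int] = {}
    caps: dict[str, int] = {}
    for i, ln in enumerate(leaves):
        ents = [e for e in (ln.node.entities or ()) if e in displayed]
        leaf_entities[i] = ents
        counts[str(i)] = len(ents)
        caps[str(i)] = compartment_capacity(ln.rect, icon_size, padding)
    plan = solve_group_size(counts, caps, icon_size)
    if max_per_icon is not None and max_per_icon < plan.g:
        raise ValidationError(
            f"--max-per-icon {max_per_icon} is below the minimal feasible "
            f"group size {plan.g} for this view"
        )
    groups_by_leaf: dict[int, list[IconGroup]] = {}
    for i, ln in enumerate(leaves):
        if not leaf_entities[i]:
            groups_by_leaf[i] = []
            continue
        sub = v.restrict(leaf_entities[i])
        groups = group_entities(sub, plan.g, scale)
        groups_by_leaf[i] = place_icons(groups, ln.rect, icon_size, padding)
    return groups_by_leaf, plan
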