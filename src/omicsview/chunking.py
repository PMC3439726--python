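"""Dynamic chunking: decide how many entities one icon stands for, group
entities into icons, and place icons on a grid inside a region.

The group size g is solved once per view as the smallest integer letting
every compartment display all of its entities within its region; a single
entity draws as a disc, a multi-entity group as a rectangle, and within a
compartment icons run from low (light) to high (dark) value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .data_io import Rect
from .errors import ValidationError
from .values import ColorScale, ValueVector, bin_index

DEFAULT_ICON_SIZE = 8.0
DEFAULT_PADDING = 2.0


@dataclass
class IconGroup:
    """One drawable icon: a run of value-adjacent entities and their mean."""

    member_entities: list[str]
    representative_value: float
    shape: str  # "disc" | "rectangle"
    bin: int | None = None
    position: tuple[float, float] | None = None  # top-left, canvas units

    def __post_init__(self):
        if not self.member_entities:
            raise ValidationError("an icon group needs at least one member")
        expected = "disc" if len(self.member_entities) == 1 else "rectangle"
        if self.shape != expected:
            raise ValidationError(
                f"shape {self.shape!r} inconsistent with {len(self.member_entities)} members"
            )


@dataclass
class PackingPlan:
    """The solved view-wide packing: group size plus per-region capacities."""

    g: int
    icon_size: float
    capacities: dict[str, int]

    def __post_init__(self):
        if self.g < 1:
            raise ValidationError("group size must be >= 1")


def compartment_capacity(region: Rect, icon_size: float, padding: float) -> int:
    """How many icons fit on the region's grid.

    Icons occupy cells of side ``icon_size + padding`` inside the region
    shrunk by ``padding`` on every edge; capacity is the full-grid count and
    is never negative.
    """
    if icon_size <= 0:
        raise ValidationError("icon size must be positive")
    cell = icon_size + padding
    usable_w = region.w - 2 * padding
    usable_h = region.h - 2 * padding
    if usable_w <= 0 or usable_h <= 0:
        return 0
    return max(int(math.floor(usable_w / cell)), 0) * max(int(math.floor(usable_h / cell)), 0)


def solve_group_size(counts: dict[str, int], capacities: dict[str, int],
                     icon_size: float = DEFAULT_ICON_SIZE) -> PackingPlan:
    """Smallest g such that every region can hold ceil(n/g) icons.

    g = max over regions of ceil(n_c / cap_c); a populated region with zero
    capacity is unsatisfiable at any g.
    """
    g = 1
    for name, n in counts.items():
        if n <= 0:
            continue
        cap = capacities.get(name, 0)
        if cap <= 0:
            raise ValidationError(
                f"compartment {name!r} holds {n} entities but has zero icon "
                "capacity (icon size too large for its region)"
            )
        g = max(g, -(-n // cap))
    return PackingPlan(g=g, icon_size=icon_size, capacities=dict(capacities))


def group_entities(v: ValueVector, g: int,
                   scale: ColorScale | None = None) -> list[IconGroup]:
    """Sort entities ascending by value (ties by id) and chunk into runs of g.

    Each group's representative value is the arithmetic mean of its members;
    its color bin comes from the representative on the shared scale.
    """
    if g < 1:
        raise ValidationError("group size must be >= 1")
    order = sorted(range(len(v)), key=lambda i: (v.v[i], v.entity_ids[i]))
    groups: list[IconGroup] = []
    for start in range(0, len(order), g):
        idx = order[start:start + g]
        members = [v.entity_ids[i] for i in idx]
        rep = float(sum(v.v[i] for i in idx) / len(idx))
        groups.append(IconGroup(
            member_entities=members,
            representative_value=rep,
            shape="disc" if len(members) == 1 else "rectangle",
            bin=None if scale is None else bin_index(scale, rep),
        ))
    return groups


def place_icons(groups: list[IconGroup], region: Rect, icon_size: float,
                padding: float) -> list[IconGroup]:
    """Assign grid positions row-major (left-to-right, top-to-bottom).

    Positions are the icon's top-left corner; overflow beyond the region's
    capacity is an error (the solved group size prevents it in the pipeline).
    """
    cap = compartment_capacity(region, icon_size, padding)
    if len(groups) > cap:
        raise ValidationError(
            f"{len(groups)} icons exceed region capacity {cap}"
        )
    cell = icon_size + padding
    cols = max(int(math.floor((region.w - 2 * padding) / cell)), 1)
    for i, grp in enumerate(groups):
        r, c = divmod(i, cols)
        grp.position = (region.x + padding + c * cell, region.y + padding + r * cell)
    return groups
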