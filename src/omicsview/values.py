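"""Per-sample value extraction, two-sample comparison statistics,
min-value filtering, and the value -> color mapping.

The color encoding uses the sequential ColorBrewer YlOrRd ramp (light
yellow through orange to dark red); by default higher values get darker
colors, and the scale range adapts automatically to the displayed values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .data_io import ExpressionDataset
from .errors import ValidationError

log = logging.getLogger(__name__)

COMPARISON_MODES = ("difference", "fold", "difference_fold")

# 9-class ColorBrewer YlOrRd, lightest first.
YLORRD9 = (
    "#FFFFCC", "#FFEDA0", "#FED976", "#FEB24C", "#FD8D3C",
    "#FC4E2A", "#E31A1C", "#BD0026", "#800026",
)


@dataclass
class ValueVector:
    """The displayed quantity for one sample or one two-sample comparison.

    Entries are always present (missing values are filtered out upstream);
    ``n_excluded_zero_denom`` counts entities dropped by a zero denominator
    in fold / difference-fold comparisons.
    """

    entity_ids: list[str]
    v: np.ndarray
    label: str = ""
    n_excluded_zero_denom: int = 0

    def __post_init__(self):
        self.v = np.asarray(self.v, dtype=float)
        if self.v.shape != (len(self.entity_ids),):
            raise ValidationError("value vector length does not match entity ids")
        if np.isnan(self.v).any():
            raise ValidationError("value vector contains missing entries")

    def __len__(self) -> int:
        return len(self.entity_ids)

    def restrict(self, entities) -> "ValueVector":
        """Sub-vector over the given entity set, original order kept."""
        wanted = set(entities)
        idx = [i for i, e in enumerate(self.entity_ids) if e in wanted]
        return ValueVector(
            [self.entity_ids[i] for i in idx], self.v[idx], label=self.label
        )

    def value_of(self, entity: str) -> float:
        return float(self.v[self.entity_ids.index(entity)])


@dataclass
class ColorScale:
    """Maps real values onto discrete palette bins.

    Values at or below ``vmin`` saturate into bin 0 and values at or above
    ``vmax`` into the top bin, so a user-narrowed range simply clips.  A
    degenerate scale (vmin == vmax) sends everything to the middle bin.
    """

    vmin: float
    vmax: float
    n_bins: int = 9
    palette_id: str = "YlOrRd"
    reversed: bool = False

    def __post_init__(self):
        if self.vmin > self.vmax:
            raise ValidationError(f"vmin {self.vmin} > vmax {self.vmax}")
        if self.n_bins < 2:
            raise ValidationError("a color scale needs at least 2 bins")

    def key(self) -> tuple:
        return (self.vmin, self.vmax, self.n_bins, self.palette_id, self.reversed)


def extract_sample(ds: ExpressionDataset, sample: str) -> ValueVector:
    """Column extraction for one sample, skipping missing values."""
    j = ds.sample_index(sample)
    col = ds.values[:, j]
    keep = ~np.isnan(col)
    if not keep.any():
        log.warning("sample %r has no present values", sample)
    ids = [e for e, k in zip(ds.entity_ids, keep) if k]
    return ValueVector(ids, col[keep], label=sample)


def compare_samples(ds: ExpressionDataset, a: str, b: str, mode: str) -> ValueVector:
    """Two-sample comparison statistic per entity.

    * ``difference``       v_a - v_b
    * ``fold``             v_a / v_b
    * ``difference_fold``  (v_a - v_b) / v_b

    Entities missing in either sample are skipped; entities with v_b == 0
    under the two ratio modes are excluded and tallied.
    """
    if a == b:
        raise ValidationError(f"comparison needs two distinct samples, got {a!r} twice")
    if mode not in COMPARISON_MODES:
        raise ValidationError(
            f"unknown comparison mode {mode!r}; choose from {', '.join(COMPARISON_MODES)}"
        )
    ja, jb = ds.sample_index(a), ds.sample_index(b)
    va, vb = ds.values[:, ja], ds.values[:, jb]
    present = ~np.isnan(va) & ~np.isnan(vb)
    excluded = 0
    if mode in ("fold", "difference_fold"):
        zero = present & (vb == 0.0)
        excluded = int(zero.sum())
        if excluded:
            log.info("comparison %s/%s: excluded %d entities with zero denominator",
                     a, b, excluded)
        present &= vb != 0.0
    ids = [e for e, k in zip(ds.entity_ids, present) if k]
    va, vb = va[present], vb[present]
    if mode == "difference":
        out = va - vb
    elif mode == "fold":
        out = va / vb
    else:
        out = (va - vb) / vb
    return ValueVector(ids, out, label=f"{a} vs {b} ({mode})",
                       n_excluded_zero_denom=excluded)


def filter_min_value(ds: ExpressionDataset, threshold: float) -> ExpressionDataset:
    """Keep entities whose maximum present value is strictly above threshold.

    This mirrors the common pre-filter "values over T in at least one
    sample"; rows that are all-missing never pass.
    """
    with np.errstate(invalid="ignore"):
        present = ~np.isnan(ds.values)
        mx = np.where(present.any(axis=1),
                      np.nanmax(np.where(present, ds.values, -np.inf), axis=1),
                      -np.inf)
    keep = mx > threshold
    if not keep.any():
        raise ValidationError(
            f"min-value filter at {threshold} removes every entity"
        )
    ids = [e for e, k in zip(ds.entity_ids, keep) if k]
    return ExpressionDataset(ids, list(ds.sample_ids), ds.values[keep])


def auto_scale(v: ValueVector, n_bins: int = 9, reversed: bool = False) -> ColorScale:
    """Color scale spanning exactly the range of the displayed values."""
    if len(v) == 0:
        raise ValidationError("cannot build a color scale from an empty value vector")
    return ColorScale(vmin=float(v.v.min()), vmax=float(v.v.max()),
                      n_bins=n_bins, reversed=reversed)


def bin_index(scale: ColorScale, value: float) -> int:
    """Discrete bin of a value: half-open equal-width bins, top bin closed,
    out-of-range values saturating at the endpoints."""
    if scale.vmin == scale.vmax:
        return scale.n_bins // 2
    if value <= scale.vmin:
        return 0
    if value >= scale.vmax:
        return scale.n_bins - 1
    w = (scale.vmax - scale.vmin) / scale.n_bins
    return min(int((value - scale.vmin) / w), scale.n_bins - 1)


def _hex_to_rgb(h: str) -> tuple[int, int, int]:
    return tuple(int(h[i:i + 2], 16) for i in (1, 3, 5))


def palette_color(scale: ColorScale, index: int) -> str:
    """Hex color for a bin: the 9-class YlOrRd anchors, linearly
    interpolated per channel when n_bins differs from 9."""
    n = scale.n_bins
    if not 0 <= index < n:
        raise ValidationError(f"bin index {index} outside [0, {n})")
    if scale.reversed:
        index = n - 1 - index
    if n == 9:
        return YLORRD9[index]
    anchors = [_hex_to_rgb(h) for h in YLORRD9]
    pos = (index / (n - 1)) * 8.0
    lo = min(int(math.floor(pos)), 7)
    frac = pos - lo
    rgb = tuple(
        int(anchors[lo][c] * (1 - frac) + anchors[lo + 1][c] * frac + 0.5)
        for c in range(3)
    )
    return "#{:02X}{:02X}{:02X}".format(*rgb)
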