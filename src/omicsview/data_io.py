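"""Readers and validated containers for the flat-file inputs.

All tabular inputs share one dialect: tab-separated, UTF-8, lines starting
with ``#`` are comments, the first column is the entity/pathway key.  The
expression matrix may carry a header row naming the samples; otherwise the
column order is taken from the sample-list file.  Missing values are blank
cells and are stored as NaN.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import InputFormatError, ValidationError

log = logging.getLogger(__name__)


class Rect(NamedTuple):
    """Axis-aligned rectangle in abstract canvas units."""

    x: float
    y: float
    w: float
    h: float

    @property
    def area(self) -> float:
        return self.w * self.h

    def shrink(self, pad: float) -> "Rect":
        return Rect(self.x + pad, self.y + pad, self.w - 2 * pad, self.h - 2 * pad)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionDataset:
    """An entities x samples matrix of measured values.

    Values may be expression levels, log ratios, fold changes, p-values from
    an upstream analysis, etc.; the package treats them as opaque reals.
    Missing measurements are NaN.
    """

    entity_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_entities, n_samples), float, NaN = missing

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.entity_ids) == 0 or len(self.sample_ids) == 0:
            raise ValidationError("dataset needs at least one entity and one sample")
        if len(set(self.entity_ids)) != len(self.entity_ids):
            seen, dup = set(), None
            for e in self.entity_ids:
                if e in seen:
                    dup = e
                    break
                seen.add(e)
            raise ValidationError(f"duplicate entity id {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample id")
        if self.values.shape != (len(self.entity_ids), len(self.sample_ids)):
            raise ValidationError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.entity_ids)} entities x {len(self.sample_ids)} samples"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def sample_index(self, sample: str) -> int:
        try:
            return self.sample_ids.index(sample)
        except ValueError:
            raise ValidationError(
                f"unknown sample {sample!r}; available: {', '.join(self.sample_ids)}"
            ) from None


@dataclass
class AnnotationCatalog:
    """Entity -> compartment/pathway annotations plus the genome background.

    ``universe`` is the full gene set of the genome against which pathway
    over-representation is tested; it must contain every entity that carries
    a pathway annotation.
    """

    entity_compartments: dict[str, frozenset[str]]
    entity_pathways: dict[str, frozenset[str]]
    pathway_compartments: dict[str, frozenset[str]]
    universe: frozenset[str]
    entity_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        orphans = sorted(
            {p for ps in self.entity_pathways.values() for p in ps}
            - set(self.pathway_compartments)
        )
        if orphans:
            raise ValidationError(
                "pathways with no compartment assignment: " + ", ".join(orphans)
            )
        stray = sorted(set(self.entity_pathways) - set(self.universe))
        if stray:
            raise ValidationError(
                "entities with pathway annotation missing from the universe: "
                + ", ".join(stray[:10])
                + ("..." if len(stray) > 10 else "")
            )
        for name, m in (
            ("entity_compartments", self.entity_compartments),
            ("entity_pathways", self.entity_pathways),
            ("pathway_compartments", self.pathway_compartments),
        ):
            for k, s in m.items():
                if not s:
                    raise ValidationError(f"{name}[{k!r}] is an empty set")

    def label(self, entity: str) -> str:
        return self.entity_labels.get(entity, entity)


@dataclass
class CellLayout:
    """The drawable cell diagram: named compartment regions on a canvas.

    Regions may overlap (organelles nest inside the cytosol) but each
    compartment name maps to exactly one rectangle.
    """

    compartments: list[tuple[str, Rect, str]]  # (name, region, fill color)
    canvas: tuple[float, float]

    def __post_init__(self):
        names = [c[0] for c in self.compartments]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate compartment name in layout")
        cw, ch = self.canvas
        for name, r, _fill in self.compartments:
            if r.w <= 0 or r.h <= 0:
                raise ValidationError(f"compartment {name!r} has non-positive size")
            if r.x < 0 or r.y < 0 or r.x + r.w > cw or r.y + r.h > ch:
                raise ValidationError(f"compartment {name!r} lies outside the canvas")

    @property
    def names(self) -> list[str]:
        return [c[0] for c in self.compartments]

    def region(self, name: str) -> Rect:
        for n, r, _ in self.compartments:
            if n == name:
                return r
        raise ValidationError(f"unknown compartment {name!r}")

    def fill(self, name: str) -> str:
        for n, _, f in self.compartments:
            if n == name:
                return f
        raise ValidationError(f"unknown compartment {name!r}")


# The ten plant-cell compartments of the default diagram, on a 1000x700 canvas.
DEFAULT_CANVAS = (1000.0, 700.0)
DEFAULT_COMPARTMENTS: list[tuple[str, Rect, str]] = [
    ("plasma membrane", Rect(10, 10, 980, 50), "#D8D8E8"),
    ("cytosol", Rect(10, 70, 500, 560), "#EFEFEF"),
    ("nucleus", Rect(530, 70, 220, 200), "#D7C6E8"),
    ("vacuole", Rect(530, 290, 220, 180), "#C6DCE8"),
    ("golgi apparatus", Rect(530, 480, 220, 150), "#E8DCC6"),
    ("chloroplast", Rect(770, 70, 220, 160), "#A8D8A8"),
    ("plastids/thylakoids", Rect(770, 240, 220, 120), "#CCE8C6"),
    ("mitochondria/cristae", Rect(770, 370, 220, 120), "#E8C6C6"),
    ("endoplasmic reticulum", Rect(770, 500, 220, 130), "#C6E8D2"),
    ("apoplast", Rect(10, 640, 980, 50), "#E0E0D0"),
]


def default_cell_layout() -> CellLayout:
    """The built-in ten-compartment plant-cell diagram."""
    return CellLayout(compartments=list(DEFAULT_COMPARTMENTS), canvas=DEFAULT_CANVAS)


# ---------------------------------------------------------------------------
# low-level line reading
# ---------------------------------------------------------------------------

def _rows(path):
    """Yield (lineno, fields) for non-comment, non-blank TSV lines."""
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_list(path) -> list[str]:
    """One identifier per line; comments and blanks ignored."""
    out = []
    for lineno, fields in _rows(path):
        ident = fields[0].strip()
        if not ident:
            raise InputFormatError(path, lineno, "empty identifier")
        out.append(ident)
    return out


def _read_two_column(path) -> list[tuple[int, str, str]]:
    rows = []
    for lineno, fields in _rows(path):
        if len(fields) < 2:
            raise InputFormatError(
                path, lineno, f"expected 2 tab-separated columns, got {len(fields)}"
            )
        rows.append((lineno, fields[0].strip(), fields[1].strip()))
    return rows


def _collapse(rows) -> dict[str, frozenset[str]]:
    out: dict[str, set[str]] = {}
    for _lineno, key, val in rows:
        out.setdefault(key, set()).add(val)
    return {k: frozenset(v) for k, v in out.items()}


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _parse_value(cell: str, path, lineno: int, col: int) -> float:
    cell = cell.strip()
    if cell == "":
        return math.nan
    try:
        return float(cell)
    except ValueError:
        raise InputFormatError(
            path, lineno, f"non-numeric value {cell!r} in column {col + 1}"
        ) from None


def read_expression(matrix_path, samples_path) -> ExpressionDataset:
    """Read a value matrix plus a sample-list file.

    The matrix may have a header row naming the samples (any order; columns
    are re-ordered to follow the sample list) or be headerless, in which case
    column order is the sample-list order.
    """
    samples = read_list(samples_path)
    if len(set(samples)) != len(samples):
        raise ValidationError(f"duplicate sample name in {samples_path}")

    rows = list(_rows(matrix_path))
    if not rows:
        raise InputFormatError(matrix_path, None, "matrix file holds no data rows")

    first_lineno, first = rows[0]

    def _all_numeric(cells):
        for c in cells:
            c = c.strip()
            if c == "":
                continue
            try:
                float(c)
            except ValueError:
                return False
        return True

    col_order = None
    if not _all_numeric(first[1:]):
        header = [c.strip() for c in first[1:]]
        if sorted(header) != sorted(samples):
            raise InputFormatError(
                matrix_path,
                first_lineno,
                f"header samples {header} do not match sample list {samples}",
            )
        col_order = [header.index(s) for s in samples]
        rows = rows[1:]
        if not rows:
            raise InputFormatError(matrix_path, None, "matrix file holds no data rows")

    entity_ids: list[str] = []
    seen: set[str] = set()
    values = []
    for lineno, fields in rows:
        ident = fields[0].strip()
        if ident in seen:
            raise InputFormatError(matrix_path, lineno, f"duplicate entity id {ident!r}")
        seen.add(ident)
        cells = fields[1:]
        if len(cells) != len(samples):
            raise InputFormatError(
                matrix_path,
                lineno,
                f"sample count mismatch: {len(samples)} samples in "
                f"{samples_path} vs {len(cells)} value columns",
            )
        row = [_parse_value(c, matrix_path, lineno, j + 1) for j, c in enumerate(cells)]
        if col_order is not None:
            row = [row[j] for j in col_order]
        entity_ids.append(ident)
        values.append(row)

    return ExpressionDataset(entity_ids, samples, np.array(values, dtype=float))


def read_expression_combined(path) -> ExpressionDataset:
    """Convenience reader for a single combined file whose first row lists
    the samples and whose remaining rows are ``entity<TAB>values...``."""
    rows = list(_rows(path))
    if len(rows) < 2:
        raise InputFormatError(path, None, "combined file needs a sample row plus data rows")
    _lineno, first = rows[0]
    samples = [c.strip() for c in first[1:] if c.strip()]
    if not samples:
        raise InputFormatError(path, rows[0][0], "no sample names in the first row")
    entity_ids, values, seen = [], [], set()
    for lineno, fields in rows[1:]:
        ident = fields[0].strip()
        if ident in seen:
            raise InputFormatError(path, lineno, f"duplicate entity id {ident!r}")
        seen.add(ident)
        cells = fields[1:]
        if len(cells) != len(samples):
            raise InputFormatError(
                path, lineno,
                f"sample count mismatch: {len(samples)} vs {len(cells)} value columns",
            )
        values.append([_parse_value(c, path, lineno, j + 1) for j, c in enumerate(cells)])
        entity_ids.append(ident)
    return ExpressionDataset(entity_ids, samples, np.array(values, dtype=float))


def read_annotations(loc_path, pw_path, pwcomp_path, universe_path,
                     labels_path=None) -> AnnotationCatalog:
    """Assemble the annotation catalog from four (optionally five) TSV files.

    Multi-row entities collapse to sets; the catalog's structural invariants
    (no orphan pathways, universe covers pathway-annotated entities) are
    enforced on construction.
    """
    loc = _collapse(_read_two_column(loc_path))
    pw_rows = _read_two_column(pw_path)
    pw = _collapse(pw_rows)
    pwcomp = _collapse(_read_two_column(pwcomp_path))
    universe = frozenset(read_list(universe_path))

    orphans = sorted({p for _, _, p in pw_rows} - set(pwcomp))
    if orphans:
        raise ValidationError(
            f"{pw_path}: pathways missing from {pwcomp_path}: " + ", ".join(orphans)
        )
    stray = sorted(set(pw) - universe)
    if stray:
        raise ValidationError(
            f"{pw_path}: entities missing from universe {universe_path}: "
            + ", ".join(stray[:10]) + ("..." if len(stray) > 10 else "")
        )

    labels: dict[str, str] = {}
    if labels_path is not None:
        for _lineno, ent, lab in _read_two_column(labels_path):
            labels[ent] = lab

    return AnnotationCatalog(
        entity_compartments=loc,
        entity_pathways=pw,
        pathway_compartments=pwcomp,
        universe=universe,
        entity_labels=labels,
    )


def apply_probe_map(ds: ExpressionDataset, map_path) -> ExpressionDataset:
    """Translate probe-level rows to gene-level rows via a probe->gene table.

    Probes mapping to the same gene are aggregated by the mean of present
    values; probes absent from the map are dropped (count logged).  Gene
    order follows first appearance among mapped probes.
    """
    rows = _read_two_column(map_path)
    if not rows:
        raise InputFormatError(map_path, None, "probe map is empty")
    probe_to_gene = {probe: gene for _lineno, probe, gene in rows}

    gene_order: list[str] = []
    gene_rows: dict[str, list[int]] = {}
    dropped = 0
    for i, probe in enumerate(ds.entity_ids):
        gene = probe_to_gene.get(probe)
        if gene is None:
            dropped += 1
            continue
        if gene not in gene_rows:
            gene_order.append(gene)
            gene_rows[gene] = []
        gene_rows[gene].append(i)
    if dropped:
        log.info("probe map: dropped %d unmapped probes", dropped)
    if not gene_order:
        raise ValidationError(f"no probe in the dataset is covered by {map_path}")

    out = np.full((len(gene_order), len(ds.sample_ids)), np.nan)
    for gi, gene in enumerate(gene_order):
        block = ds.values[gene_rows[gene], :]
        present = ~np.isnan(block)
        counts = present.sum(axis=0)
        sums = np.where(present, block, 0.0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            out[gi] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    result = ExpressionDataset(gene_order, list(ds.sample_ids), out)
    result.n_dropped_probes = dropped  # informational, mirrors the log line
    return result


# ---------------------------------------------------------------------------
# cell layout config
# ---------------------------------------------------------------------------

def read_cell_layout(path=None) -> CellLayout:
    """Read a layout config; with no path, return the built-in plant cell.

    Format (tab-separated)::

        canvas  <width>  <height>
        compartment  <name>  <x>  <y>  <w>  <h>  <fill>
    """
    if path is None:
        return default_cell_layout()
    canvas = None
    compartments: list[tuple[str, Rect, str]] = []
    for lineno, fields in _rows(path):
        kind = fields[0].strip()
        if kind == "canvas":
            if len(fields) != 3:
                raise InputFormatError(path, lineno, "canvas line needs width and height")
            canvas = (float(fields[1]), float(fields[2]))
        elif kind == "compartment":
            if len(fields) != 7:
                raise InputFormatError(
                    path, lineno,
                    f"compartment line needs name, x, y, w, h, fill (got {len(fields) - 1} fields)",
                )
            name = fields[1].strip()
            try:
                x, y, w, h = (float(v) for v in fields[2:6])
            except ValueError:
                raise InputFormatError(
                    path, lineno, f"non-numeric geometry for compartment {name!r}"
                ) from None
            compartments.append((name, Rect(x, y, w, h), fields[6].strip()))
        else:
            raise InputFormatError(path, lineno, f"unknown record type {kind!r}")
    if canvas is None:
        raise InputFormatError(path, None, "layout file lacks a canvas line")
    return CellLayout(compartments=compartments, canvas=canvas)


def write_cell_layout(layout: CellLayout, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# cell layout: canvas then one compartment per line\n")
        fh.write(f"canvas\t{layout.canvas[0]!r}\t{layout.canvas[1]!r}\n")
        for name, r, fill in layout.compartments:
            fh.write(f"compartment\t{name}\t{r.x!r}\t{r.y!r}\t{r.w!r}\t{r.h!r}\t{fill}\n")


# ---------------------------------------------------------------------------
# writers used by fixtures and round-trip tests
# ---------------------------------------------------------------------------

def write_expression(ds: ExpressionDataset, matrix_path, samples_path) -> None:
    with open(samples_path, "w", encoding="utf-8") as fh:
        for s in ds.sample_ids:
            fh.write(s + "\n")
    with open(matrix_path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(ds.sample_ids) + "\n")
        for i, ent in enumerate(ds.entity_ids):
            cells = ["" if math.isnan(v) else repr(float(v)) for v in ds.values[i]]
            fh.write(ent + "\t" + "\t".join(cells) + "\n")


def write_two_column(mapping: dict[str, frozenset[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key in sorted(mapping):
            for val in sorted(mapping[key]):
                fh.write(f"{key}\t{val}\n")


def write_list(items, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for it in sorted(items):
            fh.write(it + "\n")
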