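"""Deterministic SVG output for the three views, legend, and combined
side-by-side displays, plus TSV annotation dumps.

Output is byte-identical for identical inputs: element order follows the
deterministic orderings produced upstream, and every number is formatted
through one fixed-precision helper.  Each icon element carries
machine-readable ``data-`` attributes (entity list, value, bin) so tests
and downstream tools can inspect a rendered scene without re-running the
pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from xml.sax.saxutils import escape, quoteattr

from .chunking import IconGroup, PackingPlan
from .data_io import AnnotationCatalog, CellLayout, ExpressionDataset, Rect
from .enrichment import EnrichmentResult
from .errors import ValidationError
from .treemap import LaidOutNode
from .values import ColorScale, ValueVector, palette_color

LEGEND_HEIGHT = 70.0
LABEL_FONT = 11


def _f(x: float) -> str:
    """Fixed numeric formatting so output bytes never depend on float repr."""
    s = f"{x:.2f}"
    return s.rstrip("0").rstrip(".") if "." in s else s


@dataclass
class SvgDocument:
    width: float
    height: float
    layers: list[tuple[str, list[str]]] = field(default_factory=list)
    meta: dict[str, str] = field(default_factory=dict)
    scale: ColorScale | None = None

    def layer(self, name: str) -> list[str]:
        for n, elems in self.layers:
            if n == name:
                return elems
        elems: list[str] = []
        self.layers.append((name, elems))
        return elems

    def to_svg(self) -> str:
        out = [
            '<?xml version="1.0" encoding="UTF-8"?>',
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{_f(self.width)}" '
            f'height="{_f(self.height)}" '
            f'viewBox="0 0 {_f(self.width)} {_f(self.height)}">',
        ]
        for key in sorted(self.meta):
            out.append(f"<!-- {escape(key)}: {escape(str(self.meta[key]))} -->")
        for name, elems in self.layers:
            out.append(f'<g id={quoteattr(name)}>')
            out.extend(elems)
            out.append("</g>")
        out.append("</svg>")
        return "\n".join(out) + "\n"

    def write(self, path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(self.to_svg())


def _rect(r: Rect, fill: str, stroke: str = "#666666", stroke_width: float = 1.0,
          title: str | None = None, extra: str = "") -> str:
    t = f"<title>{escape(title)}</title>" if title else ""
    return (
        f'<rect x="{_f(r.x)}" y="{_f(r.y)}" width="{_f(r.w)}" height="{_f(r.h)}" '
        f'fill="{fill}" stroke="{stroke}" stroke-width="{_f(stroke_width)}"{extra}>'
        f"{t}</rect>"
    )


def _label(x: float, y: float, text: str, max_width: float | None = None,
           size: int = LABEL_FONT) -> str:
    """Text label, truncated with an ellipsis when the rectangle is narrow;
    the untruncated name rides along in a title element."""
    shown = text
    if max_width is not None:
        max_chars = max(int(max_width / (0.62 * size)), 1)
        if len(shown) > max_chars:
            shown = shown[: max(max_chars - 1, 1)] + "…"
    title = f"<title>{escape(text)}</title>" if shown != text else ""
    return (
        f'<text x="{_f(x)}" y="{_f(y)}" font-size="{size}" '
        f'font-family="sans-serif" fill="#222222">{escape(shown)}{title}</text>'
    )


def _icon(grp: IconGroup, icon_size: float, scale: ColorScale) -> str:
    if grp.position is None or grp.bin is None:
        raise ValidationError("icons must be placed and color-binned before rendering")
    x, y = grp.position
    fill = palette_color(scale, grp.bin)
    attrs = (
        f' data-entities={quoteattr(",".join(grp.member_entities))}'
        f' data-value="{grp.representative_value!r}" data-bin="{grp.bin}"'
    )
    title = (f"<title>{escape(', '.join(grp.member_entities))} = "
             f"{_f(grp.representative_value)}</title>")
    if grp.shape == "disc":
        r = icon_size / 2
        return (f'<circle cx="{_f(x + r)}" cy="{_f(y + r)}" r="{_f(r)}" '
                f'fill="{fill}" stroke="#333333" stroke-width="0.5"{attrs}>'
                f"{title}</circle>")
    return (f'<rect x="{_f(x)}" y="{_f(y)}" width="{_f(icon_size)}" '
            f'height="{_f(icon_size)}" fill="{fill}" stroke="#333333" '
            f'stroke-width="0.5"{attrs}>{title}</rect>')


def _legend(doc: SvgDocument, scale: ColorScale, g: int, y0: float) -> None:
    """Color ramp with vmin/vmax ticks, shape key, and the entities-per-icon
    factor of the view."""
    elems = doc.layer("legend")
    sw = 24.0
    x0 = 10.0
    elems.append(_label(x0, y0 + 12, "value"))
    for i in range(scale.n_bins):
        elems.append(_rect(Rect(x0 + 46 + i * sw, y0 + 2, sw, 14),
                           palette_color(scale, i), stroke="#999999",
                           stroke_width=0.5))
    elems.append(_label(x0 + 46, y0 + 30, _f(scale.vmin), size=10))
    end = x0 + 46 + scale.n_bins * sw
    elems.append(_label(end - 30, y0 + 30, _f(scale.vmax), size=10))
    kx = end + 30
    elems.append(
        f'<circle cx="{_f(kx + 5)}" cy="{_f(y0 + 9)}" r="5" fill="#FFFFFF" '
        f'stroke="#333333" stroke-width="0.5"/>'
    )
    elems.append(_label(kx + 14, y0 + 13, "1 entity", size=10))
    elems.append(_rect(Rect(kx, y0 + 22, 10, 10), "#FFFFFF", stroke="#333333",
                       stroke_width=0.5))
    elems.append(_label(kx + 14, y0 + 31, f"group of up to {g} entities", size=10))


def render_cell_view(layout: CellLayout,
                     groups: dict[str, list[IconGroup]],
                     scale: ColorScale,
                     plan: PackingPlan,
                     icon_size: float,
                     legend: bool = True,
                     meta: dict | None = None) -> SvgDocument:
    """The cellular-map view: compartment regions with labeled fills, icons
    colored by value, legend strip underneath."""
    w, h = layout.canvas
    doc = SvgDocument(w, h + (LEGEND_HEIGHT if legend else 0),
                      meta=dict(meta or {}), scale=scale)
    doc.meta.setdefault("view", "cellmap")
    doc.meta.setdefault("entities-per-icon", str(plan.g))
    bg = doc.layer("background")
    bg.append(_rect(Rect(0, 0, w, h), "#FFFFFF", stroke="none", stroke_width=0))
    regions = doc.layer("regions")
    labels = doc.layer("labels")
    for name, r, fill in layout.compartments:
        regions.append(_rect(r, fill, title=name))
        labels.append(_label(r.x + 3, r.y + 12, name, max_width=r.w - 6))
    icons = doc.layer("icons")
    for name in layout.names:
        for grp in groups.get(name, []):
            icons.append(_icon(grp, icon_size, scale))
    if legend:
        _legend(doc, scale, plan.g, h + 8)
    return doc


def render_treemap_view(nodes: list[LaidOutNode],
                        groups_by_leaf: dict[int, list[IconGroup]],
                        scale: ColorScale,
                        plan: PackingPlan,
                        icon_size: float,
                        enrichment: list[EnrichmentResult] | None = None,
                        legend: bool = True,
                        view_name: str = "pathways",
                        meta: dict | None = None) -> SvgDocument:
    """Nested-rectangle view (pathway tree or GO hierarchy).

    Pathways flagged by the enrichment test get a red border overlay, and
    every pathway rectangle carries its p-value in an SVG title element.
    """
    if not nodes:
        raise ValidationError("nothing to render: empty layout")
    root_rect = nodes[0].rect
    w = root_rect.x + root_rect.w
    h = root_rect.y + root_rect.h
    doc = SvgDocument(w, h + (LEGEND_HEIGHT if legend else 0),
                      meta=dict(meta or {}), scale=scale)
    doc.meta.setdefault("view", view_name)
    doc.meta.setdefault("entities-per-icon", str(plan.g))
    p_by_pathway = {}
    highlighted = set()
    for res in enrichment or []:
        p_by_pathway[res.pathway] = res.p_value
        if res.highlighted:
            highlighted.add(res.pathway)

    rects = doc.layer("rectangles")
    labels = doc.layer("labels")
    overlays = doc.layer("highlights")
    leaf_index = -1
    leaf_positions: dict[int, LaidOutNode] = {}
    for ln in nodes:
        is_leaf = not ln.node.children
        if is_leaf:
            leaf_index += 1
            leaf_positions[leaf_index] = ln
        fill = ln.node.fill or "#F5F5F5"
        title = ln.node.name
        if ln.node.name in p_by_pathway:
            title = f"{ln.node.name} (p = {p_by_pathway[ln.node.name]:.4g})"
        rects.append(_rect(ln.rect, fill, title=title))
        if ln.depth >= 1:
            labels.append(_label(ln.rect.x + 2, ln.rect.y + 11, ln.node.name,
                                 max_width=ln.rect.w - 4, size=9))
        if is_leaf and ln.node.name in highlighted:
            overlays.append(_rect(
                ln.rect, "none", stroke="#FF0000", stroke_width=2.0,
                title=f"{ln.node.name}: over-represented "
                      f"(p = {p_by_pathway[ln.node.name]:.4g})",
            ))
    icons = doc.layer("icons")
    for i in sorted(groups_by_leaf):
        for grp in groups_by_leaf[i]:
            icons.append(_icon(grp, icon_size, scale))
    if legend:
        _legend(doc, scale, plan.g, h + 8)
    return doc


def render_combined(left: SvgDocument, right: SvgDocument) -> SvgDocument:
    """Side-by-side composition of two views sharing one color scale.

    The halves must already be rendered at their reduced width (the caller
    re-solves chunking at the smaller area); a single shared legend replaces
    the per-view ones.
    """
    if left.scale is None or right.scale is None:
        raise ValidationError("combined views need color scales on both halves")
    if left.scale.key() != right.scale.key():
        raise ValidationError(
            "combined views must share one color scale; got "
            f"{left.scale.key()} vs {right.scale.key()}"
        )
    gap = 10.0
    body_h = max(left.height, right.height)
    doc = SvgDocument(left.width + right.width + gap, body_h + LEGEND_HEIGHT,
                      scale=left.scale)
    doc.meta["view"] = "combined"
    doc.meta["left"] = left.meta.get("view", "?")
    doc.meta["right"] = right.meta.get("view", "?")
    panels = doc.layer("panels")

    def nest(sub: SvgDocument, dx: float, side: str):
        panels.append(f'<g transform="translate({_f(dx)},0)">')
        for name, elems in sub.layers:
            if name == "legend":
                continue
            panels.append(f'<g id={quoteattr(side + "-" + name)}>')
            panels.extend(elems)
            panels.append("</g>")
        panels.append("</g>")

    nest(left, 0.0, "left")
    nest(right, left.width + gap, "right")
    g = max(int(left.meta.get("entities-per-icon", "1")),
            int(right.meta.get("entities-per-icon", "1")))
    _legend(doc, left.scale, g, body_h + 8)
    return doc


def describe_entities(ids, catalog: AnnotationCatalog,
                      ds: ExpressionDataset) -> str:
    """TSV annotation dump: one row per unique entity with its label,
    values, compartments and pathways; unknown ids get a warning flag."""
    seen = []
    for e in ids:
        if e not in seen:
            seen.append(e)
    lines = ["id\tlabel\t" + "\t".join(ds.sample_ids)
             + "\tcompartments\tpathways\twarning"]
    known = set(ds.entity_ids)
    index = {e: i for i, e in enumerate(ds.entity_ids)}
    for e in seen:
        if e in known:
            vals = ["" if math.isnan(x) else f"{x:.6g}" for x in ds.values[index[e]]]
            warning = ""
        else:
            vals = [""] * len(ds.sample_ids)
            warning = "unknown id"
        comp = ";".join(sorted(catalog.entity_compartments.get(e, frozenset())))
        pws = ";".join(sorted(catalog.entity_pathways.get(e, frozenset())))
        lines.append("\t".join([e, catalog.label(e), *vals, comp, pws, warning]))
    return "\n".join(lines) + "\n"
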