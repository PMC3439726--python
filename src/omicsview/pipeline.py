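"""End-to-end workflows: read inputs, filter, compare, chunk, enrich,
render.  The CLI is a thin wrapper around :func:`run`.

Pipeline order is fixed: read -> probe-map -> min-value filter -> extract
or compare -> value filters -> color scale -> view build -> chunking ->
enrichment (pathway view) -> render -> reports.  A structured log records
entity counts at each stage, the solved entities-per-icon factor, and
exclusion tallies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

from . import chunking, enrichment, go_view, render, treemap, values
from .chunking import DEFAULT_ICON_SIZE, DEFAULT_PADDING, IconGroup, PackingPlan
from .data_io import (AnnotationCatalog, CellLayout, ExpressionDataset, Rect,
                      apply_probe_map, read_annotations, read_cell_layout,
                      read_expression, read_expression_combined)
from .errors import OmicsViewError, ValidationError
from .treemap import DEFAULT_INNER_PAD, LaidOutNode, TreeNode
from .values import ColorScale, ValueVector

log = logging.getLogger(__name__)

VIEWS = ("cellmap", "pathways", "go-bp", "go-mf")
GO_NAMESPACE_BY_VIEW = {"go-bp": "biological_process",
                        "go-mf": "molecular_function"}


@dataclass
class RunConfig:
    """Everything one batch invocation needs."""

    # inputs
    matrix: str | None = None
    samples: str | None = None
    combined_input: str | None = None
    probe_map: str | None = None
    locations: str | None = None
    pathways: str | None = None
    pathway_compartments: str | None = None
    universe: str | None = None
    labels: str | None = None
    layout_path: str | None = None
    obo: str | None = None
    gaf: str | None = None
    # what to show
    view: str = "cellmap"
    combine: tuple[str, str] | None = None  # for view == "combined"
    sample: str | None = None
    compare: tuple[str, str] | None = None
    mode: str = "fold"
    # filters and scale
    min_value: float | None = None
    keep_over: float | None = None
    keep_under: float | None = None
    color_range: tuple[float, float] | None = None
    n_bins: int = 9
    reverse_colors: bool = False
    p_threshold: float = enrichment.DEFAULT_P_THRESHOLD
    fdr: bool = False
    expand_depth: int = 2
    # geometry
    icon_size: float = DEFAULT_ICON_SIZE
    padding: float = DEFAULT_PADDING
    inner_pad: float = DEFAULT_INNER_PAD
    max_per_icon: int | None = None
    canvas: tuple[float, float] = (1000.0, 700.0)
    # output
    out: str = "view.svg"

    def validate(self):
        if (self.sample is None) == (self.compare is None):
            raise ValidationError(
                "specify exactly one of --sample or --compare A B"
            )
        view_ok = self.view in VIEWS or self.view == "combined"
        if not view_ok:
            raise ValidationError(
                f"unknown view {self.view!r}; choose from "
                f"{', '.join(VIEWS + ('combined',))}"
            )
        if self.view == "combined":
            if self.combine is None:
                raise ValidationError("combined view needs two sub-views")
            for v in self.combine:
                if v not in VIEWS:
                    raise ValidationError(f"unknown sub-view {v!r}")


class StageLog:
    """Append-only key=value stage records, mirrored to the module logger."""

    def __init__(self):
        self.lines: list[str] = []

    def record(self, stage: str, **kv):
        parts = [f"stage={stage}"] + [f"{k}={v}" for k, v in kv.items()]
        line = " ".join(parts)
        self.lines.append(line)
        log.info("%s", line)

    def write(self, path):
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(self.lines) + "\n")


# ---------------------------------------------------------------------------
# building blocks shared by CLI and tests
# ---------------------------------------------------------------------------

def build_cell_groups(layout: CellLayout, catalog: AnnotationCatalog,
                      v: ValueVector, scale: ColorScale,
                      icon_size: float = DEFAULT_ICON_SIZE,
                      padding: float = DEFAULT_PADDING,
                      max_per_icon: int | None = None,
                      ) -> tuple[dict[str, list[IconGroup]], PackingPlan]:
    """Chunk + place icons for every compartment of the cellular map.

    An entity appears once per annotated compartment; entities without
    location annotation appear nowhere.
    """
    per_comp: dict[str, list[str]] = {name: [] for name in layout.names}
    for e in v.entity_ids:
        for comp in catalog.entity_compartments.get(e, frozenset()):
            if comp in per_comp:
                per_comp[comp].append(e)
    counts = {c: len(es) for c, es in per_comp.items()}
    caps = {c: chunking.compartment_capacity(layout.region(c), icon_size, padding)
            for c in layout.names}
    caps_for_solver = {c: caps[c] for c in layout.names if counts[c] > 0}
    plan = chunking.solve_group_size(
        {c: n for c, n in counts.items() if n > 0}, caps_for_solver, icon_size)
    if max_per_icon is not None and max_per_icon < plan.g:
        raise ValidationError(
            f"--max-per-icon {max_per_icon} is below the minimal feasible "
            f"group size {plan.g} for this view"
        )
    groups: dict[str, list[IconGroup]] = {}
    for comp in layout.names:
        if not per_comp[comp]:
            groups[comp] = []
            continue
        sub = v.restrict(per_comp[comp])
        gs = chunking.group_entities(sub, plan.g, scale)
        groups[comp] = chunking.place_icons(gs, layout.region(comp),
                                            icon_size, padding)
    return groups, plan


def _prune_zero(node: TreeNode) -> TreeNode | None:
    if not node.children:
        return node if node.weight > 0 else None
    kids = [k for k in (_prune_zero(c) for c in node.children) if k is not None]
    if not kids:
        return None
    return TreeNode(node.name, sum(c.weight for c in kids), children=kids,
                    fill=node.fill, highlight=node.highlight)


def build_treemap_document(tree: TreeNode, v: ValueVector, scale: ColorScale,
                           canvas: tuple[float, float],
                           inner_pad: float = DEFAULT_INNER_PAD,
                           icon_size: float = DEFAULT_ICON_SIZE,
                           padding: float = DEFAULT_PADDING,
                           enrichment_results=None,
                           max_per_icon: int | None = None,
                           legend: bool = True,
                           view_name: str = "pathways",
                           stage_log: StageLog | None = None):
    """Lay out a weighted tree, chunk icons into its leaves and render."""
    pruned = _prune_zero(tree)
    if pruned is None:
        doc = render.SvgDocument(canvas[0], canvas[1], scale=scale)
        doc.meta["view"] = view_name
        doc.meta["entities-per-icon"] = "1"
        doc.layer("labels").append(render._label(10, 20, "no annotated entities"))
        return doc, [], PackingPlan(1, icon_size, {})
    nodes = treemap.layout(pruned, Rect(0, 0, canvas[0], canvas[1]), inner_pad)
    leaves = [ln for ln in nodes if not ln.node.children]
    groups_by_leaf, plan = treemap.place_leaf_icons(
        leaves, v, icon_size, padding, scale, max_per_icon)
    if stage_log is not None:
        stage_log.record("chunk", view=view_name, g=plan.g, leaves=len(leaves))
    doc = render.render_treemap_view(
        nodes, groups_by_leaf, scale, plan, icon_size,
        enrichment=enrichment_results, legend=legend, view_name=view_name)
    return doc, nodes, plan


def _displayed_vector(ds: ExpressionDataset, cfg: RunConfig,
                      stage_log: StageLog) -> ValueVector:
    if cfg.sample is not None:
        v = values.extract_sample(ds, cfg.sample)
        stage_log.record("extract", sample=cfg.sample, entities=len(v))
    else:
        a, b = cfg.compare
        v = values.compare_samples(ds, a, b, cfg.mode)
        stage_log.record("compare", a=a, b=b, mode=cfg.mode, entities=len(v),
                         excluded_zero_denominator=v.n_excluded_zero_denom)
    if cfg.keep_over is not None or cfg.keep_under is not None:
        before = len(v)
        keep = [i for i, x in enumerate(v.v)
                if (cfg.keep_over is None or x > cfg.keep_over)
                and (cfg.keep_under is None or x < cfg.keep_under)]
        v = ValueVector([v.entity_ids[i] for i in keep], v.v[keep],
                        label=v.label,
                        n_excluded_zero_denom=v.n_excluded_zero_denom)
        stage_log.record("value-filter", before=before, after=len(v),
                         keep_over=cfg.keep_over, keep_under=cfg.keep_under)
    if len(v) == 0:
        raise ValidationError("no displayable entities after filtering")
    return v


def _make_scale(v: ValueVector, cfg: RunConfig) -> ColorScale:
    if cfg.color_range is not None:
        lo, hi = cfg.color_range
        return ColorScale(lo, hi, n_bins=cfg.n_bins, reversed=cfg.reverse_colors)
    return values.auto_scale(v, n_bins=cfg.n_bins, reversed=cfg.reverse_colors)


def _build_single_view(view: str, cfg: RunConfig, ds, catalog, layout,
                       go_graph, v, scale, stage_log: StageLog,
                       canvas: tuple[float, float], layout_scale: float = 1.0,
                       legend: bool = True):
    """One rendered document for any of the four base views."""
    if view == "cellmap":
        lay = layout if layout_scale == 1.0 else _scale_layout(layout, layout_scale)
        groups, plan = build_cell_groups(
            lay, catalog, v, scale, cfg.icon_size, cfg.padding, cfg.max_per_icon)
        stage_log.record("chunk", view=view, g=plan.g,
                         icons=sum(len(g) for g in groups.values()))
        return render.render_cell_view(lay, groups, scale, plan, cfg.icon_size,
                                       legend=legend), None
    if view == "pathways":
        displayed = set(v.entity_ids)
        results = enrichment.test_all_pathways(
            catalog, displayed, cfg.p_threshold, fdr=cfg.fdr)
        stage_log.record("enrich", pathways_tested=len(results),
                         highlighted=sum(r.highlighted for r in results),
                         n=len(displayed), threshold=cfg.p_threshold)
        tree = treemap.build_pathway_tree(catalog, v, layout)
        doc, _nodes, _plan = build_treemap_document(
            tree, v, scale, canvas, cfg.inner_pad, cfg.icon_size, cfg.padding,
            enrichment_results=results, max_per_icon=cfg.max_per_icon,
            legend=legend, view_name=view, stage_log=stage_log)
        return doc, results
    if view in GO_NAMESPACE_BY_VIEW:
        if go_graph is None:
            raise ValidationError("GO views need --obo and --gaf inputs")
        ns = GO_NAMESPACE_BY_VIEW[view]
        displayed = set(v.entity_ids)
        state = go_view.expand_to_depth(go_graph, ns, cfg.expand_depth, displayed)
        tree = go_view.build_go_tree(go_graph, state, displayed)
        stage_log.record("go-state", namespace=ns, depth=cfg.expand_depth,
                         expanded=len(state.expanded))
        doc, _nodes, _plan = build_treemap_document(
            tree, v, scale, canvas, cfg.inner_pad, cfg.icon_size, cfg.padding,
            max_per_icon=cfg.max_per_icon, legend=legend, view_name=view,
            stage_log=stage_log)
        return doc, None
    raise ValidationError(f"unknown view {view!r}")


def _scale_layout(layout: CellLayout, factor: float) -> CellLayout:
    comps = [(n, Rect(r.x * factor, r.y * factor, r.w * factor, r.h * factor), f)
             for n, r, f in layout.compartments]
    return CellLayout(compartments=comps,
                      canvas=(layout.canvas[0] * factor,
                              layout.canvas[1] * factor))


# ---------------------------------------------------------------------------
# the batch entry point
# ---------------------------------------------------------------------------

def load_dataset(cfg: RunConfig, stage_log: StageLog) -> ExpressionDataset:
    if cfg.combined_input is not None:
        ds = read_expression_combined(cfg.combined_input)
    elif cfg.matrix is not None and cfg.samples is not None:
        ds = read_expression(cfg.matrix, cfg.samples)
    else:
        raise ValidationError(
            "expression input missing: give --matrix with --samples, "
            "or --combined-input"
        )
    stage_log.record("read", entities=ds.shape[0], samples=ds.shape[1])
    if cfg.probe_map is not None:
        ds = apply_probe_map(ds, cfg.probe_map)
        stage_log.record("probe-map", entities=ds.shape[0],
                         dropped=getattr(ds, "n_dropped_probes", 0))
    if cfg.min_value is not None:
        before = ds.shape[0]
        ds = values.filter_min_value(ds, cfg.min_value)
        stage_log.record("min-value-filter", threshold=cfg.min_value,
                         before=before, after=ds.shape[0])
    return ds


def load_catalog(cfg: RunConfig) -> AnnotationCatalog:
    missing = [flag for flag, val in (
        ("--locations", cfg.locations), ("--pathways", cfg.pathways),
        ("--pathway-compartments", cfg.pathway_compartments),
        ("--universe", cfg.universe)) if val is None]
    if missing:
        raise ValidationError("annotation inputs missing: " + ", ".join(missing))
    return read_annotations(cfg.locations, cfg.pathways,
                            cfg.pathway_compartments, cfg.universe,
                            labels_path=cfg.labels)


def run(cfg: RunConfig) -> dict:
    """Execute one configured workflow; returns artifact paths and stats."""
    cfg.validate()
    stage_log = StageLog()
    ds = load_dataset(cfg, stage_log)
    catalog = load_catalog(cfg)
    layout = read_cell_layout(cfg.layout_path)

    go_graph = None
    if cfg.obo is not None:
        go_graph = go_view.read_obo(cfg.obo)
        if cfg.gaf is None:
            raise ValidationError("--obo given without --gaf annotations")
        go_view.read_annotations_gaf(cfg.gaf, go_graph)
        stage_log.record("go-read", terms=len(go_graph.terms),
                         annotated_entities=len(go_graph.annotations))

    v = _displayed_vector(ds, cfg, stage_log)
    scale = _make_scale(v, cfg)
    stage_log.record("scale", vmin=scale.vmin, vmax=scale.vmax,
                     bins=scale.n_bins)

    out = Path(cfg.out)
    artifacts = {"svg": str(out)}
    if cfg.view == "combined":
        lv, rv = cfg.combine
        half = (cfg.canvas[0] / 2.0, cfg.canvas[1] / 2.0)
        left, lres = _build_single_view(lv, cfg, ds, catalog, layout, go_graph,
                                        v, scale, stage_log, half,
                                        layout_scale=0.5, legend=False)
        right, rres = _build_single_view(rv, cfg, ds, catalog, layout, go_graph,
                                         v, scale, stage_log, half,
                                         layout_scale=0.5, legend=False)
        doc = render.render_combined(left, right)
        results = lres or rres
    else:
        doc, results = _build_single_view(
            cfg.view, cfg, ds, catalog, layout, go_graph, v, scale,
            stage_log, cfg.canvas)
    doc.meta["displayed"] = str(len(v))
    doc.meta["label"] = v.label
    doc.write(out)
    stage_log.record("render", out=str(out))

    if results is not None:
        report = out.with_suffix(".enrichment.tsv")
        enrichment.write_report(results, report)
        artifacts["enrichment"] = str(report)
        stage_log.record("report", out=str(report))

    log_path = out.with_suffix(".log")
    stage_log.write(log_path)
    artifacts["log"] = str(log_path)
    return {"artifacts": artifacts, "displayed": len(v), "stages": stage_log.lines}
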