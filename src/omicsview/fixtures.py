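"""Synthetic, self-consistent input generation.

One integer seed drives a single explicit pseudo-random stream and fully
determines every output byte, so fixture runs are reproducible.  The
generator emulates a summarized transcriptomic experiment over a genome
background: skewed (lognormal) expression values, partial compartment /
pathway / GO annotation, an acyclic GO term graph with one root per
namespace, and optionally "planted" pathways whose members are more likely
to carry high values — a detectable over-representation signal for the
enrichment test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import data_io
from .data_io import (AnnotationCatalog, CellLayout, ExpressionDataset,
                      default_cell_layout, write_cell_layout)
from .errors import ValidationError

# Entities this many times the background draw count as "high" responders;
# with the default lognormal(3, 1) background this puts most high values
# above the conventional display cutoff of 50.
HIGH_SCALE = 8.0
BASE_HIGH_PROB = 0.2


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs of one synthetic experiment."""

    n_entities: int = 500
    n_samples: int = 4
    n_pathways: int = 20
    n_compartments: int = 10
    n_go_terms: int = 60
    frac_annotated: float = 0.8
    enriched_pathways: tuple[tuple[int, float], ...] = ()
    value_distribution: tuple = ("lognormal", 3.0, 1.0)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_entities", "n_samples", "n_pathways",
                     "n_compartments", "n_go_terms"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 <= self.frac_annotated <= 1:
            raise ValidationError("frac_annotated must lie in [0, 1]")
        for idx, mult in self.enriched_pathways:
            if not 0 <= idx < self.n_pathways:
                raise ValidationError(f"enriched pathway index {idx} out of range")
            if mult < 1:
                raise ValidationError("enrichment odds multiplier must be >= 1")


@dataclass
class FixtureTables:
    """In-memory form of one generated experiment."""

    dataset: ExpressionDataset
    catalog: AnnotationCatalog
    layout: CellLayout
    go_terms: dict[str, tuple[str, str]]       # id -> (name, namespace)
    go_parents: dict[str, frozenset[str]]      # child -> is_a parents
    go_annotations: dict[str, frozenset[str]]  # entity -> terms
    high_entities: frozenset[str]


def _draw_value(rng: np.random.Generator, law: tuple, size) -> np.ndarray:
    kind = law[0]
    if kind == "lognormal":
        return rng.lognormal(mean=law[1], sigma=law[2], size=size)
    if kind == "uniform":
        return rng.uniform(law[1], law[2], size=size)
    raise ValidationError(f"unknown value distribution {kind!r}")


def generate_tables(spec: FixtureSpec) -> FixtureTables:
    """Draw one complete synthetic experiment (no files written)."""
    rng = np.random.default_rng(spec.seed)
    entities = [f"g{i:05d}" for i in range(spec.n_entities)]
    samples = [f"S{j + 1}" for j in range(spec.n_samples)]

    layout = default_cell_layout()
    comp_names = layout.names[: spec.n_compartments]

    # pathway memberships: each pathway samples 3%..6% of the genome
    pathways = [f"pw{p:03d}" for p in range(spec.n_pathways)]
    members: dict[str, list[str]] = {}
    for pw in pathways:
        m = int(rng.integers(max(spec.n_entities // 33, 4),
                             max(spec.n_entities // 16, 8) + 1))
        idx = rng.choice(spec.n_entities, size=min(m, spec.n_entities),
                         replace=False)
        members[pw] = [entities[i] for i in sorted(idx)]

    multiplier = {entities[i]: 1.0 for i in range(spec.n_entities)}
    for p_idx, mult in spec.enriched_pathways:
        for e in members[pathways[p_idx]]:
            multiplier[e] = max(multiplier[e], float(mult))

    # high-responder flags: planted pathways boost the odds of being high
    high: set[str] = set()
    for e in entities:
        odds = (BASE_HIGH_PROB / (1 - BASE_HIGH_PROB)) * multiplier[e]
        p_high = odds / (1 + odds)
        if rng.random() < p_high:
            high.add(e)

    base = _draw_value(rng, spec.value_distribution, spec.n_entities)
    if spec.value_distribution[0] == "uniform":
        lo, hi = spec.value_distribution[1], spec.value_distribution[2]
        shift = np.array([(hi - lo) if e in high else 0.0 for e in entities])
        base = base + shift
    else:
        base = base * np.array([HIGH_SCALE if e in high else 1.0 for e in entities])
    noise = rng.lognormal(mean=0.0, sigma=0.1,
                          size=(spec.n_entities, spec.n_samples))
    values = base[:, None] * noise
    # a sprinkle of missing values, never a whole row
    if spec.n_samples > 1:
        miss = rng.random(values.shape) < 0.01
        keep_col = rng.integers(0, spec.n_samples, size=spec.n_entities)
        miss[np.arange(spec.n_entities), keep_col] = False
        values[miss] = np.nan

    dataset = ExpressionDataset(entities, samples, values)

    annotated = {e for e in entities if rng.random() < spec.frac_annotated}
    entity_comp: dict[str, frozenset[str]] = {}
    for e in entities:
        if e not in annotated:
            continue
        k = 1 + int(rng.random() < 0.15)  # ~15% live in two compartments
        picks = rng.choice(len(comp_names), size=k, replace=False)
        entity_comp[e] = frozenset(comp_names[i] for i in picks)

    pw_sets: dict[str, set[str]] = {}
    for pw, ms in members.items():
        for e in ms:
            pw_sets.setdefault(e, set()).add(pw)
    entity_pw = {e: frozenset(v) for e, v in pw_sets.items()}

    pw_comp: dict[str, frozenset[str]] = {}
    for pw in pathways:
        k = 1 + int(rng.random() < 0.2)
        picks = rng.choice(len(comp_names), size=k, replace=False)
        pw_comp[pw] = frozenset(comp_names[i] for i in picks)

    catalog = AnnotationCatalog(
        entity_compartments=entity_comp,
        entity_pathways=entity_pw,
        pathway_compartments=pw_comp,
        universe=frozenset(entities),
    )

    go_terms, go_parents = _generate_go_dag(rng, spec.n_go_terms)
    bp_mf = [t for t, (_n, ns) in sorted(go_terms.items())
             if ns in ("biological_process", "molecular_function")]
    go_ann: dict[str, frozenset[str]] = {}
    for e in entities:
        if e not in annotated:
            continue
        k = int(rng.integers(1, 4))
        picks = rng.choice(len(bp_mf), size=min(k, len(bp_mf)), replace=False)
        go_ann[e] = frozenset(bp_mf[i] for i in picks)

    return FixtureTables(
        dataset=dataset,
        catalog=catalog,
        layout=CellLayout(compartments=[c for c in layout.compartments
                                        if c[0] in comp_names],
                          canvas=layout.canvas),
        go_terms=go_terms,
        go_parents=go_parents,
        go_annotations=go_ann,
        high_entities=frozenset(high),
    )


def _generate_go_dag(rng: np.random.Generator, n_terms: int):
    """Random acyclic term graph: one root per namespace, every other term
    gets 1-2 is_a parents among earlier terms of its namespace."""
    namespaces = ["biological_process", "molecular_function"]
    terms: dict[str, tuple[str, str]] = {}
    parents: dict[str, frozenset[str]] = {}
    per_ns = {ns: [] for ns in namespaces}
    n_each = max(n_terms // len(namespaces), 2)
    counter = 1
    for ns in namespaces:
        for j in range(n_each):
            tid = f"GO:{counter:07d}"
            counter += 1
            terms[tid] = (f"{ns.split('_')[0]} term {j}", ns)
            if per_ns[ns]:
                k = 1 + int(rng.random() < 0.3)
                pool = per_ns[ns]
                picks = rng.choice(len(pool), size=min(k, len(pool)),
                                   replace=False)
                parents[tid] = frozenset(pool[i] for i in picks)
            per_ns[ns].append(tid)
    return terms, parents


def as_go_graph(tables: FixtureTables):
    """In-memory GoGraph for a generated experiment (no OBO/GAF round trip)."""
    from .go_view import GoGraph

    g = GoGraph(terms=dict(tables.go_terms), parents=dict(tables.go_parents))
    g.annotations = dict(tables.go_annotations)
    return g


# ---------------------------------------------------------------------------
# file output
# ---------------------------------------------------------------------------

def write_obo(go_terms, go_parents, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: synthetic-go\n")
        for tid in sorted(go_terms):
            name, ns = go_terms[tid]
            fh.write(f"\n[Term]\nid: {tid}\nname: {name}\nnamespace: {ns}\n")
            for p in sorted(go_parents.get(tid, frozenset())):
                fh.write(f"is_a: {p} ! {go_terms[p][0]}\n")


def write_gaf(go_annotations, go_terms, path) -> None:
    """Minimal but well-formed 17-column GAF 2.2."""
    aspect = {"biological_process": "P", "molecular_function": "F",
              "cellular_component": "C"}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("!gaf-version: 2.2\n")
        for ent in sorted(go_annotations):
            for term in sorted(go_annotations[ent]):
                ns = go_terms[term][1]
                row = ["SYN", ent, ent, "involved_in", term, "SYN:0000001",
                       "IEA", "", aspect.get(ns, "P"), "", "", "protein",
                       "taxon:0000", "20240101", "SYN", "", ""]
                fh.write("\t".join(row) + "\n")


def generate(spec: FixtureSpec, out_dir) -> dict[str, int]:
    """Write every input file and return a manifest {path: row count}.

    The same seed always produces byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t = generate_tables(spec)

    paths = {
        "matrix": out / "matrix.tsv",
        "samples": out / "samples.txt",
        "locations": out / "locations.tsv",
        "pathways": out / "pathways.tsv",
        "pathway_compartments": out / "pathway_compartments.tsv",
        "universe": out / "universe.txt",
        "layout": out / "layout.tsv",
        "obo": out / "ontology.obo",
        "gaf": out / "annotations.gaf",
    }
    data_io.write_expression(t.dataset, paths["matrix"], paths["samples"])
    data_io.write_two_column(t.catalog.entity_compartments, paths["locations"])
    data_io.write_two_column(t.catalog.entity_pathways, paths["pathways"])
    data_io.write_two_column(t.catalog.pathway_compartments,
                             paths["pathway_compartments"])
    data_io.write_list(t.catalog.universe, paths["universe"])
    write_cell_layout(t.layout, paths["layout"])
    write_obo(t.go_terms, t.go_parents, paths["obo"])
    write_gaf(t.go_annotations, t.go_terms, paths["gaf"])

    manifest: dict[str, int] = {}
    for _key, p in paths.items():
        with open(p, encoding="utf-8") as fh:
            manifest[str(p)] = sum(1 for _ in fh)
    return manifest
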