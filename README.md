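# omicsview

Batch visualization of transcriptomic measurements in their biological
context.  Given an entities × samples value matrix (RNA-Seq summaries,
microarray intensities, log ratios, p-values — any per-gene real number),
omicsview maps each entity onto three linked displays and writes them as
deterministic SVG:

- **Cellular map** — a fixed plant-cell diagram (nucleus, vacuole,
  mitochondria/cristae, golgi apparatus, endoplasmic reticulum, apoplast,
  plastids/thylakoids, chloroplast, cytosol, plasma membrane).  Each entity
  is drawn as an icon inside every compartment its protein is annotated to;
  entities with unknown location are not drawn.
- **Pathway treemap** — nested rectangles (view → compartment → pathway)
  whose areas are proportional to how many displayed entities each pathway
  holds, with Fisher-exact over-representation highlighting.
- **GO hierarchy treemap** — the Gene Ontology Biological Process or
  Molecular Function DAG, opened level by level, with entity counts
  propagated to ancestors by the true-path rule.

It is aimed at biologists who want a first, genome-wide look at an
experiment — where in the cell, in which pathways, and under which GO
processes the responsive transcripts sit — before committing to a focused
analysis.

## The statistics underneath

**Over-representation.**  For each pathway holding at least one displayed
gene, omicsview computes the one-sided Fisher exact (hypergeometric tail)
probability

    p = Σ_{j=k}^{min(K,n)}  C(K,j) · C(N−K, n−j) / C(N,n)

where *N* is the genome universe size, *K* the pathway size, *n* the number
of displayed genes and *k* the displayed genes in the pathway.  Pathways
with *p* strictly below the user threshold (default 0.05) are outlined in
red in the pathway view; an optional Benjamini–Hochberg mode highlights on
adjusted values instead.

**Comparisons.**  Any two samples *a*, *b* can be compared per entity as a
difference (v_a − v_b), a fold change (v_a / v_b), or a difference fold
((v_a − v_b)/v_b); zero-denominator entities are excluded and tallied.

**Color coding.**  Values map onto the sequential ColorBrewer YlOrRd ramp
(light yellow → dark red, darker = higher by default) through an
equal-width binning whose range adapts to the displayed values or is fixed
by the user.  Within each compartment, icons are arranged in ascending
value order.

**Dynamic chunking.**  When a compartment cannot fit one icon per entity,
a single view-wide group size *g* — the smallest integer such that every
compartment can show ⌈n_c / g⌉ icons — makes each icon stand for up to *g*
value-adjacent entities, colored by their mean.  Single entities draw as
discs, groups as squares.

## Worked example

Enrichment on a 40-gene toy genome (`examples/pathway_enrichment.py`):

```
universe N=40, input list n=8
pathway                K   k     p-value  highlighted
glycolysis             8   8     1.3e-08  True
starch synthesis      10   2       0.659  False
```

All 8 input genes land in the 8-gene glycolysis pathway — essentially
impossible by chance (p ≈ 1.3·10⁻⁸), so the pathway would be outlined in
red.  Two of ten starch-synthesis genes is what random sampling gives
(p = 0.66).  The photorespiration pathway contains no input gene and is
not tested at all.

Comparison statistics and coloring (`examples/compare_and_color.py`):

```
difference       psbA=80, rbcL=0, cab1=-45, lhcb2=33  (excluded zero-denominator: 0)
fold             psbA=3, rbcL=1, cab1=0.25  (excluded zero-denominator: 1)
difference_fold  psbA=2, rbcL=0, cab1=-0.75  (excluded zero-denominator: 1)

auto color range [0.25, 3], 9 bins:
  psbA: value 3 -> bin 8 -> #800026
  rbcL: value 1 -> bin 2 -> #FED976
  cab1: value 0.25 -> bin 0 -> #FFFFCC
```

A full batch run (`examples/render_views.py`) generates a synthetic
experiment and renders all three views; each SVG gets a sibling `.log`
with per-stage entity counts and the solved entities-per-icon factor.

## Command line

```sh
omicsview fixtures --out demo --seed 1          # synthetic input set
omicsview cellmap  --matrix demo/matrix.tsv --samples demo/samples.txt \
    --loc demo/locations.tsv --pathways demo/pathways.tsv \
    --pathway-compartments demo/pathway_compartments.tsv \
    --universe demo/universe.txt --sample S1 -o cell.svg
omicsview pathways ... --compare S1 S2 --mode fold --p-threshold 0.01
omicsview go ... --namespace bp --obo demo/ontology.obo --gaf demo/annotations.gaf
omicsview combined ... --views cellmap pathways --sample S1
omicsview enrich ... --sample S1 --min-value 50     # TSV report only
omicsview describe ... g00001 g00002                # annotation dump
```

Outputs are byte-identical across reruns with identical inputs, and every
icon element carries `data-entities` / `data-value` / `data-bin` attributes
for downstream inspection.

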