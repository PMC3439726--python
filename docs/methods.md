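# Methods

This note documents the models, conventions and deliberate design choices
behind omicsview, in the order the pipeline applies them: input handling,
value statistics and coloring, chunking and placement, treemap layout,
enrichment, GO handling, rendering, and the synthetic-data generator used
throughout the tests.

## Input model

All tabular inputs share one dialect: UTF-8, tab-separated, `#`-comment
lines ignored, first column is the key.  The expression matrix may carry a
header row naming the samples in any order (columns are re-ordered to the
sample-list order) or be headerless with column order taken from the
sample list; a convenience reader also accepts a single combined file
whose first row lists the samples.  Blank cells are missing values.
Missing values never enter color ranges, comparisons or filters: an entity
missing in the displayed sample is simply absent from that view.

Microarray probe ids are translated through a two-column probe → gene
table; probes sharing a gene are aggregated by the arithmetic mean of
present values (an unbiased default; max/first aggregation is deliberately
not offered), and unmapped probes are dropped with a logged count.

Replicate handling is out of scope: the input matrix is assumed to be
already summarized (e.g. replicate means), which matches how such
experiments are normally exported.

The annotation catalog enforces two cross-file invariants at load time:
every pathway referenced by a gene must have at least one compartment
assignment, and every pathway-annotated gene must belong to the genome
universe file.  The universe is the supplied genome list, not the union of
annotations — enrichment is only meaningful against a fixed background.
Validation errors always name the file, line and offending identifier.

## Comparison statistics and the min-value filter

Two samples are compared per entity as a difference (v_a − v_b), a fold
change (v_a / v_b) or a difference fold ((v_a − v_b)/v_b); the identity
difference_fold = fold − 1 is verified to 1e-12 in the tests.  Entities
with v_b = 0 under the two ratio modes are excluded rather than mapped to
±∞ (which would destroy the color scale) or raised as errors; the
exclusion count is logged and carried on the result vector.

The min-value pre-filter keeps entities whose maximum present value is
*strictly* greater than the threshold ("over T in at least one sample").
It is idempotent by construction.  A threshold that would remove every
entity is reported as an error, since an empty dataset cannot be displayed.

## Color scale

Values map to bins on the 9-class ColorBrewer YlOrRd ramp.  The default
bin count is 9 (the maximal YlOrRd class count); other counts interpolate
the 9 anchors linearly per RGB channel.  Binning is equal-width and
half-open — bin i covers [vmin + i·w, vmin + (i+1)·w), w =
(vmax − vmin)/n_bins, top bin closed — with out-of-range values saturating
at the end bins, so a user-narrowed range behaves as a clip.  A degenerate
scale (constant vector) sends everything to the middle bin, implying
neither high nor low signal.  Higher = darker by default; `reversed`
flips the ramp.

## Chunking and icon placement

Compartment capacity is a grid count: cells of side icon_size + padding
inside the region shrunk by the padding on each edge,
⌊usable_w/cell⌋·⌊usable_h/cell⌋.  The entities-per-icon factor g is
solved once per view as max_c ⌈n_c / cap_c⌉ (floored at 1), the smallest
value letting every compartment display all of its entities; a populated
compartment with zero capacity (icon larger than the region) is an error
naming the compartment.  The same solver runs over treemap leaves for the
pathway and GO views, and re-runs at the reduced area of combined views,
so g can grow when screen space shrinks.

Within a compartment, entities are sorted ascending by value with ties
broken by entity id (determinism), chunked into consecutive runs of g
(the last run may be shorter), and each icon takes the arithmetic mean of
its members as its representative value and color.  Icons are placed
row-major on the capacity grid.  A single entity draws as a disc, a
multi-entity group as a square.  `--max-per-icon` lets the user cap the
group size and errors if the cap is below the solved minimum.

Whether g should be shared across compartments or solved per compartment
is genuinely open; a single shared g was chosen so that icon "weight" is
comparable across the whole view.

## Treemap layout

The squarified variant was chosen from the treemap family: it keeps
aspect ratios near 1 (readable rectangles) and has a published row-by-row
algorithm that an independent transcription can be checked against.  At
each level, children sorted by descending weight (name tiebreak) tile the
parent's interior — the parent rectangle shrunk by `inner_pad` (default 4
canvas units) — with areas exactly proportional to weights; rows are laid
along the shorter free side, and an item joins the current row while it
does not worsen the row's worst aspect ratio (ties continue the row).
Proportionality and tiling hold to 1e-9 relative tolerance in the tests,
and the layout beats slice-and-dice's worst aspect ratio on ≥95% of
random instances.

Pathway leaf weights count displayed entities with duplication: an entity
in m pathways spanning k compartments contributes to all m·k leaves,
matching the duplication rule of the icon views.  Zero-weight pathways
are omitted entirely rather than rendered as slivers.  Node labels are a
render-level decoration (truncated with an ellipsis, full name in a title
element) and take no part in the area accounting.

## Enrichment

One-sided (over-representation) Fisher exact test per pathway containing
at least one displayed gene: p = Σ_{j=k}^{min(K,n)} C(K,j)C(N−K,n−j)/C(N,n),
evaluated through the scipy hypergeometric survival function (stable
log-gamma route); the tests pin it against exact rational arithmetic to
1e-12 over every instance with N ≤ 30.  N is the universe size, n the
displayed-entity count *after* filtering — the displayed set is what the
user is looking at, and its size is logged so the choice is transparent.
Raw p-values are compared to the user threshold with strict inequality
(p exactly at the threshold is not flagged); no multiple-testing
correction is applied by default, with Benjamini–Hochberg available
behind `--fdr`.  Results are sorted by (p, pathway name).

## Gene Ontology views

The OBO reader (via obonet) keeps id, name, namespace and `is_a` edges,
drops obsolete terms, and verifies acyclicity; only `is_a` is traversed —
the conservative core of the true-path rule (part_of and regulates
reasoning is out of scope).  Annotations come from GAF 2.x (NOT-qualified
rows skipped, unknown terms skipped with a logged count) or a two-column
TSV.  `entities_at_term` counts each displayed entity once per term if it
is annotated to the term or any descendant, so counts are monotone
non-increasing down the DAG and the namespace root holds every annotated
displayed entity.

The rendered tree mirrors an expansion frontier.  Because the batch tool
has no mouse, the level buttons become `--expand-depth D` (expand every
populated term whose shortest-path depth from the root is < D, default 2);
programmatic `expand`/`collapse` cover per-term interaction, with collapse
pruning expanded descendants that lose their expanded ancestor.  Inside an
expanded rectangle, entities whose specific annotations fall under no
shown child gather in a residual "(other)" leaf, so every rectangle's
children cover exactly its entity set — nothing disappears on expansion.
An entity under several children appears under each.  Rectangle fills
cycle a blue depth palette, deliberately disjoint from the YlOrRd icon
ramp.  Cellular-component is parsed but not offered as a view.

## Rendering

SVG is the sole output: text, diffable, and byte-identical across runs —
element order follows the deterministic orderings upstream and all
numbers pass through one fixed two-decimal formatter.  Icons carry
`data-entities`, `data-value` and `data-bin` attributes, and pathway
rectangles carry their p-value in a `<title>` element (the static analog
of hover text); over-represented pathways get a 2-unit red border (the
red treatment was open; a border keeps the fill's compartment color
legible).  The legend shows the ramp with vmin/vmax ticks, the disc/square
key and the current g.  Combined views place two half-width renders side
by side and must share one color scale; each half re-solves chunking at
its reduced area.  The annotation panel of an interactive tool becomes
`describe`, a TSV dump with one row per unique entity.

## Synthetic data generator

The generator emulates a summarized transcriptomic experiment: 500 genes
× 4 samples by default, values from lognormal(μ=3, σ=1) — skewed,
expression-like, median ≈ 20 — times per-sample lognormal(0, 0.1) noise,
with ~1% missing cells (never a whole row).  80% of genes carry
compartment and GO annotation (~15% in two compartments); each of 20
pathways samples 3–6% of the genome; the GO graph gets one root per
namespace and 1–2 parents per term, guaranteeing a DAG.  A "high
responder" flag (base probability 0.2) multiplies a gene's value by 8,
lifting most high genes over the conventional display cutoff of 50 used
in the enrichment experiments.

Planted over-representation multiplies the *odds* of the high flag for
every member of a chosen pathway; with multiplier 10 and 2000 genes the
planted pathway is the minimum-p result in ≥90% of seeds, while with
multiplier 1 membership and values are independent, so pathway p-values
are (super-)uniform and ≤8% fall below 0.05 across seeds.  One integer
seed drives a single numpy Generator stream and determines every output
byte.

What the generator does not emulate: microarray noise models, count
overdispersion, correlated co-expression modules, realistic GO term sizes
or annotation bias.  Passing tests therefore demonstrate the correctness
of the mechanics (counting, propagation, layout, calibration under
independence), not performance on any real organism's annotation
structure.

## Problem sizes in the tests and acceptance script

The shipped checks use what the statistics need and no more: exhaustive
hypergeometric verification to N ≤ 30 (N ≤ 20 in the script), 200 random
trees / 500 packing instances / 50 planted and 100 null seeds.  All run
in seconds; the sizes are stated here so they can be scaled up freely.

## Known limitations

- Regions are axis-aligned rectangles; organelle shapes are stylized.
- One shared color scale per (combined) view; per-panel scales and log
  transforms are the user's job upstream.
- `keep-over`/`keep-under` are symmetric strict thresholds combined with
  AND; other combination semantics would need explicit flags.
- The GO residual-leaf convention inflates an expanded term's apparent
  child-weight sum relative to its own entity count when annotations
  overlap several children; weights are counts of (entity, rectangle)
  pairs, not unique entities.
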