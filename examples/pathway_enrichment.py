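"""Pathway over-representation on a small hand-built catalog.

Builds a 40-gene genome with three pathways, declares 8 genes as the
"interesting" input list, and tests each pathway for over-representation
with the one-sided Fisher exact (hypergeometric tail) test.
"""

from omicsview import AnnotationCatalog, test_all_pathways

universe = frozenset(f"g{i}" for i in range(40))
pathways = {
    "glycolysis": {f"g{i}" for i in range(8)},        # fully hit by the input
    "starch synthesis": {f"g{i}" for i in range(6, 16)},
    "photorespiration": {f"g{i}" for i in range(30, 40)},
}
entity_pathways = {}
for pw, members in pathways.items():
    for e in members:
        entity_pathways.setdefault(e, set()).add(pw)

catalog = AnnotationCatalog(
    entity_compartments={},
    entity_pathways={e: frozenset(s) for e, s in entity_pathways.items()},
    pathway_compartments={p: frozenset({"cytosol"}) for p in pathways},
    universe=universe,
)

displayed = {f"g{i}" for i in range(8)}  # the uploaded gene list
results = test_all_pathways(catalog, displayed, threshold=0.05)

print(f"universe N={len(universe)}, input list n={len(displayed)}")
print(f"{'pathway':<20}{'K':>4}{'k':>4}  {'p-value':>10}  highlighted")
for r in results:
    print(f"{r.pathway:<20}{r.input.K:>4}{r.input.k:>4}  "
          f"{r.p_value:>10.3g}  {r.highlighted}")
# p is the chance of seeing >= k input genes in a size-K pathway when n
# genes are drawn from the N-gene genome; pathways with p < 0.05 would be
# outlined in red in the pathway view.
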