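"""Pathway over-representation by the one-sided Fisher exact test.

For each pathway holding at least one displayed gene, the probability of
seeing that many or more displayed genes in the pathway by chance is the
upper tail of the hypergeometric distribution with

    N = genome universe size
    K = pathway size within the universe
    n = displayed (input-list) genes
    k = displayed genes in the pathway

    p = sum_{j=k}^{min(K,n)} C(K,j) C(N-K, n-j) / C(N,n)

Pathways with p strictly below the user threshold are flagged for red
highlighting in the pathway view.  No multiple-testing correction is
applied by default; an optional Benjamini-Hochberg mode highlights on the
adjusted values instead.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom

from .data_io import AnnotationCatalog
from .errors import ValidationError

DEFAULT_P_THRESHOLD = 0.05


@dataclass(frozen=True)
class EnrichmentInput:
    """The 2x2 counts of one pathway test."""

    N: int
    K: int
    n: int
    k: int

    def __post_init__(self):
        ok = (0 <= self.k <= min(self.K, self.n)
              and 0 <= self.K <= self.N and 0 <= self.n <= self.N)
        if not ok:
            raise ValidationError(
                f"inconsistent contingency counts N={self.N} K={self.K} "
                f"n={self.n} k={self.k}"
            )


@dataclass
class EnrichmentResult:
    pathway: str
    input: EnrichmentInput
    p_value: float
    highlighted: bool


def hypergeom_tail(inp: EnrichmentInput) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n)."""
    # sf(k-1) = P(X >= k); survival-function route is numerically stable
    return float(hypergeom.sf(inp.k - 1, inp.N, inp.K, inp.n))


def test_all_pathways(catalog: AnnotationCatalog, displayed_entities: set,
                      threshold: float = DEFAULT_P_THRESHOLD,
                      fdr: bool = False) -> list[EnrichmentResult]:
    """One test per pathway containing >= 1 displayed gene.

    Displayed entities must all come from the genome universe (the test's
    background); results are sorted ascending by p then pathway name, and
    highlighting uses strict inequality (p exactly at the threshold is not
    flagged).  With ``fdr=True`` highlighting is on Benjamini-Hochberg
    adjusted p-values instead of raw ones.
    """
    if not 0 < threshold <= 1:
        raise ValidationError(f"p threshold must lie in (0, 1], got {threshold}")
    displayed = set(displayed_entities)
    stray = sorted(displayed - set(catalog.universe))
    if stray:
        raise ValidationError(
            "displayed entities outside the genome universe: "
            + ", ".join(stray[:10]) + ("..." if len(stray) > 10 else "")
        )

    members: dict[str, set[str]] = {}
    for ent, pws in catalog.entity_pathways.items():
        for pw in pws:
            members.setdefault(pw, set()).add(ent)

    N = len(catalog.universe)
    n = len(displayed)
    results: list[EnrichmentResult] = []
    for pw in sorted(members):
        in_universe = members[pw] & set(catalog.universe)
        k = len(in_universe & displayed)
        if k < 1:
            continue
        inp = EnrichmentInput(N=N, K=len(in_universe), n=n, k=k)
        p = hypergeom_tail(inp)
        results.append(EnrichmentResult(pw, inp, p, highlighted=False))

    results.sort(key=lambda r: (r.p_value, r.pathway))
    if fdr and results:
        from statsmodels.stats.multitest import multipletests
        _rej, q, _a, _b = multipletests([r.p_value for r in results], method="fdr_bh")
        for r, qv in zip(results, q):
            r.q_value = float(qv)
            r.highlighted = qv < threshold
    else:
        for r in results:
            r.highlighted = r.p_value < threshold
    return results


def write_report(results: list[EnrichmentResult], path) -> None:
    """TSV report: pathway, N, K, n, k, p_value, highlighted."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pathway\tN\tK\tn\tk\tp_value\thighlighted\n")
        for r in results:
            fh.write(
                f"{r.pathway}\t{r.input.N}\t{r.input.K}\t{r.input.n}\t"
                f"{r.input.k}\t{r.p_value:.6g}\t{int(r.highlighted)}\n"
            )
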