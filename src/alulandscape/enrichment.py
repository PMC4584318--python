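"""Statistical tests for repeat and gene-set enrichment.

Covers the 2x2 chi-square test used for repeat over-representation, the
Welch two-sample t-test for GC-content comparisons, the right-tail Fisher
exact (hypergeometric) probability, the conservative EASE variant that
removes one supporting gene before computing the tail, Bonferroni
correction, and the group enrichment score (minus log10 of the geometric
mean of EASE scores, so 1.3 corresponds to 0.05).

Tail probabilities are accumulated in log space so extremely significant
terms do not underflow; the familiar "< 2.2e-16" floor is applied only in
the display helper, never to stored values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "EnrichmentRow",
    "chi_square_2x2",
    "welch_t_test",
    "fisher_right_tail",
    "ease_score",
    "bonferroni",
    "group_enrichment_score",
    "enrich_terms",
    "format_p",
]

#: display floor used when printing p-values (machine-epsilon convention)
P_DISPLAY_FLOOR = 2.2e-16


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = target vs background, columns = hit vs non-hit."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float


@dataclass(frozen=True)
class EnrichmentRow:
    term: str
    count: int
    percent: float
    p_value: float
    bonferroni: float


def chi_square_2x2(table: ContingencyTable2x2, yates: bool = True) -> TestResult:
    """Pearson chi-square on a 2x2 table, Yates-corrected by default."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined with a zero marginal")
    res = stats.chi2_contingency(arr, correction=yates)
    return TestResult(statistic=float(res.statistic), df=1.0, p_value=float(res.pvalue))


def welch_t_test(xs, ys) -> TestResult:
    """Welch two-sample t-test (unequal variances), two-sided."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if x.mean() == y.mean():
            return TestResult(statistic=0.0, df=float(len(x) + len(y) - 2), p_value=1.0)
        raise ValueError("zero variance in both groups with unequal means")
    se2 = vx / len(x) + vy / len(y)
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (vx / len(x)) ** 2 / (len(x) - 1) + (vy / len(y)) ** 2 / (len(y) - 1)
    )
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(statistic=float(t), df=float(df), p_value=float(min(p, 1.0)))


def _check_margins(k: int, K: int, n: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("category/list sizes must lie within the universe")
    if not 0 <= k <= min(K, n):
        raise ValueError("hit count inconsistent with margins")


def fisher_right_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), summed in log space.

    ``k`` hits from a list of ``n`` genes, a category of ``K`` genes, and a
    universe of ``N`` genes.
    """
    _check_margins(k, K, n, N)
    if k <= 0:
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    if len(support) == 0:
        return 0.0
    log_terms = stats.hypergeom.logpmf(support, N, K, n)
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def ease_score(k: int, K: int, n: int, N: int) -> float:
    """Conservative Fisher tail with one supporting gene removed.

    Equals ``fisher_right_tail(k - 1, K, n, N)`` and therefore always upper
    bounds the plain Fisher probability; undefined for k = 0.
    """
    if k < 1:
        raise ValueError("EASE score requires at least one overlapping gene")
    _check_margins(k, K, n, N)
    return fisher_right_tail(k - 1, K, n, N)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(1, p * m)."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    return min(1.0, p * m)


def group_enrichment_score(ease_scores) -> float:
    """Minus log10 of the geometric mean of EASE scores."""
    arr = np.asarray(list(ease_scores), dtype=float)
    if arr.size == 0:
        raise ValueError("need at least one EASE score")
    if (arr <= 0).any() or (arr > 1).any():
        raise ValueError("EASE scores must lie in (0, 1]")
    return float(-np.mean(np.log10(arr)))


def read_annotation_table(path) -> list[tuple[str, str]]:
    """Read a two-column gene TAB term table."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            gene, term = line.split("\t")[:2]
            rows.append((gene, term))
    return rows


def enrich_terms(
    gene_list,
    annotation_rows: list[tuple[str, str]],
    universe=None,
    min_count: int = 10,
    alpha: float | None = None,
) -> list[EnrichmentRow]:
    """Term enrichment of a gene list against an annotation table.

    The universe defaults to every gene appearing in the annotation table;
    query genes absent from the universe are dropped (unannotated genes
    cannot inform the test).  Each term with at least ``min_count``
    overlapping genes is scored by its EASE probability and
    Bonferroni-corrected over the number of tested terms.  Rows come back
    sorted by ascending p; ``alpha`` optionally filters on the EASE p.
    """
    term_genes: dict[str, set[str]] = {}
    table_genes: set[str] = set()
    for gene, term in annotation_rows:
        term_genes.setdefault(term, set()).add(gene)
        table_genes.add(gene)
    universe_set = set(universe) if universe is not None else table_genes
    if not universe_set:
        raise ValueError("empty annotation universe")
    query = set(gene_list) & universe_set
    n, N = len(query), len(universe_set)
    candidates = []
    for term in sorted(term_genes):
        members = term_genes[term] & universe_set
        k = len(members & query)
        if k >= max(min_count, 1):
            candidates.append((term, k, len(members)))
    m = len(candidates)
    rows = [
        EnrichmentRow(
            term=term,
            count=k,
            percent=100.0 * k / n if n else 0.0,
            p_value=(p := ease_score(k, K, n, N)),
            bonferroni=bonferroni(p, m),
        )
        for term, k, K in candidates
    ]
    rows.sort(key=lambda r: (r.p_value, r.term))
    if alpha is not None:
        rows = [r for r in rows if r.p_value < alpha]
    return rows


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in rows],
                        columns=["term", "count", "percent", "p_value", "bonferroni"])


def format_p(p: float, floor: float = P_DISPLAY_FLOOR) -> str:
    """Display convention: very small p-values print as '< 2.2e-16'."""
    return f"< {floor:g}" if p < floor else f"{p:.3g}"
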