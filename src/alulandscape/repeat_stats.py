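"""Aggregate repeat-hit statistics over region categories.

Reproduces the reporting conventions of repeat-landscape summary tables:
counts of repeats and Alus per category, the fraction of sequences harboring
them, base coverage on the interval union, the "one Alu per N nt" density,
sense/antisense orientation tallies, and per-gene rankings.

Two display conventions are implemented exactly as such tables print them:
ratios like densities and average lengths are *truncated* to integers, and
percentages default to truncation at a chosen precision with an explicit
rounding mode for integer prose figures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from fractions import Fraction

import pandas as pd

from .annotation import RepeatHit, is_alu

__all__ = [
    "RepeatSummary",
    "summarize",
    "density",
    "average_length",
    "percent",
    "orientation_tally",
    "rank_genes",
    "length_contributions",
    "summary_table",
]


@dataclass(frozen=True)
class RepeatSummary:
    """Per-region-category aggregate of repeat annotation results."""

    category: str
    n_sequences: int
    total_length: int
    n_repeats: int
    n_alus: int
    pct_seq_with_repeats: float
    pct_seq_with_alus: float
    alu_covered_bases: int
    pct_covered_by_alus: float
    density_nt_per_alu: int | None
    n_sense_alus: int
    n_antisense_alus: int


def density(total_length: int, n_alus: int) -> int:
    """Nucleotides per Alu element, truncated to an integer."""
    if n_alus < 1:
        raise ValueError("density undefined for zero Alu elements")
    return int(total_length) // int(n_alus)


def average_length(total_length: int, n_sequences: int) -> int:
    """Average sequence length, truncated to an integer."""
    return density(total_length, n_sequences)


def percent(
    numerator, denominator, decimals: int = 2, mode: str = "truncate"
) -> float:
    """Percentage with explicit display semantics.

    ``truncate`` (default) cuts at ``decimals`` places without rounding;
    ``round`` applies conventional half-up rounding, used for integer prose
    figures (e.g. 58.87 -> 59).
    """
    if denominator == 0:
        raise ValueError("percent undefined for zero denominator")
    scale = 10**decimals
    if float(numerator).is_integer() and float(denominator).is_integer():
        frac = Fraction(int(numerator) * 100 * scale, int(denominator))
    else:
        frac = Fraction(numerator) * 100 * scale / Fraction(denominator)
    if mode == "truncate":
        return math.floor(frac) / scale
    if mode == "round":
        return math.floor(frac + Fraction(1, 2)) / scale
    raise ValueError(f"unknown rounding mode {mode!r}")


def _union_length(intervals: list[tuple[int, int]]) -> int:
    total = 0
    current_start = current_end = None
    for start, end in sorted(intervals):
        if current_end is None or start > current_end:
            if current_end is not None:
                total += current_end - current_start
            current_start, current_end = start, end
        else:
            current_end = max(current_end, end)
    if current_end is not None:
        total += current_end - current_start
    return total


def summarize(
    hits: list[RepeatHit], sequences: list[tuple[str, str]], category: str
) -> RepeatSummary:
    """Aggregate hits over one region category.

    Covered bases are computed on the union of Alu hit intervals per
    sequence, so overlapping annotations are not double-counted.  Every
    hit's ``query_id`` must name one of ``sequences``.
    """
    ids = [name for name, _ in sequences]
    id_set = set(ids)
    for h in hits:
        if h.query_id not in id_set:
            raise ValueError(f"hit on unknown sequence {h.query_id!r}")
    total_length = sum(len(s) for _, s in sequences)
    alu_hits = [h for h in hits if is_alu(h)]
    seq_with_repeats = {h.query_id for h in hits}
    seq_with_alus = {h.query_id for h in alu_hits}
    per_seq: dict[str, list[tuple[int, int]]] = {}
    for h in alu_hits:
        per_seq.setdefault(h.query_id, []).append((h.start, h.end))
    covered = sum(_union_length(ivs) for ivs in per_seq.values())
    n = len(ids)
    n_alus = len(alu_hits)
    return RepeatSummary(
        category=category,
        n_sequences=n,
        total_length=total_length,
        n_repeats=len(hits),
        n_alus=n_alus,
        pct_seq_with_repeats=percent(len(seq_with_repeats), n) if n else 0.0,
        pct_seq_with_alus=percent(len(seq_with_alus), n) if n else 0.0,
        alu_covered_bases=covered,
        pct_covered_by_alus=percent(covered, total_length) if total_length else 0.0,
        density_nt_per_alu=density(total_length, n_alus) if n_alus else None,
        n_sense_alus=sum(1 for h in alu_hits if h.strand == "+"),
        n_antisense_alus=sum(1 for h in alu_hits if h.strand == "-"),
    )


def orientation_tally(
    alu_hits: list[RepeatHit], decimals: int = 1, mode: str = "truncate"
) -> tuple[int, int, float, float]:
    """Sense/antisense counts and display percentages for Alu hits."""
    n_sense = sum(1 for h in alu_hits if h.strand == "+")
    n_antisense = sum(1 for h in alu_hits if h.strand == "-")
    total = n_sense + n_antisense
    if total == 0:
        raise ValueError("orientation tally undefined without Alu hits")
    return (
        n_sense,
        n_antisense,
        percent(n_sense, total, decimals, mode),
        percent(n_antisense, total, decimals, mode),
    )


def rank_genes(
    per_gene_hits: dict[str, list[RepeatHit]], top_n: int | None = 20
) -> pd.DataFrame:
    """Rank genes by total repeat count (columns: gene, total_repeats, sines,
    alus).  Ties break by Alu count (descending) then gene name."""
    rows = []
    for gene, hits in per_gene_hits.items():
        rows.append(
            {
                "gene": gene,
                "total_repeats": len(hits),
                "sines": sum(1 for h in hits if h.repeat_class.startswith("SINE")),
                "alus": sum(1 for h in hits if is_alu(h)),
            }
        )
    df = pd.DataFrame(rows, columns=["gene", "total_repeats", "sines", "alus"])
    df = df.sort_values(
        ["total_repeats", "alus", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return df if top_n is None else df.head(top_n)


def length_contributions(
    utr5_len: int, cds_len: int, utr3_len: int
) -> tuple[float, float, float]:
    """Percent of mRNA length contributed by 5'UTR, CDS and 3'UTR."""
    total = utr5_len + cds_len + utr3_len
    if total <= 0:
        raise ValueError("total mRNA length must be > 0")
    if min(utr5_len, cds_len, utr3_len) < 0:
        raise ValueError("lengths must be >= 0")
    return (
        100.0 * utr5_len / total,
        100.0 * cds_len / total,
        100.0 * utr3_len / total,
    )


_ROW_LABELS = {
    "n_sequences": "Sequences",
    "total_length": "Total length (nt)",
    "n_repeats": "Total number of repeats",
    "n_alus": "Total number of Alus",
    "pct_seq_with_repeats": "Sequences harboring repeats (%)",
    "pct_seq_with_alus": "Sequences harboring Alus (%)",
    "density_nt_per_alu": "One Alu element occurrence per (nt)",
    "pct_covered_by_alus": "Percentage sequence covered by Alus (%)",
}


def summary_table(summaries: list[RepeatSummary]) -> pd.DataFrame:
    """Wide report with one column per category and the conventional row
    labels of repeat-landscape summary tables."""
    data = {}
    for s in summaries:
        d = asdict(s)
        data[s.category] = {label: d[key] for key, label in _ROW_LABELS.items()}
    return pd.DataFrame(data)
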