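"""Inverted-Alu (IRAlu) detection in 3'UTRs.

A transcript's 3'UTR harbors an IRAlu when at least one sense and one
antisense Alu element co-occur in it; such a configuration can base-pair
into a double-stranded RNA duplex.  Alu fragments of any length count
toward the co-occurrence call, while explicit sense/antisense *pairs* (the
candidates handed to the folding stage) additionally require both elements
to reach a minimum length, separating the inventory of fragments from the
pairs worth folding.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .annotation import RepeatHit, is_alu

__all__ = [
    "IRAluPair",
    "IRAluRow",
    "find_iralus",
    "build_report",
    "tabulate_iralu_genes",
    "read_iralu_table",
    "synthetic_iralu_validation",
]


@dataclass(frozen=True)
class IRAluPair:
    """A sense/antisense Alu pair within one transcript's 3'UTR."""

    transcript_id: str
    sense_hit: RepeatHit
    antisense_hit: RepeatHit
    gap: int  # nt between the pair's inner boundaries (0 if overlapping)
    combined_score: int


@dataclass(frozen=True)
class IRAluRow:
    """One transcript's 3'UTR Alu inventory (machine form of a report row)."""

    gene: str
    transcript: str
    total_alus: int
    subfamilies: tuple[str, ...]
    lengths: tuple[int, ...]
    directions: tuple[str, ...]  # "s" / "a", transcript orientation
    biotype: str
    is_iralu: bool


def _pair_gap(a: RepeatHit, b: RepeatHit) -> int:
    left, right = (a, b) if a.start <= b.start else (b, a)
    return max(0, right.start - left.end)


def find_iralus(
    utr_hits: list[RepeatHit],
    min_alu_length: int = 100,
    transcript_id: str = "",
) -> tuple[list[IRAluPair], bool]:
    """Enumerate sense/antisense Alu pairs within one 3'UTR.

    ``utr_hits`` must be the hits of a single transcript's 3'UTR in
    transcript-oriented coordinates.  The IRAlu call itself requires only
    co-occurrence of both orientations among Alu hits of any length; the
    returned pair list is restricted to pairs whose two elements are both at
    least ``min_alu_length`` long.  Pairs are ordered by descending combined
    score, then smaller gap, then leftmost position, so the first entry is
    the primary pair for folding.
    """
    alus = [h for h in utr_hits if is_alu(h)]
    sense = [h for h in alus if h.strand == "+"]
    antisense = [h for h in alus if h.strand == "-"]
    is_iralu = bool(sense) and bool(antisense)
    tid = transcript_id or (alus[0].query_id if alus else "")
    pairs = [
        IRAluPair(
            transcript_id=tid,
            sense_hit=s,
            antisense_hit=a,
            gap=_pair_gap(s, a),
            combined_score=s.score + a.score,
        )
        for s in sense
        if s.length >= min_alu_length
        for a in antisense
        if a.length >= min_alu_length
    ]
    pairs.sort(
        key=lambda p: (
            -p.combined_score,
            p.gap,
            min(p.sense_hit.start, p.antisense_hit.start),
        )
    )
    return pairs, is_iralu


def build_report(
    utr_hits_by_transcript: dict[str, list[RepeatHit]],
    gene_of_transcript: dict[str, str],
    biotype_of_transcript: dict[str, str] | None = None,
    min_alu_length: int = 100,
) -> list[IRAluRow]:
    """Per-transcript IRAlu report rows from 3'UTR hit lists."""
    biotype_of_transcript = biotype_of_transcript or {}
    rows = []
    for tid in sorted(utr_hits_by_transcript):
        hits = sorted(utr_hits_by_transcript[tid], key=lambda h: h.start)
        alus = [h for h in hits if is_alu(h)]
        if not alus:
            continue
        _, flag = find_iralus(hits, min_alu_length=min_alu_length, transcript_id=tid)
        rows.append(
            IRAluRow(
                gene=gene_of_transcript.get(tid, tid),
                transcript=tid,
                total_alus=len(alus),
                subfamilies=tuple(h.family for h in alus),
                lengths=tuple(h.length for h in alus),
                directions=tuple("s" if h.strand == "+" else "a" for h in alus),
                biotype=biotype_of_transcript.get(tid, "protein_coding"),
                is_iralu=flag,
            )
        )
    return rows


def _is_protein_coding(biotype: str) -> bool:
    return biotype.lower().replace("_", " ").startswith("protein coding")


def tabulate_iralu_genes(rows: list[IRAluRow]) -> tuple[int, int]:
    """Distinct genes with an IRAlu-positive transcript, overall and
    restricted to protein-coding transcript biotypes."""
    genes = {r.gene for r in rows if r.is_iralu}
    coding = {r.gene for r in rows if r.is_iralu and _is_protein_coding(r.biotype)}
    return len(genes), len(coding)


def read_iralu_table(path) -> list[IRAluRow]:
    """Read a TSV report of 3'UTR Alu inventories.

    Expected columns: gene, transcript, total_alus, subfamilies, lengths,
    directions (";"-joined, "s"/"a"), biotype.  The IRAlu flag is recomputed
    from the directions column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    rows = []
    for rec in df.itertuples(index=False):
        directions = tuple(d.strip() for d in rec.directions.split(";"))
        rows.append(
            IRAluRow(
                gene=rec.gene,
                transcript=rec.transcript,
                total_alus=int(rec.total_alus),
                subfamilies=tuple(s.strip() for s in rec.subfamilies.split(";")),
                lengths=tuple(int(x) for x in rec.lengths.split(";")),
                directions=directions,
                biotype=rec.biotype,
                is_iralu="s" in directions and "a" in directions,
            )
        )
    return rows


def write_iralu_table(rows: list[IRAluRow], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "gene\ttranscript\ttotal_alus\tsubfamilies\tlengths\tdirections\tbiotype\tis_iralu\n"
        )
        for r in rows:
            fh.write(
                f"{r.gene}\t{r.transcript}\t{r.total_alus}\t"
                f"{';'.join(r.subfamilies)}\t{';'.join(map(str, r.lengths))}\t"
                f"{';'.join(r.directions)}\t{r.biotype}\t{r.is_iralu}\n"
            )


def synthetic_iralu_validation(
    utr_bundles, library: dict[str, str], params=None, min_alu_length: int = 100
) -> dict[str, int]:
    """Confusion counts of the detector's IRAlu call against planted truth.

    ``utr_bundles`` is an iterable of (utr_sequence, truth) pairs as
    produced by the synthetic generator.
    """
    from .annotation import AlignmentParams, scan

    params = params or AlignmentParams()
    counts = {"tp": 0, "fp": 0, "tn": 0, "fn": 0}
    for i, (utr_seq, truth) in enumerate(utr_bundles):
        hits = scan(utr_seq, library, params, query_id=f"utr_{i}")
        _, called = find_iralus(hits, min_alu_length=min_alu_length)
        if truth.is_iralu:
            counts["tp" if called else "fn"] += 1
        else:
            counts["fp" if called else "tn"] += 1
    return counts
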