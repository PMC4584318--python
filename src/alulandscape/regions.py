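"""Gene and transcript region handling.

Builds transcript structures (CDS, introns, 5'UTR, 3'UTR) from GFF3, splices
out region sequences in transcript orientation, and maps repeat hits or point
positions (e.g. SNPs) onto annotated intervals.

GFF3 coordinates (1-based inclusive) are converted to 0-based half-open at
read time; all in-memory intervals use the half-open convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import gffutils
from intervaltree import IntervalTree

from .seqs import revcomp

__all__ = [
    "GeneModel",
    "TranscriptModel",
    "read_gff3",
    "write_gff3",
    "extract_region_sequences",
    "gc_content",
    "annotate_positions",
]

REGION_CATEGORIES = ("genes", "cds", "introns", "utr5", "utr3")

Interval = tuple[int, int]


@dataclass
class TranscriptModel:
    transcript_id: str
    seqid: str
    strand: str  # "+" or "-"
    biotype: str = "protein_coding"  # protein_coding | nonsense_mediated_decay | other
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    @property
    def introns(self) -> list[Interval]:
        """Gaps between consecutive exons, in genomic order."""
        exons = sorted(self.exons)
        return [
            (prev_end, start)
            for (_, prev_end), (start, _) in zip(exons, exons[1:])
            if start > prev_end
        ]

    @property
    def span(self) -> Interval:
        exons = sorted(self.exons)
        return (exons[0][0], exons[-1][1])


@dataclass
class GeneModel:
    gene_id: str
    transcripts: list[TranscriptModel]

    @property
    def seqid(self) -> str:
        return self.transcripts[0].seqid

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def span(self) -> Interval:
        starts, ends = zip(*(t.span for t in self.transcripts))
        return (min(starts), max(ends))


_BIOTYPES = {"protein_coding", "nonsense_mediated_decay"}


def _biotype(feature) -> str:
    for key in ("biotype", "transcript_biotype", "gene_biotype"):
        if key in feature.attributes:
            value = feature.attributes[key][0]
            return value if value in _BIOTYPES else "other"
    return "protein_coding"


def read_gff3(path) -> list[GeneModel]:
    """Read gene models from GFF3 (gene / mRNA / exon / CDS / UTR features).

    Raises a parse error listing offending feature IDs when any feature
    references a Parent that does not exist in the file.
    """
    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    known_ids = {f.id for f in db.all_features()}
    orphans = sorted(
        {
            parent
            for feat in db.all_features()
            for parent in feat.attributes.get("Parent", [])
            if parent not in known_ids
        }
    )
    if orphans:
        raise ValueError(f"GFF3 orphan Parent references: {', '.join(orphans)}")

    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        transcripts: list[TranscriptModel] = []
        for tx in db.children(gene, level=1):
            if tx.featuretype not in ("mRNA", "transcript"):
                continue
            model = TranscriptModel(
                transcript_id=tx.id,
                seqid=tx.seqid,
                strand=tx.strand,
                biotype=_biotype(tx),
            )
            for child in db.children(tx, order_by="start"):
                iv = (child.start - 1, child.end)  # to 0-based half-open
                if child.featuretype == "exon":
                    model.exons.append(iv)
                elif child.featuretype == "CDS":
                    model.cds.append(iv)
                elif child.featuretype == "five_prime_UTR":
                    model.utr5.append(iv)
                elif child.featuretype == "three_prime_UTR":
                    model.utr3.append(iv)
            if model.exons:
                transcripts.append(model)
        if transcripts:
            genes.append(GeneModel(gene_id=gene.id, transcripts=transcripts))
    return genes


def write_gff3(models: list[GeneModel], path) -> None:
    """Write gene models as GFF3 (1-based inclusive on output)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in models:
            g_start, g_end = gene.span
            fh.write(
                f"{gene.seqid}\t.\tgene\t{g_start + 1}\t{g_end}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            for tx in gene.transcripts:
                t_start, t_end = tx.span
                fh.write(
                    f"{tx.seqid}\t.\tmRNA\t{t_start + 1}\t{t_end}\t.\t{tx.strand}\t.\t"
                    f"ID={tx.transcript_id};Parent={gene.gene_id};biotype={tx.biotype}\n"
                )
                for ftype, ivs in (
                    ("exon", tx.exons),
                    ("five_prime_UTR", tx.utr5),
                    ("CDS", tx.cds),
                    ("three_prime_UTR", tx.utr3),
                ):
                    for start, end in sorted(ivs):
                        fh.write(
                            f"{tx.seqid}\t.\t{ftype}\t{start + 1}\t{end}\t.\t"
                            f"{tx.strand}\t.\tParent={tx.transcript_id}\n"
                        )


def _splice(genome: dict[str, str], seqid: str, intervals: list[Interval], strand: str) -> str:
    chrom = genome[seqid]
    for start, end in intervals:
        if start < 0 or end > len(chrom):
            raise ValueError(
                f"interval [{start},{end}) out of bounds for {seqid} "
                f"(length {len(chrom)})"
            )
    seq = "".join(chrom[s:e] for s, e in sorted(intervals))
    return revcomp(seq) if strand == "-" else seq


def extract_region_sequences(
    models: list[GeneModel], genome: dict[str, str]
) -> dict[str, list[tuple[str, str]]]:
    """Spliced, transcript-oriented sequences per region category.

    Returns {category: [(id, sequence), ...]} for the categories ``genes``
    (one per gene, whole span), and ``cds``/``introns``/``utr5``/``utr3``
    (one per isoform that annotates the category).  Minus-strand sequences
    are reverse-complemented so that "sense" downstream always means
    transcript orientation.
    """
    out: dict[str, list[tuple[str, str]]] = {c: [] for c in REGION_CATEGORIES}
    for gene in models:
        start, end = gene.span
        out["genes"].append(
            (gene.gene_id, _splice(genome, gene.seqid, [(start, end)], gene.strand))
        )
        for tx in gene.transcripts:
            for category, ivs in (
                ("cds", tx.cds),
                ("introns", tx.introns),
                ("utr5", tx.utr5),
                ("utr3", tx.utr3),
            ):
                if ivs:
                    out[category].append(
                        (tx.transcript_id, _splice(genome, tx.seqid, ivs, tx.strand))
                    )
    return out


def gc_content(seq: str) -> float:
    """(G+C) / (A+C+G+T); N is excluded from both numerator and denominator."""
    seq = seq.upper()
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("gc_content undefined for empty or all-N sequence")
    return (counts["G"] + counts["C"]) / total


def annotate_positions(hits, positions):
    """Overlap point positions with repeat hits.

    ``positions`` is a list of (query_id, 0-based position); a position
    overlaps a hit iff start <= position < end on the same query.  Returns a
    list of (query_id, position, hit-or-None); when several hits cover a
    position the highest-scoring one is reported.
    """
    trees: dict[str, IntervalTree] = {}
    for h in hits:
        trees.setdefault(h.query_id, IntervalTree()).addi(h.start, h.end, h)
    out = []
    for query_id, pos in positions:
        tree = trees.get(query_id)
        matches = sorted(tree[pos], key=lambda iv: -iv.data.score) if tree else []
        out.append((query_id, pos, matches[0].data if matches else None))
    return out
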