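"""Repeat annotation: a seed-and-extend detector plus RepeatMasker interop.

The detector finds matches between query sequences and a consensus repeat
library on both strands.  Exact k-mer seeds are clustered by diagonal and
each cluster's window is scored by optimal local alignment against the
consensus, so every reported score is a true Smith-Waterman score for the
reported interval.  A reader/writer pair for the RepeatMasker ``.out``
dialect maps pre-computed annotations onto the same hit model.

Coordinates are 0-based half-open everywhere in memory; conversions to the
1-based inclusive ``.out`` convention happen only at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import biotite.sequence as btseq
import biotite.sequence.align as btalign

from .seqs import revcomp

__all__ = [
    "AlignmentParams",
    "RepeatHit",
    "scan",
    "resolve_overlaps",
    "read_repeatmasker_out",
    "write_repeatmasker_out",
    "write_bed",
    "is_alu",
    "classify_family",
]

#: repeat classes recognized in the hit model
REPEAT_CLASSES = ("SINE/Alu", "SINE/other", "LINE", "LTR", "DNA", "other")

#: family-name prefixes of the Alu clade, including the free monomers
_ALU_PREFIXES = ("Alu", "FLAM", "FRAM", "FAM")


@dataclass(frozen=True)
class AlignmentParams:
    """Detector scoring and filtering parameters (BLAST-like defaults)."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    seed_k: int = 12
    xdrop: int = 30
    min_score: int = 200
    min_length: int = 50

    def __post_init__(self) -> None:
        if not (self.match > 0 > self.mismatch):
            raise ValueError("need match > 0 > mismatch")
        if self.min_length < self.seed_k:
            raise ValueError("min_length must be >= seed_k")


@dataclass(frozen=True)
class RepeatHit:
    """One annotated repeat occurrence on a query sequence."""

    query_id: str
    start: int  # 0-based
    end: int  # half-open
    strand: str  # "+" sense, "-" antisense (relative to the query)
    family: str
    repeat_class: str
    score: int
    divergence_pct: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("hit interval must be non-empty (start < end)")
        if not 0.0 <= self.divergence_pct <= 100.0:
            raise ValueError("divergence_pct must be in [0, 100]")

    @property
    def length(self) -> int:
        return self.end - self.start


def classify_family(family: str, class_field: str | None = None) -> str:
    """Map a repeat family name (and optional class string) to a repeat class.

    An explicit RepeatMasker-style ``class/family`` string wins; otherwise the
    class is inferred from the family-name prefix.  ``SINE/Alu`` covers the
    dimeric subfamilies as well as the FLAM/FRAM/FAM monomers and bare "Alu".
    """
    if class_field:
        upper = class_field.upper()
        if upper.startswith("SINE/ALU"):
            return "SINE/Alu"
        if upper.startswith("SINE"):
            return "SINE/other"
        for cls in ("LINE", "LTR", "DNA"):
            if upper.startswith(cls):
                return cls
        return "other"
    if any(family.startswith(p) for p in _ALU_PREFIXES):
        return "SINE/Alu"
    if family.upper().startswith(("L1", "L2", "LINE")):
        return "LINE"
    return "other"


def is_alu(hit: RepeatHit) -> bool:
    """True iff the hit belongs to the Alu clade (class SINE/Alu)."""
    return hit.repeat_class == "SINE/Alu"


# ---------------------------------------------------------------------------
# seed-and-extend scanning
# ---------------------------------------------------------------------------

_ALPHABET = btseq.NucleotideSequence.alphabet_amb


def _substitution_matrix(params: AlignmentParams) -> btalign.SubstitutionMatrix:
    n = len(_ALPHABET)
    mat = np.full((n, n), params.mismatch, dtype=np.int32)
    for base in "ACGT":
        i = _ALPHABET.encode(base)
        mat[i, i] = params.match
    return btalign.SubstitutionMatrix(_ALPHABET, _ALPHABET, mat)


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _cluster_diagonals(diags: list[int], band: int) -> list[list[int]]:
    """Group sorted diagonal values into runs closer than ``band``."""
    diags = sorted(diags)
    clusters: list[list[int]] = [[diags[0]]]
    for d in diags[1:]:
        if d - clusters[-1][-1] <= band:
            clusters[-1].append(d)
        else:
            clusters.append([d])
    return clusters


def _align_window(
    window_seq: str,
    window_start: int,
    target: str,
    matrix: btalign.SubstitutionMatrix,
    params: AlignmentParams,
) -> tuple[int, int, int, float] | None:
    """Best local alignment of a query window against one consensus strand.

    Returns (query_start, query_end, score, divergence_pct) in full-query
    coordinates, or None when nothing aligns.
    """
    try:
        q = btseq.NucleotideSequence(window_seq)
        t = btseq.NucleotideSequence(target)
    except Exception:
        return None
    alns = btalign.align_optimal(
        q, t, matrix, gap_penalty=(params.gap_open, params.gap_extend),
        local=True, max_number=1,
    )
    if not alns or alns[0].score <= 0:
        return None
    aln = alns[0]
    trace = aln.trace
    q_cols = trace[:, 0]
    q_positions = q_cols[q_cols != -1]
    q_start = int(q_positions.min())
    q_end = int(q_positions.max()) + 1
    codes = btalign.get_codes(aln)
    both = (codes[0] != -1) & (codes[1] != -1)
    mismatches = int(np.sum(codes[0][both] != codes[1][both]))
    aligned_cols = int(both.sum())
    div = 100.0 * mismatches / aligned_cols if aligned_cols else 0.0
    return window_start + q_start, window_start + q_end, int(aln.score), div


def scan(
    query: str,
    library: dict[str, str],
    params: AlignmentParams = AlignmentParams(),
    query_id: str = "query",
    resolve: bool = True,
) -> list[RepeatHit]:
    """Detect library matches in ``query`` on both strands.

    Exact ``seed_k``-mers shared between the query and a consensus (forward or
    reverse-complemented) are clustered by diagonal; each cluster's window,
    padded by ``xdrop`` on both sides, is re-scored by optimal local
    alignment.  Hits below ``min_score`` or shorter than ``min_length`` are
    discarded.  With ``resolve`` (default) overlapping hits are reduced to the
    best-scoring annotation per locus.
    """
    if not library:
        raise ValueError("repeat library is empty")
    query = query.upper()
    if set(query) - set("ACGTN"):
        raise ValueError("query contains characters outside {A,C,G,T,N}")
    matrix = _substitution_matrix(params)
    k = params.seed_k
    query_index = _kmer_positions(query, k)
    band = 2 * params.seed_k
    hits: list[RepeatHit] = []
    for family in sorted(library):
        consensus = library[family].upper()
        for strand, target in (("+", consensus), ("-", revcomp(consensus))):
            diags: list[int] = []
            for tpos in range(len(target) - k + 1):
                kmer = target[tpos : tpos + k]
                for qpos in query_index.get(kmer, ()):
                    diags.append(qpos - tpos)
            if not diags:
                continue
            for cluster in _cluster_diagonals(diags, band):
                w_start = max(0, cluster[0] - params.xdrop)
                w_end = min(len(query), cluster[-1] + len(target) + params.xdrop)
                result = _align_window(
                    query[w_start:w_end], w_start, target, matrix, params
                )
                if result is None:
                    continue
                h_start, h_end, score, div = result
                if score < params.min_score or h_end - h_start < params.min_length:
                    continue
                hits.append(
                    RepeatHit(
                        query_id=query_id,
                        start=h_start,
                        end=h_end,
                        strand=strand,
                        family=family,
                        repeat_class=classify_family(family),
                        score=score,
                        divergence_pct=round(div, 2),
                    )
                )
    # identical loci can be seeded twice (e.g. palindromic consensi); dedupe
    hits = list({(h.start, h.end, h.strand, h.family): h for h in hits}.values())
    if resolve:
        hits = resolve_overlaps(hits)
    return sorted(hits, key=lambda h: (h.start, h.end, h.family))


def resolve_overlaps(
    hits: list[RepeatHit], max_overlap_frac: float = 0.5
) -> list[RepeatHit]:
    """Greedy non-redundant annotation: keep hits by descending score, dropping
    any hit that overlaps an already-kept hit by more than
    ``max_overlap_frac`` of the shorter of the two.  Ties break by earlier
    start, then lexicographic family name."""
    kept: list[RepeatHit] = []
    for hit in sorted(hits, key=lambda h: (-h.score, h.start, h.family)):
        ok = True
        for other in kept:
            if other.query_id != hit.query_id:
                continue
            overlap = min(hit.end, other.end) - max(hit.start, other.start)
            if overlap <= 0:
                continue
            shorter = min(hit.length, other.length)
            if overlap > max_overlap_frac * shorter:
                ok = False
                break
        if ok:
            kept.append(hit)
    return sorted(kept, key=lambda h: (h.query_id, h.start, h.end))


# ---------------------------------------------------------------------------
# RepeatMasker .out interop
# ---------------------------------------------------------------------------

_RM_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def read_repeatmasker_out(path) -> list[RepeatHit]:
    """Parse a RepeatMasker ``.out`` file into RepeatHit records.

    The three header lines are skipped; positions are converted from 1-based
    inclusive to 0-based half-open and strand ``C`` becomes antisense.
    """
    hits: list[RepeatHit] = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines, start=1):
        if lineno <= 3 or not line.strip():
            continue
        fields = line.split()
        if len(fields) < 11:
            raise ValueError(
                f"{path}: line {lineno}: expected >= 11 whitespace-delimited "
                f"columns, found {len(fields)}"
            )
        score, div = int(fields[0]), float(fields[1])
        query_id = fields[4]
        begin, end = int(fields[5]), int(fields[6])
        strand = "-" if fields[8] == "C" else "+"
        family = fields[9]
        repeat_class = classify_family(family, fields[10])
        hits.append(
            RepeatHit(
                query_id=query_id,
                start=begin - 1,
                end=end,
                strand=strand,
                family=family,
                repeat_class=repeat_class,
                score=score,
                divergence_pct=div,
            )
        )
    return hits


_CLASS_FIELD = {
    "SINE/Alu": "SINE/Alu",
    "SINE/other": "SINE/MIR",
    "LINE": "LINE/L1",
    "LTR": "LTR/ERVL",
    "DNA": "DNA/hAT",
    "other": "Unknown",
}


def write_repeatmasker_out(hits: list[RepeatHit], path) -> None:
    """Write hits in the ``.out`` dialect (1-based inclusive, C = antisense)."""
    with open(path, "w") as fh:
        fh.write(_RM_HEADER)
        for i, h in enumerate(sorted(hits, key=lambda h: (h.query_id, h.start)), 1):
            strand = "C" if h.strand == "-" else "+"
            cls = _CLASS_FIELD.get(h.repeat_class, "Unknown")
            fh.write(
                f"{h.score:5d} {h.divergence_pct:5.1f}  0.0  0.0  {h.query_id}  "
                f"{h.start + 1}  {h.end}  (0)  {strand}  {h.family}  {cls}  "
                f"1  {h.length}  (0)  {i}\n"
            )


def write_bed(hits: list[RepeatHit], path) -> None:
    """Write hits as BED6+2 (name=family, score, strand, class, %div)."""
    with open(path, "w") as fh:
        for h in sorted(hits, key=lambda h: (h.query_id, h.start)):
            fh.write(
                f"{h.query_id}\t{h.start}\t{h.end}\t{h.family}\t{h.score}\t"
                f"{h.strand}\t{h.repeat_class}\t{h.divergence_pct}\n"
            )


def read_bed(path) -> list[RepeatHit]:
    """Read hits written by :func:`write_bed`."""
    hits = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            hits.append(
                RepeatHit(
                    query_id=f[0], start=int(f[1]), end=int(f[2]), family=f[3],
                    score=int(f[4]), strand=f[5],
                    repeat_class=f[6] if len(f) > 6 else classify_family(f[3]),
                    divergence_pct=float(f[7]) if len(f) > 7 else 0.0,
                )
            )
    return hits
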