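"""Synthetic sequence bundles with planted repeats and known ground truth.

Everything downstream of this module (the detector, the summary statistics,
the IRAlu classifier, the folding step) is validated against data produced
here: GC-controlled background sequence, a consensus "library" standing in
for a curated repeat-family collection, point-mutated copies planted on
either strand, 3'UTR-like sequences carrying inverted-repeat pairs, and a
gene-to-term annotation table with one planted enriched term.

Copies are substituted into the background (never inserted), so truth
coordinates refer directly to the emitted sequence, and mutation is
substitution-only, so a planted interval's length always equals the
consensus length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqs import DNA, revcomp

__all__ = [
    "SyntheticConfig",
    "PlantedCopy",
    "IRAluTruth",
    "PlacementError",
    "generate_background",
    "generate_consensus_library",
    "generate_related_library",
    "mutate_copy",
    "plant_copies",
    "generate_iralu_utr",
    "generate_annotation_table",
    "write_truth_bed",
]

#: default family spec: one young dimeric-Alu-sized family plus a free monomer
DEFAULT_LIBRARY_SPEC: tuple[tuple[str, int], ...] = (("AluY", 300), ("FLAM", 120))


class PlacementError(RuntimeError):
    """Raised when non-overlapping placement fails after bounded retries."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic host sequence with planted repeat copies.

    ``divergence`` is the per-base substitution probability applied to each
    planted copy; ``strand_prob_sense`` the probability a copy is planted in
    sense (plus-strand) orientation.
    """

    background_length: int = 50_000
    gc_fraction: float = 0.41
    n_copies: int = 20
    divergence: float = 0.05
    strand_prob_sense: float = 0.5
    seed: int = 0
    library_spec: tuple[tuple[str, int], ...] = DEFAULT_LIBRARY_SPEC

    def __post_init__(self) -> None:
        if self.background_length < 0:
            raise ValueError("background_length must be >= 0")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        if not 0.0 <= self.divergence < 1.0:
            raise ValueError("divergence must be in [0, 1)")
        if not 0.0 <= self.strand_prob_sense <= 1.0:
            raise ValueError("strand_prob_sense must be in [0, 1]")


@dataclass(frozen=True)
class PlantedCopy:
    """Ground truth for one planted repeat copy (0-based half-open interval)."""

    family: str
    start: int
    end: int
    strand: str  # "+" sense, "-" antisense
    realized_divergence: float

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass(frozen=True)
class IRAluTruth:
    """Truth record for a synthetic 3'UTR carrying a planted repeat pair."""

    copies: tuple[PlantedCopy, PlantedCopy]
    gap: int
    is_iralu: bool


def generate_background(length: int, gc_fraction: float, seed: int) -> str:
    """I.i.d. background DNA with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if length < 0:
        raise ValueError("length must be >= 0")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    codes = rng.choice(4, size=length, p=[at, gc, gc, at])
    return "".join(DNA[c] for c in codes)


def generate_consensus_library(
    library_spec, seed: int, gc_fraction: float = 0.55
) -> dict[str, str]:
    """Random consensus sequence per family; GC-rich by default, as Alu-family
    consensi are.  Family names must be distinct; lengths must be >= 30."""
    names = [name for name, _ in library_spec]
    if len(set(names)) != len(names):
        raise ValueError("duplicate family name in library spec")
    rng = np.random.default_rng(seed)
    library: dict[str, str] = {}
    for name, length in library_spec:
        if length < 30:
            raise ValueError(f"consensus length for {name!r} must be >= 30")
        at = (1.0 - gc_fraction) / 2.0
        gc = gc_fraction / 2.0
        codes = rng.choice(4, size=length, p=[at, gc, gc, at])
        library[name] = "".join(DNA[c] for c in codes)
    return library


def generate_related_library(
    library_spec, seed: int, family_divergence: float = 0.12, gc_fraction: float = 0.55
) -> dict[str, str]:
    """Consensus library whose families descend from one common ancestor.

    The first family is random; each further family is a point-mutated copy
    of it, truncated or extended to its specified length.  This mirrors how
    real Alu subfamilies relate (high mutual identity), so opposite-strand
    copies of *different* families can still base-pair into duplexes.
    """
    names = [name for name, _ in library_spec]
    if len(set(names)) != len(names):
        raise ValueError("duplicate family name in library spec")
    rng = np.random.default_rng(seed)
    base_name, base_len = library_spec[0]
    if base_len < 30:
        raise ValueError("consensus lengths must be >= 30")
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    codes = rng.choice(4, size=base_len, p=[at, gc, gc, at])
    ancestor = "".join(DNA[c] for c in codes)
    library = {base_name: ancestor}
    for name, length in library_spec[1:]:
        if length < 30:
            raise ValueError(f"consensus length for {name!r} must be >= 30")
        mutated, _ = mutate_copy(ancestor, family_divergence, rng)
        if length <= len(mutated):
            library[name] = mutated[:length]
        else:
            extra = rng.choice(4, size=length - len(mutated), p=[at, gc, gc, at])
            library[name] = mutated + "".join(DNA[c] for c in extra)
    return library


def mutate_copy(
    consensus: str, divergence: float, seed: int | np.random.Generator
) -> tuple[str, float]:
    """Apply independent point substitutions at rate ``divergence``.

    Length is preserved; each mutated position receives a base different from
    the original.  Returns the mutated sequence and the realized divergence
    (Hamming distance over length).
    """
    if not 0.0 <= divergence < 1.0:
        raise ValueError("divergence must be in [0, 1)")
    if not consensus:
        return "", 0.0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hit = rng.random(len(consensus)) < divergence
    out = list(consensus)
    n_mut = 0
    for i in np.flatnonzero(hit):
        alternatives = [b for b in DNA if b != consensus[i]]
        out[i] = alternatives[rng.integers(3)]
        n_mut += 1
    return "".join(out), n_mut / len(consensus)


def _place_intervals(
    rng: np.random.Generator, host_length: int, lengths: list[int], max_retries: int = 1000
) -> list[int]:
    """Random non-overlapping start positions by rejection sampling."""
    taken: list[tuple[int, int]] = []
    starts: list[int] = []
    for length in lengths:
        if length > host_length:
            raise PlacementError("copy longer than host sequence")
        for _ in range(max_retries):
            s = int(rng.integers(0, host_length - length + 1))
            if all(s >= e or s + length <= b for b, e in taken):
                taken.append((s, s + length))
                starts.append(s)
                break
        else:
            raise PlacementError(
                f"could not place {len(lengths)} copies without overlap "
                f"in {host_length} nt after {max_retries} retries"
            )
    return starts


def plant_copies(
    background: str, library: dict[str, str], config: SyntheticConfig
) -> tuple[str, list[PlantedCopy]]:
    """Substitute mutated, strand-randomized library copies into ``background``.

    Each copy is drawn uniformly from the library families, point-mutated at
    the configured divergence, reverse-complemented when antisense, and
    written over a random non-overlapping interval.  The host length never
    changes.  Truth is returned sorted by interval start.
    """
    rng = np.random.default_rng(config.seed)
    families = sorted(library)
    if config.n_copies == 0:
        return background, []
    chosen = [families[int(rng.integers(len(families)))] for _ in range(config.n_copies)]
    lengths = [len(library[f]) for f in chosen]
    if sum(lengths) > len(background):
        raise PlacementError("total planted length exceeds background length")
    starts = _place_intervals(rng, len(background), lengths)
    host = list(background)
    truth: list[PlantedCopy] = []
    for family, start in zip(chosen, starts):
        mutated, realized = mutate_copy(library[family], config.divergence, rng)
        sense = rng.random() < config.strand_prob_sense
        placed = mutated if sense else revcomp(mutated)
        host[start : start + len(placed)] = placed
        truth.append(
            PlantedCopy(
                family=family,
                start=start,
                end=start + len(placed),
                strand="+" if sense else "-",
                realized_divergence=realized,
            )
        )
    truth.sort(key=lambda c: c.start)
    return "".join(host), truth


def generate_iralu_utr(
    library: dict[str, str],
    gap: int,
    divergence: float,
    seed: int,
    families: tuple[str, str] | None = None,
    orientations: tuple[str, str] = ("+", "-"),
    flank: int = 100,
    gc_fraction: float = 0.45,
) -> tuple[str, IRAluTruth]:
    """Build a 3'UTR-like sequence with two planted repeat copies.

    Layout: ``flank | copy1 | gap | copy2 | flank``.  With the default
    orientations the two copies are inverted relative to each other and the
    truth record is flagged as an IRAlu; passing two identical orientations
    produces the negative control.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    rng = np.random.default_rng(seed)
    names = sorted(library)
    if families is None:
        families = (names[0], names[-1] if len(names) > 1 else names[0])
    pieces: list[str] = []
    copies: list[PlantedCopy] = []
    pieces.append(generate_background(flank, gc_fraction, int(rng.integers(2**31))))
    pos = flank
    for k, (family, strand) in enumerate(zip(families, orientations)):
        mutated, realized = mutate_copy(library[family], divergence, rng)
        placed = mutated if strand == "+" else revcomp(mutated)
        pieces.append(placed)
        copies.append(
            PlantedCopy(family, pos, pos + len(placed), strand, realized)
        )
        pos += len(placed)
        if k == 0:
            pieces.append(generate_background(gap, gc_fraction, int(rng.integers(2**31))))
            pos += gap
    pieces.append(generate_background(flank, gc_fraction, int(rng.integers(2**31))))
    truth = IRAluTruth(
        copies=(copies[0], copies[1]),
        gap=gap,
        is_iralu=orientations[0] != orientations[1],
    )
    return "".join(pieces), truth


def generate_annotation_table(
    n_genes: int,
    n_terms: int,
    enriched_term: str = "term_0",
    fold_effect: float = 10.0,
    seed: int = 0,
    subset_size: int | None = None,
    base_prob: float = 0.05,
    gene_ids: list[str] | None = None,
    subset: list[str] | None = None,
) -> tuple[list[tuple[str, str]], dict]:
    """Gene-to-term memberships with one term enriched in a designated subset.

    Background membership of every term is Bernoulli(``base_prob``); for the
    genes of the designated subset the membership probability of
    ``enriched_term`` is multiplied by ``fold_effect``.  Returns the TSV rows
    (gene_id, term_id) and a truth dict with the subset gene ids and the
    planted term.
    """
    if n_genes < 1 or n_terms < 1:
        raise ValueError("n_genes and n_terms must be >= 1")
    if fold_effect < 1.0:
        raise ValueError("fold_effect must be >= 1")
    rng = np.random.default_rng(seed)
    genes = gene_ids if gene_ids is not None else [f"gene_{i}" for i in range(n_genes)]
    if len(genes) != n_genes:
        raise ValueError("gene_ids length must equal n_genes")
    terms = [f"term_{j}" for j in range(n_terms)]
    if enriched_term not in terms:
        raise ValueError(f"enriched_term {enriched_term!r} not among generated terms")
    if subset is None:
        if subset_size is None:
            subset_size = max(1, n_genes // 10)
        subset = rng.choice(genes, size=subset_size, replace=False).tolist()
    subset = set(subset)
    enriched_p = min(1.0, base_prob * fold_effect)
    rows: list[tuple[str, str]] = []
    for gene in genes:
        for term in terms:
            p = enriched_p if (term == enriched_term and gene in subset) else base_prob
            if rng.random() < p:
                rows.append((gene, term))
    truth = {"subset": sorted(subset), "enriched_term": enriched_term}
    return rows, truth


def write_truth_bed(path, truth: list[PlantedCopy], query_id: str) -> None:
    """Write planted-copy truth as BED6 (0-based half-open, strand column 6)."""
    with open(path, "w") as fh:
        for copy in truth:
            fh.write(
                f"{query_id}\t{copy.start}\t{copy.end}\t{copy.family}\t"
                f"{copy.realized_divergence:.4f}\t{copy.strand}\n"
            )
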