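# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `alulandscape`, in the order the pipeline runs them.

## Synthetic data model

The generator produces the study conditions every downstream stage is
validated against.

* **Background** — i.i.d. nucleotides with P(G)=P(C)=gc/2,
  P(A)=P(T)=(1−gc)/2. Defaults: 41% GC for genome-like background (the
  human average), 45% for gene-like contigs (candidate genes in this
  setting are GC-rich), 55% for consensus sequences (Alu consensi are
  GC-rich).
* **Consensus libraries** — random sequences per family, fixed by seed.
  Two generators exist: independent families
  (`generate_consensus_library`) for detection tests, and ancestor-derived
  families (`generate_related_library`, 12% divergence from a common
  ancestor, truncated/extended to each family's length) for folding tests.
  The second mirrors the real situation — Alu subfamilies share 70–99.7%
  identity — and is required for cross-subfamily inverted pairs to be
  complementary enough to duplex, e.g. the sense-AluSz-like (311 nt) /
  antisense-AluSg-like (307 nt) layout used throughout the examples.
* **Copies** — substitution-only point mutation (each position
  independently mutated with probability = divergence to a different
  base), reverse complementation for antisense placements, and
  *substitution into* the background at non-overlapping random intervals.
  No indels and no insertion: planted truth coordinates are exact in the
  emitted FASTA, lengths equal consensus lengths, and the host length
  never changes. Divergence of real Alu copies is substitution-dominated,
  so this loses little realism while keeping truth exact.
* **Gene bundles** — one plus-strand contig per gene with a fixed layout
  (200 nt 5'UTR, 300+300 nt split CDS, 3 kb intron, 1.5 kb 3'UTR), planted
  intronic copies, and inverted pairs in designated 3'UTRs. Default
  per-copy divergence 5% (a typical AluS-age divergence), gap 150 nt
  between pair members.
* **Annotation tables** — Bernoulli term membership (base probability
  0.05–0.1), with one term's probability multiplied by `fold_effect`
  (default 10) inside a designated gene subset.

What the generator does **not** emulate: the dimeric Alu structure (left/
right arm, A-rich linker), indel evolution, nested or fragmented
insertions, CpG hypermutation, isoform complexity (one transcript per
gene in bundles), and realistic term-size distributions. Passing tests
therefore demonstrate algorithmic correctness under clean conditions, not
performance on real RepeatMasker-grade genomic sequence.

## Repeat detector

Seed-and-extend: exact `seed_k`-mers (default 12) shared between query and
consensus (forward and reverse complement) are collected as diagonals
(query position − consensus position); diagonals closer than `2·seed_k`
are clustered; each cluster defines a window (cluster diagonal span plus
the consensus length, padded by `xdrop`=30 nt on both sides) that is
scored by *optimal local alignment* against the consensus (match +2,
mismatch −3, gap open −5, gap extend −2 — the BLASTN-style
parameterization). Hits below `min_score`=200 or shorter than
`min_length`=50 are dropped. Because each window is scored by a full
local-alignment DP rather than a greedy extension, every reported score is
a true Smith–Waterman score for its interval (an invariant the test suite
checks against an independent naive DP).

Divergence is mismatches / aligned columns × 100, gaps excluded — close
enough to RepeatMasker's %div for ranking purposes. Overlap resolution is
greedy by descending score (ties: earlier start, then lexicographic family
name); a hit overlapping a kept hit by more than half the shorter hit's
length is dropped. With min_score 200, monomer-length copies (FLAM/FRAM,
~120 nt) sit near the detection threshold above ~5% divergence; full-length
(≥200 nt) copies are detected essentially always up to 10% divergence.
These defaults are this package's choice — repeat-masking tools expose
sensitivity modes this desk-scale detector does not reproduce.

Coordinates are 0-based half-open everywhere in memory; the RepeatMasker
`.out` reader/writer converts to and from that format's 1-based inclusive
convention (strand `C` ⇔ antisense) at the file boundary only.

## Region handling and orientation semantics

GFF3 gene models (1-based inclusive) are converted on read; introns are
the gaps between consecutive exons. Region sequences are spliced in
transcript order and reverse-complemented for minus-strand transcripts, so
a "+" hit on an extracted sequence always means *sense relative to the
transcript* — the convention behind all orientation tallies and the s/a
columns of IRAlu reports. All isoforms are counted independently (no
per-gene deduplication of shared UTRs), matching how published per-category
sequence counts are built. GC content is (G+C)/(A+C+G+T) with N excluded
from both numerator and denominator.

## Display conventions

Two printing conventions are implemented exactly because published tables
use both: ratio cells ("one Alu per N nt", average lengths) are
**truncated** to integers (verified against five density cells and the
recomputable average-length cells), and percentages default to truncation
at the printed precision (51.612…% → 51.6) with an explicit half-up
rounding mode for integer prose figures (58.87% → 59). `percent` computes
in exact rational arithmetic before truncating so float representation
cannot flip a displayed digit.

## Enrichment statistics

* 2×2 chi-square: Pearson statistic with Yates continuity correction on by
  default (the R default for 2×2 tables, and immaterial at the base-count
  sample sizes involved); the coverage contingency is built from covered
  vs non-covered *bases*, target region vs genome background. The genome
  background is evaluated across 2.8–3.2 Gb because the survey's exact
  denominator is not recoverable; the significance bound holds across the
  whole range.
* Welch's t: statistic and Welch–Satterthwaite df computed from the
  formulas, two-sided p from the t distribution.
* Fisher right tail P(X ≥ k): hypergeometric log-pmf summed with
  `logsumexp`, so values far below 1e-300 remain meaningful; the
  "< 2.2e−16" floor is applied only when *formatting*, never to stored
  values.
* EASE score: the tail at k−1 — the jackknifed, conservative variant that
  penalizes categories supported by few genes; undefined at k=0.
* Term enrichment: universe = genes present in the annotation table
  (query genes without annotations are dropped), one EASE p per term with
  ≥ `min_count` overlaps, Bonferroni over the number of *tested* terms.
* Group enrichment score: −mean(log₁₀ EASE); 1.3 corresponds to 0.05.

## IRAlu definition

A transcript's 3'UTR is IRAlu-positive iff at least one sense and one
antisense Alu-class hit co-occur there, *regardless of length* — Alu-clade
monomer fragments count. This reading is forced by the published
transcript inventory, which includes a row whose only antisense element is
a 75 nt fragment. Separately, explicit sense/antisense pairs are
enumerated only between elements ≥ `min_alu_length` (default 100 nt,
separating the fragment inventory from pairs worth folding) and ranked by
combined alignment score, then smaller gap, then leftmost position; the
top pair is the one handed to the folding stage. No maximum gap is imposed
by default. The gene-level tabulation counts distinct genes with any
positive transcript, and separately those with a positive *protein-coding*
transcript (nonsense-mediated-decay isoforms excluded by the filter).

## Folding

Weighted base-pair maximization (Nussinov recurrence) with GC=3, AU=2,
GU=1 and a minimum hairpin loop of 3 nt; the O(n³) fill runs as a numba
kernel, the traceback deterministically pairs each position with its
smallest optimal partner. Cofolding concatenates the two strands across a
10 nt non-pairing sentinel linker (≥ the hairpin minimum, so
cross-linker pairs are never loop-constrained) and reports the fraction of
pairs spanning the cut. The duplex verdict requires intermolecular
fraction ≥ 0.5 *and* pair count ≥ 0.3 × the shorter element's length.
IRAlu elements are folded exactly as they occur in the transcript (no
reverse complementation — the antisense element already carries the
complementary sequence).

This objective is deliberately not a thermodynamic model: no stacking
energies, dangles or partition function, hence no kcal/mol values and no
base-pair probabilities. It reproduces the *qualitative* dichotomy that
matters here — inverted pairs form long intermolecular duplexes
(intermolecular fraction ≳ 0.8 at 10% divergence), same-orientation
controls do not — which is the inference the duplex verdict encodes.
One caveat: the score is not invariant under A↔U/G↔C relabeling when GU
wobble pairs are enabled, since the relabeling maps GU onto the
non-pairing CA.

## Pipeline

Stages communicate via files (FASTA/GFF3/BED/TSV/JSON) so each is
independently runnable; a manifest records tool version, config, input
SHA-256 checksums, per-stage row counts and timestamps. Analytic outputs
are byte-identical across re-runs with the same config and inputs; any
stage failure aborts with the stage name. The CLI is a thin click layer
over these library functions.

## Problem sizes

Tests and the acceptance script use deliberately small instances chosen to
exercise every code path with comfortable statistical margins: 40–60 kb
hosts with 10–20 planted copies per trial (≥40 full-length copies for the
recall estimate), 200 random sequences ≤14 nt for the folding-DP
enumeration check, 300 nt elements for cofolding, 200 null terms over a
400-gene universe for the EASE calibration, and 100 replicates for the
planted-enrichment ranking check.

## Known limitations

No indel handling in the synthetic truth (real copies have deletions);
detector sensitivity modes, CpG-adjusted matrices and satellite masking
are out of scope; kappa-based annotation-term clustering is not
implemented (only the group score over a given cluster); the folding stage
ranks and verifies duplexes but does not predict editing sites or decay
outcomes; raw genome-scale counts of the published survey depend on
database versions and are treated as inputs, not recomputed.
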