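"""Recompute the headline statistics of the T1D candidate-gene Alu survey.

Uses the published per-category totals shipped with the package as inputs
and re-derives the printed density cells ("one Alu per N nt"), average
lengths, orientation percentages, and the Alu-enrichment chi-square bound.
"""

from alulandscape import (
    ContingencyTable2x2,
    average_length,
    chi_square_2x2,
    density,
    percent,
)
from alulandscape.enrichment import format_p
from alulandscape.reference import (
    ALU_COVERAGE_GENOME_PCT,
    ALU_COVERAGE_T1D_PCT,
    N_GENES,
    N_GENES_WITH_ALUS,
    orientation_counts,
    region_summary,
)

summary = region_summary()
print("one Alu element occurrence per (nt):")
for category in summary.index:
    row = summary.loc[category]
    print(f"  {category:8s} {density(int(row.total_length_nt), int(row.n_alus)):>7,d}")

utr3 = summary.loc["utr3"]
print(
    f"\naverage 3'UTR length: "
    f"{average_length(int(utr3.total_length_nt), int(utr3.n_sequences))} nt"
)

orient = orientation_counts()
u3 = orient.loc["t1d_utr3"]
total = int(u3.n_sense + u3.n_antisense)
print(
    f"T1D 3'UTR orientation: {percent(int(u3.n_sense), total, 1)}% sense, "
    f"{percent(int(u3.n_antisense), total, 1)}% antisense"
)
print(
    f"genes harboring Alus: {percent(N_GENES_WITH_ALUS, N_GENES, 0, mode='round'):.0f}%"
    f" ({N_GENES_WITH_ALUS}/{N_GENES})"
)

# Alu base coverage vs the genome background, as a 2x2 chi-square
t1d_len = int(summary.loc["genes"].total_length_nt)
covered = round(t1d_len * ALU_COVERAGE_T1D_PCT / 100)
genome_len = 3_100_000_000
bg_covered = round(genome_len * ALU_COVERAGE_GENOME_PCT / 100)
res = chi_square_2x2(
    ContingencyTable2x2(covered, t1d_len - covered, bg_covered, genome_len - bg_covered)
)
print(
    f"\nAlu enrichment vs genome ({ALU_COVERAGE_T1D_PCT}% vs "
    f"{ALU_COVERAGE_GENOME_PCT}% coverage): chi2={res.statistic:.3g}, "
    f"p {format_p(res.p_value)}"
)
print(
    "\nThe densities show Alu accumulation in introns and 3'UTRs; the "
    "chi-square confirms coverage far above the genomic background."
)
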