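"""Detect an inverted-Alu pair in a 3'UTR and verify duplex formation.

Builds a synthetic 3'UTR carrying a sense 311 nt element and an antisense
307 nt element of two related subfamilies (the classic two-subfamily
inverted pair), detects both, enumerates the sense/antisense pair, and
cofolds it.  A same-orientation control UTR is analyzed alongside.
"""

from alulandscape import (
    find_iralus,
    generate_iralu_utr,
    generate_related_library,
    scan,
    tabulate_iralu_genes,
)
from alulandscape.fold import duplex_report
from alulandscape.reference import iralu_table

library = generate_related_library([("AluSz", 311), ("AluSg", 307)], seed=31)

for label, orientations in (("inverted pair", ("+", "-")), ("same orientation", ("+", "+"))):
    utr, truth = generate_iralu_utr(
        library, gap=80, divergence=0.05, seed=32,
        families=("AluSz", "AluSg"), orientations=orientations,
    )
    hits = scan(utr, library, query_id="utr")
    pairs, is_iralu = find_iralus(hits, min_alu_length=100)
    line = f"{label:17s} IRAlu={is_iralu!s:5s} pairs={len(pairs)}"
    if pairs:
        result, verdict = duplex_report(pairs[0], utr)
        line += (
            f"  cofold: {result.n_pairs} pairs, "
            f"{result.intermolecular_fraction:.0%} intermolecular, "
            f"duplex={verdict}"
        )
    print(line)

n_all, n_coding = tabulate_iralu_genes(iralu_table())
print(
    f"\npublished 3'UTR survey: {n_all} genes with IRAlus, "
    f"{n_coding} with protein-coding transcripts"
)
print(
    "Only the opposite-orientation pair base-pairs across strands; the "
    "duplex verdict mirrors the dsRNA structures formed in vivo."
)
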