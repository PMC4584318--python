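"""Generator correctness: composition, determinism, planted ground truth."""

import numpy as np
import pytest

from alulandscape import (
    SyntheticConfig,
    generate_annotation_table,
    generate_background,
    generate_consensus_library,
    generate_iralu_utr,
    generate_related_library,
    mutate_copy,
    plant_copies,
)
from alulandscape.enrichment import fisher_right_tail
from alulandscape.seqs import revcomp
from alulandscape.synthetic import PlacementError


class TestBackground:
    def test_zero_length_is_empty(self):
        assert generate_background(0, 0.5, 1) == ""

    def test_degenerate_gc_only(self):
        assert set(generate_background(1000, 1.0, 7)) <= {"G", "C"}

    def test_gc_fraction_matches_binomial_sampling(self):
        # at n=100000 the observed GC fraction sits within 3 binomial s.e.
        seq = generate_background(100_000, 0.5, 42)
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.5) < 3 * np.sqrt(0.25 / 100_000)

    def test_negative_length_rejected(self):
        with pytest.raises(ValueError):
            generate_background(-1, 0.5, 1)

    def test_seed_reproducibility(self):
        assert generate_background(5000, 0.41, 9) == generate_background(5000, 0.41, 9)


class TestConsensusLibrary:
    def test_lengths_and_names(self):
        lib = generate_consensus_library([("FLAM", 120), ("AluY", 300)], seed=1)
        assert set(lib) == {"FLAM", "AluY"}
        assert len(lib["FLAM"]) == 120 and len(lib["AluY"]) == 300

    def test_same_seed_identical(self):
        spec = [("AluY", 300)]
        assert generate_consensus_library(spec, 1) == generate_consensus_library(spec, 1)

    def test_duplicate_family_rejected(self):
        with pytest.raises(ValueError):
            generate_consensus_library([("AluY", 300), ("AluY", 280)], seed=1)

    def test_related_library_families_are_homologous(self):
        lib = generate_related_library([("AluSz", 311), ("AluSg", 307)], seed=5)
        a, b = lib["AluSz"], lib["AluSg"]
        n = min(len(a), len(b))
        identity = sum(x == y for x, y in zip(a[:n], b[:n])) / n
        assert identity > 0.8
        assert len(a) == 311 and len(b) == 307


class TestMutateCopy:
    def test_zero_divergence_identity(self, library):
        out, realized = mutate_copy(library["AluY"], 0.0, 1)
        assert out == library["AluY"] and realized == 0.0

    def test_empty_consensus(self):
        assert mutate_copy("", 0.5, 1) == ("", 0.0)

    def test_length_preserved_and_substitution_only(self, library):
        out, realized = mutate_copy(library["AluY"], 0.2, 3)
        assert len(out) == len(library["AluY"])
        hamming = sum(a != b for a, b in zip(out, library["AluY"]))
        assert realized == hamming / len(out)

    def test_mean_realized_divergence_binomial(self, library):
        # 500 independent mutated copies: mean realized rate within 3 s.e. of 0.10
        rates = [mutate_copy(library["AluY"], 0.10, s)[1] for s in range(500)]
        se = np.sqrt(0.10 * 0.90 / (300 * 500))
        assert abs(np.mean(rates) - 0.10) < 3 * se


class TestPlantCopies:
    def test_no_copies_is_identity(self, library):
        bg = generate_background(2000, 0.5, 4)
        host, truth = plant_copies(bg, library, SyntheticConfig(n_copies=0, seed=1))
        assert host == bg and truth == []

    def test_planted_substring_matches_truth(self, library):
        bg = generate_background(3000, 0.5, 4)
        config = SyntheticConfig(n_copies=1, divergence=0.0, strand_prob_sense=1.0, seed=8)
        host, truth = plant_copies(bg, library, config)
        (copy,) = truth
        assert host[copy.start : copy.end] == library[copy.family]

    def test_antisense_copy_is_reverse_complement(self, library):
        bg = generate_background(3000, 0.5, 4)
        config = SyntheticConfig(n_copies=1, divergence=0.0, strand_prob_sense=0.0, seed=8)
        host, truth = plant_copies(bg, library, config)
        (copy,) = truth
        assert revcomp(host[copy.start : copy.end]) == library[copy.family]

    def test_intervals_pairwise_disjoint_and_sorted(self, library):
        bg = generate_background(30_000, 0.5, 4)
        host, truth = plant_copies(bg, library, SyntheticConfig(n_copies=20, seed=5))
        assert len(host) == len(bg)  # substitution, not insertion
        starts = [c.start for c in truth]
        assert starts == sorted(starts)
        for a in truth:
            for b in truth:
                if a is not b:
                    assert a.end <= b.start or b.end <= a.start

    def test_impossible_placement_raises(self, library):
        bg = generate_background(500, 0.5, 4)
        with pytest.raises(PlacementError):
            plant_copies(bg, library, SyntheticConfig(n_copies=10, seed=5))


class TestIRAluUTR:
    def test_inverted_layout_and_gap(self, library):
        utr, truth = generate_iralu_utr(library, gap=0, divergence=0.0, seed=1)
        assert truth.is_iralu
        first, second = truth.copies
        assert second.start - first.end == 0
        assert first.strand != second.strand

    def test_fut2_like_layout_lengths(self):
        # sense 311 nt + antisense 307 nt, the classic two-subfamily pair
        lib = generate_related_library([("AluSz", 311), ("AluSg", 307)], seed=2)
        utr, truth = generate_iralu_utr(
            lib, gap=50, divergence=0.0, seed=3, families=("AluSz", "AluSg")
        )
        lengths = [c.end - c.start for c in truth.copies]
        assert lengths == [311, 307]
        assert [c.strand for c in truth.copies] == ["+", "-"]

    def test_same_orientation_is_negative_control(self, library):
        _, truth = generate_iralu_utr(
            library, gap=10, divergence=0.0, seed=1, orientations=("+", "+")
        )
        assert not truth.is_iralu

    def test_truth_substrings_match_orientation(self, library):
        utr, truth = generate_iralu_utr(library, gap=25, divergence=0.0, seed=9)
        sense, antisense = truth.copies
        assert utr[sense.start : sense.end] == library[sense.family]
        assert revcomp(utr[antisense.start : antisense.end]) == library[antisense.family]


class TestAnnotationTable:
    def test_single_term_table(self):
        rows, _ = generate_annotation_table(20, 1, enriched_term="term_0", seed=1)
        assert {t for _, t in rows} <= {"term_0"}

    def test_fold_effect_below_one_rejected(self):
        with pytest.raises(ValueError):
            generate_annotation_table(10, 2, fold_effect=0.5, seed=1)

    def test_planted_term_has_smallest_median_fisher_p(self):
        # across replicates the planted term's Fisher p is the smallest median
        n_genes, n_terms = 200, 6
        p_by_term = {f"term_{j}": [] for j in range(n_terms)}
        for rep in range(40):
            rows, truth = generate_annotation_table(
                n_genes, n_terms, enriched_term="term_0", fold_effect=10.0,
                seed=rep, subset_size=30, base_prob=0.05,
            )
            subset = set(truth["subset"])
            genes = {g for g, _ in rows} | subset
            term_members = {t: set() for t in p_by_term}
            for g, t in rows:
                term_members[t].add(g)
            for term, members in term_members.items():
                k = len(members & subset)
                p_by_term[term].append(
                    fisher_right_tail(k, len(members), len(subset), n_genes)
                    if members else 1.0
                )
        medians = {t: np.median(ps) for t, ps in p_by_term.items()}
        assert min(medians, key=medians.get) == "term_0"

    def test_null_table_has_no_small_fisher_p_bias(self):
        rows, truth = generate_annotation_table(
            300, 5, enriched_term="term_0", fold_effect=1.0, seed=7,
            subset_size=40, base_prob=0.1,
        )
        subset = set(truth["subset"])
        term_members = {}
        for g, t in rows:
            term_members.setdefault(t, set()).add(g)
        ps = [
            fisher_right_tail(len(m & subset), len(m), len(subset), 300)
            for m in term_members.values()
        ]
        assert min(ps) > 1e-4  # no term systematically enriched under the null
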