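"""Folding engine: DP optimality, structure validity, duplex verdicts."""

import numpy as np
import pytest

from alulandscape import (
    FoldParams,
    IRAluPair,
    RepeatHit,
    cofold,
    generate_related_library,
    mutate_copy,
    nussinov_fold,
)
from alulandscape.fold import duplex_report
from alulandscape.seqs import revcomp
from oracles import enumerate_best_structure

UNIT = FoldParams(pair_scores={"GC": 1, "AU": 1, "GU": 1})


def _random_rna(rng, n):
    return "".join("ACGU"[i] for i in rng.integers(0, 4, n))


def _check_structure(result, min_hairpin):
    """Structural validity: balanced brackets, canonical pairs, loop length."""
    stack = []
    for idx, ch in enumerate(result.structure):
        if ch == "(":
            stack.append(idx)
        elif ch == ")":
            i = stack.pop()
            assert (i, idx) in result.pairs
    assert not stack
    canonical = {"AU", "UA", "GC", "CG", "GU", "UG"}
    for i, j in result.pairs:
        assert result.sequence[i] + result.sequence[j] in canonical
        if result.cut_point is None or not (i < result.cut_point <= j):
            assert j - i - 1 >= min_hairpin


class TestNussinov:
    def test_unpairable_sequence(self):
        r = nussinov_fold("AAAAAA")
        assert r.structure == "......" and r.n_pairs == 0

    def test_simple_hairpin_with_unit_scores(self):
        r = nussinov_fold("GGGAAAACCC", UNIT)
        assert r.structure == "(((....)))"
        assert r.n_pairs == 3 and r.score == 3

    def test_too_short_to_pair(self):
        for seq in ("GC", "GAC", "GAAC"):
            assert nussinov_fold(seq).n_pairs == 0

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError):
            nussinov_fold("ACGX")

    def test_dp_matches_exhaustive_enumeration(self):
        # random short sequences: DP optimum equals brute-force maximum
        rng = np.random.default_rng(1234)
        for _ in range(60):
            seq = _random_rna(rng, int(rng.integers(5, 15)))
            result = nussinov_fold(seq)
            assert result.score == enumerate_best_structure(seq)
            assert sum(p for p in [result.score]) >= 0
            _check_structure(result, 3)

    def test_traceback_score_consistent_with_pairs(self):
        rng = np.random.default_rng(5)
        weights = {"GC": 3, "AU": 2, "GU": 1}
        for _ in range(20):
            seq = _random_rna(rng, 40)
            r = nussinov_fold(seq)
            total = 0
            for i, j in r.pairs:
                key = "".join(sorted((r.sequence[i], r.sequence[j])))
                total += {"CG": 3, "AU": 2, "GU": 1}[key]
            assert total == r.score

    def test_score_invariant_under_complement_relabeling(self):
        # A<->U, G<->C relabeling maps AU/GC pairs onto each other; the GU
        # wobble maps to the non-pairing CA, so it is disabled here
        params = FoldParams(pair_scores={"GC": 3, "AU": 2})
        rng = np.random.default_rng(9)
        swap = str.maketrans("AUGC", "UACG")
        for _ in range(10):
            seq = _random_rna(rng, 30)
            assert (
                nussinov_fold(seq, params).score
                == nussinov_fold(seq.translate(swap), params).score
            )

    def test_complementary_context_never_decreases_score(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            core = _random_rna(rng, 20)
            extended = "GGGGG" + core + "CCCCC"
            assert nussinov_fold(extended).score >= nussinov_fold(core).score


class TestCofold:
    def test_full_complementarity(self):
        rng = np.random.default_rng(21)
        seq_a = _random_rna(rng, 50)
        seq_b = revcomp(seq_a.replace("U", "T")).replace("T", "U")
        r = cofold(seq_a, seq_b)
        assert r.n_pairs >= 45
        assert r.intermolecular_fraction >= 0.9
        _check_structure(r, 3)

    def test_polya_strands_cannot_pair(self):
        r = cofold("A" * 30, "A" * 30)
        assert r.n_pairs == 0 and r.intermolecular_fraction == 0.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            cofold("", "ACGU")

    def test_cut_point_separates_strands(self):
        r = cofold("GGGG", "CCCC", FoldParams(min_hairpin=3))
        assert r.cut_point == 4
        assert all(i < 4 <= j for i, j in r.pairs)
        assert r.intermolecular_fraction == 1.0

    def test_diverged_inverted_copy_forms_duplex(self):
        # sense consensus vs antisense 10%-mutated copy: strong duplex signal
        lib = generate_related_library([("AluY", 300)], seed=31)
        sense = lib["AluY"]
        mutated, _ = mutate_copy(lib["AluY"], 0.10, 32)
        antisense = revcomp(mutated)
        r = cofold(sense, antisense)
        assert r.intermolecular_fraction >= 0.7


class TestDuplexReport:
    def _pair_on(self, utr, a_iv, b_iv):
        sense = RepeatHit(
            query_id="utr", start=a_iv[0], end=a_iv[1], strand="+", family="AluSz",
            repeat_class="SINE/Alu", score=500, divergence_pct=0.0,
        )
        anti = RepeatHit(
            query_id="utr", start=b_iv[0], end=b_iv[1], strand="-", family="AluSg",
            repeat_class="SINE/Alu", score=500, divergence_pct=0.0,
        )
        return IRAluPair(
            transcript_id="utr", sense_hit=sense, antisense_hit=anti,
            gap=b_iv[0] - a_iv[1], combined_score=1000,
        )

    def _synthetic_utr(self, seed=41, divergence=0.0):
        from alulandscape import generate_iralu_utr

        lib = generate_related_library([("AluSz", 311), ("AluSg", 307)], seed=seed)
        utr, truth = generate_iralu_utr(
            lib, gap=80, divergence=divergence, seed=seed, families=("AluSz", "AluSg")
        )
        a, b = truth.copies
        return utr, (a.start, a.end), (b.start, b.end)

    def test_inverted_pair_verdict_duplex(self):
        utr, a_iv, b_iv = self._synthetic_utr()
        result, verdict = duplex_report(self._pair_on(utr, a_iv, b_iv), utr)
        assert verdict
        assert result.intermolecular_fraction >= 0.5

    def test_same_orientation_fails_verdict(self):
        # force two same-orientation copies through the API: no complementarity
        lib = generate_related_library([("AluSz", 311), ("AluSg", 307)], seed=43)
        from alulandscape import generate_iralu_utr

        utr, truth = generate_iralu_utr(
            lib, gap=80, divergence=0.0, seed=43,
            families=("AluSz", "AluSg"), orientations=("+", "+"),
        )
        a, b = truth.copies
        _, verdict = duplex_report(
            self._pair_on(utr, (a.start, a.end), (b.start, b.end)), utr
        )
        assert not verdict

    def test_threshold_above_one_never_duplex(self):
        utr, a_iv, b_iv = self._synthetic_utr()
        _, verdict = duplex_report(
            self._pair_on(utr, a_iv, b_iv), utr, intermolecular_threshold=1.01
        )
        assert not verdict

    def test_out_of_bounds_pair_rejected(self):
        utr, a_iv, b_iv = self._synthetic_utr()
        with pytest.raises(ValueError):
            duplex_report(self._pair_on(utr, a_iv, (len(utr) - 10, len(utr) + 50)), utr)
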