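"""Statistical tests against hand formulas and combinatorial enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from alulandscape import (
    ContingencyTable2x2,
    bonferroni,
    chi_square_2x2,
    ease_score,
    enrich_terms,
    fisher_right_tail,
    generate_annotation_table,
    group_enrichment_score,
    welch_t_test,
)
from alulandscape.enrichment import format_p
from oracles import hypergeom_right_tail


class TestChiSquare:
    def test_homogeneous_table_is_null(self):
        res = chi_square_2x2(ContingencyTable2x2(50, 50, 50, 50), yates=False)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_matches_direct_formula_without_correction(self):
        a, b, c, d = 10, 90, 20, 80
        res = chi_square_2x2(ContingencyTable2x2(a, b, c, d), yates=False)
        n = a + b + c + d
        by_hand = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.statistic == pytest.approx(by_hand)
        assert res.df == 1

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.tuples(*[st.integers(1, 500)] * 4))
    def test_formula_identity_property(self, counts):
        a, b, c, d = counts
        res = chi_square_2x2(ContingencyTable2x2(a, b, c, d), yates=False)
        n = a + b + c + d
        by_hand = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
        assert res.statistic == pytest.approx(by_hand, rel=1e-9)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2(ContingencyTable2x2(0, 0, 10, 10))


class TestWelch:
    def test_identical_groups(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_hand_formula_and_scipy_agreement(self):
        xs, ys = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        res = welch_t_test(xs, ys)
        # hand Welch-Satterthwaite: equal variances 1, n=3 -> t=-1.2247, df=4
        assert res.statistic == pytest.approx(-np.sqrt(1.5))
        assert res.df == pytest.approx(4.0)
        ref = sps.ttest_ind(xs, ys, equal_var=False)
        assert res.statistic == pytest.approx(ref.statistic)
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_scale_invariance(self):
        xs, ys = [1.1, 2.2, 2.9, 4.0], [2.0, 3.3, 4.1]
        a, b = welch_t_test(xs, ys), welch_t_test([10 * x for x in xs], [10 * y for y in ys])
        assert a.statistic == pytest.approx(b.statistic)
        assert a.df == pytest.approx(b.df)
        assert a.p_value == pytest.approx(b.p_value)

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])


class TestFisherTails:
    def test_zero_hits_is_one(self):
        assert fisher_right_tail(0, 5, 5, 20) == 1.0

    def test_matches_combinatorial_enumeration(self):
        assert fisher_right_tail(3, 5, 5, 20) == pytest.approx(
            float(hypergeom_right_tail(3, 5, 5, 20))
        )

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(2, 25), st.data())
    def test_enumeration_agreement_small_universes(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(0, min(K, n)))
        assert fisher_right_tail(k, K, n, N) == pytest.approx(
            float(hypergeom_right_tail(k, K, n, N)), rel=1e-9, abs=1e-12
        )

    def test_maximal_overlap_single_pmf_term(self):
        K, n, N = 4, 6, 20
        k = min(K, n)
        assert fisher_right_tail(k, K, n, N) == pytest.approx(
            float(sps.hypergeom.pmf(k, N, K, n))
        )

    def test_non_increasing_in_k(self):
        vals = [fisher_right_tail(k, 8, 10, 25) for k in range(0, 9)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_inconsistent_margins_rejected(self):
        with pytest.raises(ValueError):
            fisher_right_tail(6, 5, 5, 20)


class TestEase:
    def test_single_gene_gives_one(self):
        assert ease_score(1, 5, 5, 100) == 1.0

    def test_equals_tail_with_one_gene_removed(self):
        assert ease_score(5, 40, 10, 100) == pytest.approx(
            float(hypergeom_right_tail(4, 40, 10, 100))
        )

    def test_dominates_plain_fisher(self):
        for k, K, n, N in [(3, 5, 5, 20), (5, 40, 10, 100), (2, 4, 8, 25)]:
            assert ease_score(k, K, n, N) >= fisher_right_tail(k, K, n, N)

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            ease_score(0, 5, 5, 20)


class TestBonferroniAndGroupScore:
    def test_scaling_and_cap(self):
        assert bonferroni(0.01, 10) == pytest.approx(0.1)
        assert bonferroni(0.5, 10) == 1.0

    def test_preserves_ranking(self):
        ps = sorted([2.12e-14, 5.77e-13, 8.29e-10, 0.04])
        corrected = [bonferroni(p, 400) for p in ps]
        assert corrected == sorted(corrected)

    def test_threshold_equivalence(self):
        # geometric mean of all-0.05 scores sits exactly at the 1.3 cutoff
        assert group_enrichment_score([0.05] * 7) == pytest.approx(1.30103, abs=1e-5)

    def test_single_trivial_score(self):
        assert group_enrichment_score([1.0]) == 0.0

    def test_log_average(self):
        assert group_enrichment_score([0.1, 0.001]) == pytest.approx(2.0)

    def test_invalid_scores_rejected(self):
        with pytest.raises(ValueError):
            group_enrichment_score([0.0, 0.5])

    def test_display_floor(self):
        assert format_p(1e-300) == "< 2.2e-16"
        assert format_p(0.03).startswith("0.03")


class TestEnrichTerms:
    def _replicate(self, seed, fold_effect):
        n_genes = 300
        rows, truth = generate_annotation_table(
            n_genes, 8, enriched_term="term_0", fold_effect=fold_effect,
            seed=seed, subset_size=50, base_prob=0.08,
        )
        result = enrich_terms(truth["subset"], rows, min_count=1)
        return result[0].term if result else None

    def test_planted_term_ranked_first(self):
        wins = sum(self._replicate(seed, 10.0) == "term_0" for seed in range(100))
        assert wins >= 90

    def test_null_table_no_consistent_winner(self):
        wins = sum(self._replicate(seed, 1.0) == "term_0" for seed in range(60))
        assert wins < 30

    def test_min_count_filters_everything(self):
        rows = [("g1", "t1"), ("g2", "t1")]
        assert enrich_terms(["g1", "g2"], rows, min_count=10) == []

    def test_type_one_error_rate_under_null(self):
        # EASE < 0.05 rate across 200 null terms stays within 0.05 + 3 s.e.
        rows, truth = generate_annotation_table(
            400, 200, enriched_term="term_0", fold_effect=1.0,
            seed=99, subset_size=60, base_prob=0.1,
        )
        result = enrich_terms(truth["subset"], rows, min_count=1)
        n_terms = len(result)
        rate = sum(r.p_value < 0.05 for r in result) / n_terms
        se = np.sqrt(0.05 * 0.95 / n_terms)
        assert rate <= 0.05 + 3 * se
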