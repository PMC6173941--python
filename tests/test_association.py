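"""Exact one-tailed association, burden operations, and detection power."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact, kstest

from rarescreen.association import (
    TwoByTwo,
    associate,
    bonferroni_alpha,
    burden_permutation_test,
    burden_tally,
    detection_power,
    fisher_one_tailed,
    odds_ratio,
)
from rarescreen.core import AlleleCount, CohortGenotypes, VariantRecord


def hypergeom_tail_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Independent oracle: exhaustive enumeration of P(X >= a) in exact
    rational arithmetic over the hypergeometric support."""
    N, K, n = a + b + c + d, a + c, a + b
    denom = math.comb(N, n)
    total = Fraction(0)
    for k in range(a, min(K, n) + 1):
        if n - k <= N - K:
            total += Fraction(math.comb(K, k) * math.comb(N - K, n - k), denom)
    return total


class TestFisherOneTailed:
    def test_index_variant_worked_example(self):
        # combined carriers of the stop-gain: 10/694 cases vs 1/751 controls
        p = fisher_one_tailed(TwoByTwo(10, 684, 1, 750))
        assert p <= 0.004

    def test_no_minor_alleles_gives_one(self):
        assert fisher_one_tailed(TwoByTwo(0, 10, 0, 10)) == 1.0

    def test_small_table_exact_value(self):
        p = fisher_one_tailed(TwoByTwo(3, 2, 1, 4))
        assert p == pytest.approx(66 / 252, abs=1e-12)

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            TwoByTwo(-1, 2, 3, 4)

    @given(
        a=st.integers(0, 15), b=st.integers(0, 15),
        c=st.integers(0, 15), d=st.integers(0, 15),
    )
    @settings(deadline=None, max_examples=200)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        p = fisher_one_tailed(TwoByTwo(a, b, c, d))
        assert p == pytest.approx(float(hypergeom_tail_exact(a, b, c, d)), abs=1e-12)

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    @settings(deadline=None, max_examples=100)
    def test_matches_independent_library(self, a, b, c, d):
        if a + b == 0 or c + d == 0:
            return
        ours = fisher_one_tailed(TwoByTwo(a, b, c, d))
        theirs = fisher_exact([[a, b], [c, d]], alternative="greater")[1]
        assert ours == pytest.approx(theirs, abs=1e-10)

    def test_monotone_in_a_with_fixed_margins(self):
        # shifting one minor allele from controls to cases (margins fixed)
        previous = 1.0
        for a in range(0, 8):
            c = 7 - a
            p = fisher_one_tailed(TwoByTwo(a, 50 - a, c, 50 - c))
            assert p <= previous + 1e-12
            previous = p

    def test_zero_threshold_tail_is_one(self):
        assert fisher_one_tailed(TwoByTwo(0, 5, 3, 2)) == 1.0


class TestBonferroni:
    def test_family_of_three(self):
        alpha = bonferroni_alpha(0.05, 3)
        assert alpha == pytest.approx(0.0166667, abs=1e-6)
        assert f"{alpha:.3f}" == "0.017"

    @pytest.mark.parametrize("alpha,m,expected", [(0.05, 1, 0.05), (0.01, 5, 0.002)])
    def test_analytic_division(self, alpha, m, expected):
        assert bonferroni_alpha(alpha, m) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)
        with pytest.raises(ValueError):
            bonferroni_alpha(0.0, 3)


class TestAssociate:
    def test_significant_at_family_threshold(self):
        # 8/694 cases vs 1/751 controls, family of three tests
        res = associate("x", AlleleCount(0, 8, 694), AlleleCount(0, 1, 751),
                        alpha_family=0.05, m=3)
        assert res.p_one_tailed <= 0.015
        assert res.alpha_adjusted == pytest.approx(0.05 / 3)
        assert res.significant

    def test_recoded_common_variant_not_significant(self):
        res = associate("x", AlleleCount(0, 19, 318), AlleleCount(1, 7, 254), m=3)
        assert res.p_one_tailed > 0.05
        assert not res.significant

    def test_identical_counts_not_significant(self):
        res = associate("x", AlleleCount(0, 3, 100), AlleleCount(0, 3, 100))
        assert res.p_one_tailed > 0.5
        assert not res.significant

    def test_zero_total_alleles_undefined(self):
        with pytest.raises(ValueError):
            associate("x", AlleleCount(0, 0, 0), AlleleCount(0, 1, 10))

    def test_odds_ratio_infinity_without_control_carriers(self):
        res = associate("x", AlleleCount(0, 5, 100), AlleleCount(0, 0, 100))
        assert math.isinf(res.odds_ratio)
        assert odds_ratio(TwoByTwo(2, 98, 1, 99)) == pytest.approx(99 * 2 / 98)


class TestBurden:
    def _cohort(self, matrix):
        variants = [
            VariantRecord("chr1", 10 * (j + 1), "A", "T") for j in range(matrix.shape[1])
        ]
        subjects = [f"s{i}" for i in range(matrix.shape[0])]
        return CohortGenotypes("cases", subjects, variants, matrix)

    def test_planted_counts_recovered_exactly(self):
        rng = np.random.default_rng(11)
        matrix = rng.integers(0, 3, size=(25, 8)).astype(np.int8)
        cohort = self._cohort(matrix)
        qualifying = [v.key for v in cohort.variants[:5]]
        burdens = burden_tally(cohort, qualifying)
        assert np.array_equal(burdens, matrix[:, :5].sum(axis=1))

    def test_empty_qualifying_set_and_missing_dosages(self):
        matrix = np.array([[1, -1], [2, 1]], dtype=np.int8)
        cohort = self._cohort(matrix)
        assert burden_tally(cohort, []).tolist() == [0, 0]
        # missing dosages contribute zero, not -1
        assert burden_tally(cohort, [v.key for v in cohort.variants]).tolist() == [1, 3]

    def test_permutation_identical_sequences(self):
        p = burden_permutation_test([3] * 10, [3] * 10, n_perm=200, seed=1)
        assert p == 1.0

    def test_permutation_maximal_separation(self):
        p = burden_permutation_test([5] * 10, [0] * 10, n_perm=2000, seed=1)
        assert p < 0.01

    def test_permutation_reproducible_and_errors(self):
        args = ([1, 2, 3, 4], [0, 1, 2, 2])
        assert burden_permutation_test(*args, n_perm=500, seed=7) == \
            burden_permutation_test(*args, n_perm=500, seed=7)
        with pytest.raises(ValueError):
            burden_permutation_test([1], [2], n_perm=0)
        with pytest.raises(ValueError):
            burden_permutation_test([], [1])

    def test_permutation_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(3)
        ps = []
        for _ in range(200):
            pooled = rng.poisson(2.0, size=30)
            ps.append(burden_permutation_test(pooled[:15], pooled[15:],
                                              n_perm=199, seed=int(rng.integers(1 << 30))))
        # discrete, conservative p-values: KS against uniform with loose bound
        stat = kstest(ps, "uniform").statistic
        assert stat < 0.15


class TestDetectionPower:
    @pytest.mark.parametrize("maf,n,expected", [
        (0.0, 76, 0.0),
        (1.0, 1, 1.0),
        (0.005, 76, 0.533),
        (0.005, 150, 0.778),
    ])
    def test_closed_form(self, maf, n, expected):
        assert detection_power(maf, n) == pytest.approx(expected, abs=5e-4)

    def test_monotone_in_both_arguments(self):
        mafs = np.linspace(0.0, 0.05, 11)
        powers = [detection_power(m, 76) for m in mafs]
        assert all(x <= y for x, y in zip(powers, powers[1:]))
        sizes = [10, 50, 100, 500]
        powers = [detection_power(0.005, n) for n in sizes]
        assert all(x < y for x, y in zip(powers, powers[1:]))
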