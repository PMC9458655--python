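"""Exact binomial machinery, odds ratios, co-occurrence and ordering tests."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from clonalshift.stats import (
    OrderingResult,
    ShiftCount,
    allelic_shift_test,
    binom_one_sided_ge,
    binom_two_sided,
    clonal_order_test,
    cooccurrence_test,
    locus_enrichment,
    odds_ratio_from_props,
)


def exact_tails(k: int, n: int, p0: Fraction) -> tuple[Fraction, Fraction]:
    """Exhaustive-rational binomial tails, independent of scipy."""
    pmf = [
        Fraction(math.comb(n, i)) * p0**i * (1 - p0) ** (n - i) for i in range(n + 1)
    ]
    return sum(pmf[: k + 1]), sum(pmf[k:])


class TestBinomial:
    @pytest.mark.parametrize(
        "k,n,expected",
        [
            (23, 28, 9.12e-4),  # risk haplotype amplified by gains
            (14, 16, 4.18e-3),  # retained by losses
            (51, 59, 9.05e-9),  # duplicated by CNLOH
        ],
    )
    def test_allelic_shift_p_values(self, k, n, expected):
        p = binom_two_sided(k, n, 0.5)
        assert p == pytest.approx(expected, rel=5e-3)

    def test_nominal_variant_count(self):
        # 7 of 19 telomere variants nominally associated at the 5% rate
        assert binom_one_sided_ge(7, 19, 0.05) == pytest.approx(2.31e-5, rel=5e-3)

    def test_center_is_one(self):
        assert binom_two_sided(14, 28, 0.5) == 1.0

    def test_zero_successes_one_sided(self):
        assert binom_one_sided_ge(0, 50, 0.2) == 1.0

    @pytest.mark.parametrize("k,n,p0", [(5, 12, 0.3), (0, 9, 0.5), (17, 25, 0.62), (25, 25, 0.9)])
    def test_matches_exhaustive_enumeration(self, k, n, p0):
        lower, upper = exact_tails(k, n, Fraction(p0).limit_denominator(10**6))
        assert binom_one_sided_ge(k, n, p0) == pytest.approx(float(upper), rel=1e-12)
        expected_two = min(1.0, 2.0 * min(float(lower), float(upper)))
        assert binom_two_sided(k, n, p0) == pytest.approx(expected_two, rel=1e-12)

    def test_minlike_convention_available(self):
        p = binom_two_sided(7, 20, 0.3, method="minlike")
        assert p == pytest.approx(sps.binomtest(7, 20, 0.3).pvalue, rel=1e-12)

    @given(n=st.integers(1, 60), k_frac=st.floats(0, 1), p0=st.floats(0.05, 0.95))
    @settings(max_examples=80, deadline=None)
    def test_pvalue_bounds_and_tail_ordering(self, n, k_frac, p0):
        k = min(n, int(round(k_frac * n)))
        two = binom_two_sided(k, n, p0)
        ge = binom_one_sided_ge(k, n, p0)
        assert 0.0 < two <= 1.0
        assert 0.0 < ge <= 1.0
        # doubling the smaller tail can never fall below either tail's minimum
        le = float(sps.binom.cdf(k, n, p0))
        assert two >= min(le, ge) - 1e-12

    def test_symmetry_at_half(self):
        for k, n in [(3, 10), (0, 7), (20, 28)]:
            assert binom_two_sided(k, n, 0.5) == pytest.approx(
                binom_two_sided(n - k, n, 0.5), rel=1e-12
            )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            binom_two_sided(5, 4, 0.5)
        with pytest.raises(ValueError):
            binom_one_sided_ge(1, 4, 1.0)


class TestAllelicShift:
    def test_cnloh_shift(self):
        res = allelic_shift_test(ShiftCount("CNLOH", 51, 59))
        assert res.p_value == pytest.approx(9.05e-9, rel=5e-3)

    def test_extreme_counts_symmetric(self):
        up = allelic_shift_test(ShiftCount("gain", 30, 30))
        down = allelic_shift_test(ShiftCount("gain", 0, 30))
        assert up.p_value == pytest.approx(down.p_value, rel=1e-12)

    def test_empty_flagged(self):
        res = allelic_shift_test(ShiftCount("loss", 0, 0))
        assert res.p_value is None and res.note

    def test_power_at_reported_retention(self):
        """With the CNLOH retention probability of 51/59, the n=59 shift
        test rejects at alpha=0.05 in >=80% of replicate cohorts."""
        rng = np.random.default_rng(12)
        k = rng.binomial(59, 51 / 59, size=2000)
        pvals = np.minimum(
            1.0, 2.0 * np.minimum(sps.binom.cdf(k, 59, 0.5), sps.binom.sf(k - 1, 59, 0.5))
        )
        assert (pvals < 0.05).mean() >= 0.80

    def test_type_one_error_calibration(self):
        """Null rejection rate near nominal alpha (n chosen large enough
        that the exact test's discrete size is ~0.05)."""
        n = 997
        rng = np.random.default_rng(5)
        k = rng.binomial(n, 0.5, size=10_000)
        pvals = np.minimum(
            1.0, 2.0 * np.minimum(sps.binom.cdf(k, n, 0.5), sps.binom.sf(k - 1, n, 0.5))
        )
        rate = (pvals <= 0.05).mean()
        assert 0.04 <= rate <= 0.06


class TestOddsRatio:
    def test_reported_proportion_pairs(self):
        assert odds_ratio_from_props(0.7835, 0.7103) == pytest.approx(1.48, abs=5e-3)
        assert odds_ratio_from_props(0.9412, 0.7103) == pytest.approx(6.53, abs=5e-3)

    def test_identity(self):
        assert odds_ratio_from_props(0.42, 0.42) == pytest.approx(1.0)

    @given(p1=st.floats(0.01, 0.99), p2=st.floats(0.01, 0.99))
    @settings(max_examples=60, deadline=None)
    def test_reciprocity(self, p1, p2):
        assert odds_ratio_from_props(p1, p2) * odds_ratio_from_props(p2, p1) == pytest.approx(
            1.0, rel=1e-9
        )

    def test_boundary_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_from_props(0.0, 0.5)
        with pytest.raises(ValueError):
            odds_ratio_from_props(0.5, 1.0)


class TestCooccurrence:
    def test_perfect_association(self):
        res = cooccurrence_test([[10, 0], [0, 10]])
        assert res.odds_ratio > 100 and res.p_value < 0.01 and res.haldane

    def test_no_association(self):
        res = cooccurrence_test([[5, 5], [5, 5]])
        assert res.odds_ratio == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        """Fisher p equals the exhaustive sum of hypergeometric outcome
        probabilities no larger than the observed one."""
        table = [[36, 8], [19, 35]]
        res = cooccurrence_test(table)
        a, b = table[0]
        c, d = table[1]
        n, row1, col1 = a + b + c + d, a + b, a + c
        dist = sps.hypergeom(n, row1, col1)
        obs = dist.pmf(a)
        support = np.arange(max(0, col1 - (n - row1)), min(row1, col1) + 1)
        p_oracle = float(dist.pmf(support)[dist.pmf(support) <= obs * (1 + 1e-9)].sum())
        assert res.method == "fisher_exact"
        assert res.p_value == pytest.approx(p_oracle, rel=1e-9)

    def test_large_table_uses_chi2(self):
        res = cooccurrence_test([[6000, 2000], [2500, 5500]])
        assert res.method == "chi2" and res.p_value < 1e-10

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            cooccurrence_test([[0, 0], [0, 0]])


class TestClonalOrder:
    def test_saturated(self):
        records = [(0.8, 0.3)] * 20
        res = clonal_order_test(records)
        assert res.k_af_gt_cf == 20
        assert res.p_value == pytest.approx(2.0 * 0.5**20, rel=1e-12)

    def test_all_ties_flagged(self):
        res = clonal_order_test([(0.5, 0.5)] * 6)
        assert isinstance(res, OrderingResult)
        assert res.p_value is None and res.n == 0 and res.n_ties == 6

    def test_split_tie_policy(self):
        res = clonal_order_test([(0.6, 0.2)] * 4 + [(0.5, 0.5)] * 2, tie_policy="split")
        assert res.n == 6 and res.k_af_gt_cf == 5

    def test_generator_cohort_rate(self, default_cohort):
        """AF exceeds CF at the configured rate (0.95) in the simulated cohort."""
        pairs = [
            (s.v617f_af, s.mca.cell_fraction)
            for s in default_cohort
            if s.v617f_af is not None and s.mca is not None
        ]
        assert len(pairs) > 400
        res = clonal_order_test(pairs)
        rate = res.k_af_gt_cf / res.n
        se = math.sqrt(0.95 * 0.05 / res.n)
        assert abs(rate - 0.95) <= 3 * se

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            clonal_order_test([(0.0, 0.5)])


class TestLocusEnrichment:
    def test_strong_enrichment_vs_population_rate(self):
        assert locus_enrichment(300, 933, 0.03) < 1e-8

    def test_null_rate(self):
        k = round(500 * 0.03)
        assert 0.3 <= locus_enrichment(k, 500, 0.03) <= 1.0

    def test_zero_observed(self):
        assert locus_enrichment(0, 100, 0.1) == 1.0
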