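"""Agreement statistics: Bland-Altman, t inference, Wilcoxon, regression LoA."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from ndiagree import (
    BAStats,
    BlandAltman,
    PairedScores,
    RegressionLoA,
    apply_bias_transform,
    bland_altman,
    differences_and_means,
    normality_summary,
    one_sample_t,
    regression_loa,
    wilcoxon_signed_rank,
)
from ndiagree.agreement import exact_signed_rank_p


def brute_force_signed_rank_p(d):
    """Two-sided signed-rank p by full enumeration over all 2^n sign vectors.

    Independent oracle: ranks the absolute nonzero differences with
    midranks, then walks every sign assignment explicitly.
    """
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    w_all = [sum(r for r, s in zip(ranks, signs) if s)
             for signs in itertools.product([False, True], repeat=n)]
    w_all = np.asarray(w_all)
    eps = 1e-9
    lower = np.mean(w_all <= w_obs + eps)
    upper = np.mean(w_all >= w_obs - eps)
    return min(1.0, 2.0 * min(lower, upper))


class TestDifferencesAndMeans:
    def test_identical_methods(self):
        D, A = differences_and_means(PairedScores("x", "y", [10, 20], [10, 20]))
        np.testing.assert_array_equal(D, [0, 0])
        np.testing.assert_array_equal(A, [10, 20])

    def test_hand_arithmetic(self):
        D, A = differences_and_means(PairedScores("x", "y", [10, 20], [12, 24]))
        np.testing.assert_array_equal(D, [-2, -4])
        np.testing.assert_array_equal(A, [11, 22])

    def test_length_one_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            PairedScores("x", "y", [0.0], [0.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            PairedScores("x", "y", [0.0, 1.0], [0.0, 1.0, 2.0])


class TestBlandAltman:
    def test_identical_methods_degenerate(self):
        ba = bland_altman(PairedScores("x", "y", [3, 7, 9.0], [3, 7, 9.0]))
        assert ba.d == 0 and ba.sd == 0
        assert (ba.loa_lower, ba.loa_upper) == (0, 0)
        assert ba.degenerate and np.isnan(ba.t_stat)

    def test_from_summary_reproduces_published_arithmetic(self):
        # d=-4.6, sd=5.3 -> upper LoA 5.8 at one decimal
        assert round(BAStats.from_summary(-4.6, 5.3, 201).loa_upper, 1) == 5.8
        # d=-2.3, sd=2.8 -> lower LoA -7.8
        assert round(BAStats.from_summary(-2.3, 2.8, 201).loa_lower, 1) == -7.8

    def test_loa_width_and_se_identities(self, rng):
        a = rng.uniform(0, 50, 80)
        b = a + rng.normal(1.0, 3.0, 80)
        ba = bland_altman(PairedScores("a", "b", a, b))
        assert ba.loa_upper - ba.loa_lower == pytest.approx(2 * 1.96 * ba.sd)
        assert ba.se == pytest.approx(ba.sd / np.sqrt(ba.n))
        assert ba.ci_low <= ba.d <= ba.ci_high
        assert ba.loa_lower < ba.ci_low and ba.ci_high < ba.loa_upper

    def test_antisymmetry_under_method_swap(self, rng):
        a = rng.uniform(0, 50, 40)
        b = a + rng.normal(-2.0, 4.0, 40)
        pair = PairedScores("a", "b", a, b)
        fwd, rev = bland_altman(pair), bland_altman(pair.swapped())
        assert rev.d == pytest.approx(-fwd.d)
        assert rev.sd == pytest.approx(fwd.sd)
        assert rev.t_stat == pytest.approx(-fwd.t_stat)
        assert rev.loa_upper == pytest.approx(-fwd.loa_lower)
        assert rev.loa_lower == pytest.approx(-fwd.loa_upper)

    @given(st.floats(-20, 20))
    @settings(max_examples=30, deadline=None)
    def test_location_invariance(self, c):
        rng = np.random.default_rng(5)
        a = rng.uniform(5, 45, 30)
        b = a + rng.normal(1, 2, 30)
        base = bland_altman(PairedScores("a", "b", a, b))
        shifted = bland_altman(PairedScores("a", "b", a + c, b + c))
        assert shifted.d == pytest.approx(base.d, abs=1e-9)
        assert shifted.sd == pytest.approx(base.sd, abs=1e-9)
        assert shifted.loa_upper == pytest.approx(base.loa_upper, abs=1e-9)

    def test_matches_scipy_t_inference(self, rng):
        a = rng.uniform(0, 50, 60)
        b = a + rng.normal(1.5, 4.0, 60)
        ba = bland_altman(PairedScores("a", "b", a, b))
        t_ref = sps.ttest_rel(a, b)
        assert ba.t_stat == pytest.approx(t_ref.statistic)
        assert ba.p_value == pytest.approx(t_ref.pvalue)

    def test_estimator_interface(self, rng):
        a = rng.uniform(0, 50, 30)
        b = a + 1
        est = BlandAltman(z=2.0).fit(a, b)
        assert est.get_params() == {"z": 2.0, "ci_method": "z"}
        assert est.loa_upper_ - est.loa_lower_ == pytest.approx(4.0 * est.sd_)

    def test_t_quantile_ci_is_wider(self, rng):
        a = rng.uniform(0, 50, 10)
        b = a + rng.normal(1, 2, 10)
        z_ci = bland_altman(PairedScores("a", "b", a, b), ci_method="z")
        t_ci = bland_altman(PairedScores("a", "b", a, b), ci_method="t")
        assert t_ci.ci_high - t_ci.ci_low > z_ci.ci_high - z_ci.ci_low


class TestOneSampleT:
    def test_hand_computed_example(self):
        t, df, p, _ = one_sample_t([1, 2, 3])
        assert t == pytest.approx(3.4641016)
        assert df == 2
        assert p == pytest.approx(0.0742, abs=5e-4)

    def test_symmetric_differences_give_zero_t(self):
        t, _, p, _ = one_sample_t([-1, 1])
        assert t == 0 and p == pytest.approx(1.0)

    def test_published_ci_arithmetic(self):
        # d=-2.3, sd=5.0, n=201 -> 95% CI lower bound -3.0 at one decimal
        d, sd, n = -2.3, 5.0, 201
        lo = d - 1.96 * sd / np.sqrt(n)
        ba = BAStats.from_summary(d, sd, n)
        assert ba.ci_low == pytest.approx(lo)
        assert round(ba.ci_low, 1) == -3.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            one_sample_t([2.0, 2.0, 2.0])


class TestWilcoxon:
    def test_identical_pairs_degenerate(self):
        res = wilcoxon_signed_rank(PairedScores("a", "b", [1, 2, 3.0], [1, 2, 3.0]))
        assert res.degenerate and res.p_value == 1.0 and res.n_effective == 0

    def test_two_opposite_differences(self):
        res = wilcoxon_signed_rank(PairedScores("a", "b", [1.0, 0.0], [0.0, 1.0]))
        assert res.p_value == pytest.approx(1.0)

    def test_five_positive_differences_exact(self):
        res = wilcoxon_signed_rank(
            PairedScores("a", "b", [1, 2, 3, 4, 5.0], [0, 0, 0, 0, 0.0]))
        assert res.method == "exact"
        assert res.w_statistic == 0
        assert res.p_value == pytest.approx(2 / 32)

    def test_statistic_is_min_of_rank_sums(self, rng):
        d = rng.normal(0.5, 1, 12)
        res = wilcoxon_signed_rank(PairedScores("a", "b", d, np.zeros(12)))
        assert 0 <= res.w_statistic <= res.n_effective * (res.n_effective + 1) / 2

    @given(st.lists(st.integers(-40, 40), min_size=2, max_size=10))
    @settings(max_examples=150, deadline=None)
    def test_exact_p_matches_brute_force_enumeration(self, diffs):
        d = np.asarray(diffs, dtype=float)
        assert exact_signed_rank_p(d) == pytest.approx(brute_force_signed_rank_p(d))

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(25):
            d = rng.normal(0.3, 1.0, 12)
            res = wilcoxon_signed_rank(PairedScores("a", "b", d, np.zeros(12)))
            ref = sps.wilcoxon(d, method="exact")
            assert res.method == "exact"
            assert res.p_value == pytest.approx(ref.pvalue)

    def test_approximation_matches_scipy_with_correction(self, rng):
        d = rng.normal(0.5, 2.0, 60)
        res = wilcoxon_signed_rank(PairedScores("a", "b", d, np.zeros(60)))
        ref = sps.wilcoxon(d, method="approx", correction=True)
        assert res.method == "normal-approximation"
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    def test_large_or_tied_samples_use_approximation(self, rng):
        tied = np.array([1.0, 1.0, 2.0, -1.0, 3.0])
        res = wilcoxon_signed_rank(PairedScores("a", "b", tied, np.zeros(5)))
        assert res.method == "normal-approximation"
        big = rng.normal(0.2, 1, 30)
        assert wilcoxon_signed_rank(
            PairedScores("a", "b", big, np.zeros(30))).method == "normal-approximation"

    def test_pratt_policy_keeps_zeros_in_ranking(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([1.0, 0.0, 0.0, 0.0])
        wil = wilcoxon_signed_rank(PairedScores("a", "b", a, b), zero_method="wilcox")
        pratt = wilcoxon_signed_rank(PairedScores("a", "b", a, b), zero_method="pratt")
        assert wil.n_effective == pratt.n_effective == 3
        assert pratt.w_statistic >= wil.w_statistic  # zero consumed rank 1


class TestRegressionLoA:
    def test_noiseless_line_recovered(self):
        A_src = np.array([0.0, 10, 20, 30, 40])
        # construct a,b with D = 0.5*A - 1 exactly
        D = 0.5 * A_src - 1
        a = A_src + D / 2
        b = A_src - D / 2
        reg = regression_loa(PairedScores("a", "b", a, b))
        assert reg.b1 == pytest.approx(0.5, abs=1e-9)
        assert reg.b0 == pytest.approx(-1.0, abs=1e-9)
        assert reg.sd_res == pytest.approx(0.0, abs=1e-9)

    def test_hand_ols_three_points(self):
        # A=(0,1,2), D=(0,1,1): b1=1/2, b0=1/6, residuals (-1/6, 1/3, -1/6)
        A = np.array([0.0, 1.0, 2.0])
        D = np.array([0.0, 1.0, 1.0])
        a = A + D / 2
        b = A - D / 2
        reg = regression_loa(PairedScores("a", "b", a, b))
        assert reg.b1 == pytest.approx(0.5)
        assert reg.b0 == pytest.approx(1 / 6)
        assert reg.sd_res == pytest.approx(np.sqrt((1 / 36 + 1 / 9 + 1 / 36) / 1))

    def test_band_width_constant(self, rng):
        a = rng.uniform(0, 50, 50)
        b = a + rng.normal(0, 2, 50) + 0.1 * a
        reg = regression_loa(PairedScores("a", "b", a, b))
        lower, center, upper = reg.loa_band(np.linspace(0, 50, 7))
        np.testing.assert_allclose(upper - lower, 2 * 1.96 * reg.sd_res)
        np.testing.assert_allclose(center - lower, 1.96 * reg.sd_res)

    def test_zero_slope_fit_degrades_to_classical_loa(self, rng):
        """On centered averages with no trend, band ~ d +/- 1.96*sd."""
        a = rng.uniform(10, 40, 200)
        b = a + rng.normal(-1.0, 2.0, 200)
        pair = PairedScores("a", "b", a, b)
        ba = bland_altman(pair)
        reg = regression_loa(pair)
        D, A = differences_and_means(pair)
        lower, center, upper = reg.loa_band(np.mean(A))
        assert center == pytest.approx(ba.d)  # OLS passes through the means
        assert reg.sd_res == pytest.approx(ba.sd, rel=0.05)

    def test_constant_averages_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            regression_loa(PairedScores("a", "b", [4, 6, 5.0], [6, 4, 5.0]))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            RegressionLoA().fit([1.0, 2.0], [0.0, 1.0])

    def test_matches_statsmodels_p(self, rng):
        a = rng.uniform(0, 50, 80)
        b = 0.9 * a + rng.normal(2, 1.5, 80)
        reg = regression_loa(PairedScores("a", "b", a, b))
        assert 0 <= reg.model_p <= 1
        assert reg.model_p < 0.001  # strong proportional bias by construction


class TestNormalityAndTransforms:
    def test_symmetric_sample_has_zero_skew(self):
        s = normality_summary([-1.0, 0.0, 1.0], bins=3)
        assert s.skewness == pytest.approx(0.0)
        assert s.counts.sum() == 3

    def test_constant_sample_flagged(self):
        s = normality_summary([2.0, 2.0, 2.0])
        assert s.zero_variance and np.isnan(s.skewness)

    def test_normal_sample_skew_small(self, rng):
        d = rng.normal(0, 1, 10000)
        s = normality_summary(d, bins=30)
        assert abs(s.skewness) < 0.1  # ~4 SE of skewness at n=1e4
        assert s.counts.sum() == 10000

    def test_linear_identity_and_rescale(self):
        out = apply_bias_transform([1.0, 2.0], kind="linear", offset=0, scale=1)
        np.testing.assert_array_equal(out.values, [1.0, 2.0])
        out = apply_bias_transform([24.0], kind="linear", offset=0, scale=50 / 24)
        assert out.values[0] == pytest.approx(50.0)

    def test_log_with_offset_admits_zero(self):
        out = apply_bias_transform([0.0, np.e - 1], kind="log", offset=1.0)
        np.testing.assert_allclose(out.values, [0.0, 1.0])
        assert "log" in out.label

    def test_log_rejects_nonpositive_argument(self):
        with pytest.raises(ValueError, match="-2"):
            apply_bias_transform([5.0, -2.0], kind="log", offset=1.0)
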