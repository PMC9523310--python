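"""Estimator core: Wald ratio, IVW, MR-Egger, weighted median, scales."""

import math

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from ferromr import (
    EstimationError,
    HarmonizedInstrument,
    MREstimate,
    heterogeneity_q,
    ivw_fixed,
    mr_egger,
    pvalue_two_sided,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from ferromr.estimators import Z_975

from conftest import random_instruments


def _h(bx, by, sx=0.01, sy=0.05, rsid="rs1"):
    return HarmonizedInstrument(
        rsid=rsid, effect_allele="A", other_allele="G",
        beta_exposure=bx, se_exposure=sx, beta_outcome=by, se_outcome=sy,
    )


def _hs(bx, by, sx, sy):
    return [_h(bx[j], by[j], sx[j], sy[j], rsid=f"rs{j}") for j in range(len(bx))]


class TestWaldRatio:
    def test_point_estimate_is_effect_ratio(self):
        est = wald_ratio(_h(0.5, 0.4))
        assert est.theta == pytest.approx(0.8)

    def test_first_order_se(self):
        est = wald_ratio(_h(0.5, 0.4, sy=0.1), se_order="first")
        assert est.se == pytest.approx(0.2)

    def test_second_order_se(self):
        # sqrt(0.1^2/0.5^2 + 0.4^2 0.05^2 / 0.5^4) = sqrt(0.04 + 0.0064)
        est = wald_ratio(_h(0.5, 0.4, sx=0.05, sy=0.1), se_order="second")
        assert est.se == pytest.approx(math.sqrt(0.0464), rel=1e-12)
        assert est.se == pytest.approx(0.21541, abs=5e-6)

    def test_zero_exposure_effect_rejected(self):
        with pytest.raises(EstimationError):
            wald_ratio(_h(0.0, 0.4))

    def test_ci_and_pvalue_follow_normal_theory(self):
        est = wald_ratio(_h(0.5, 0.4, sy=0.1))
        assert est.ci_low == pytest.approx(est.theta - Z_975 * est.se)
        assert est.ci_high == pytest.approx(est.theta + Z_975 * est.se)
        assert est.pvalue == pytest.approx(pvalue_two_sided(est.z))


class TestIVW:
    def test_single_instrument_equals_wald_ratio(self):
        w = wald_ratio(_h(0.5, 0.4))
        pooled = ivw_fixed([w])
        assert pooled.theta == w.theta and pooled.se == w.se

    def test_two_equal_weight_instruments(self):
        ests = [MREstimate.from_theta_se("wald_ratio", t, 1.0, 1) for t in (1.0, 3.0)]
        pooled = ivw_fixed(ests)
        assert pooled.theta == pytest.approx(2.0)
        assert pooled.se == pytest.approx(1 / math.sqrt(2))

    def test_constant_input_any_weights(self):
        ests = [MREstimate.from_theta_se("wald_ratio", 2.0, s, 1)
                for s in (0.1, 0.5, 2.0)]
        assert ivw_fixed(ests).theta == pytest.approx(2.0)

    def test_empty_input_rejected(self):
        with pytest.raises(EstimationError):
            ivw_fixed([])

    def test_matches_explicit_sum_oracle_on_random_inputs(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 12))
            theta = rng.normal(size=n)
            se = rng.uniform(0.05, 2.0, n)
            ests = [MREstimate.from_theta_se("wald_ratio", t, s, 1)
                    for t, s in zip(theta, se)]
            pooled = ivw_fixed(ests)
            w = se**-2.0
            assert pooled.theta == pytest.approx(np.sum(w * theta) / np.sum(w),
                                                 abs=1e-12)
            assert pooled.se == pytest.approx(np.sum(w) ** -0.5, abs=1e-12)


class TestMREgger:
    def test_line_through_origin(self):
        h = _hs([0.1, 0.2, 0.3], [0.05, 0.10, 0.15],
                [0.01] * 3, [0.03, 0.04, 0.05])
        slope, intercept = mr_egger(h)
        assert slope.theta == pytest.approx(0.5, abs=1e-12)
        assert intercept.theta == pytest.approx(0.0, abs=1e-12)

    def test_exact_affine_fit(self):
        bx = [0.1, 0.2, 0.3]
        by = [0.1 + 0.5 * b for b in bx]
        slope, intercept = mr_egger(_hs(bx, by, [0.01] * 3, [0.03, 0.05, 0.02]))
        assert slope.theta == pytest.approx(0.5, abs=1e-12)
        assert intercept.theta == pytest.approx(0.1, abs=1e-12)

    def test_matches_statsmodels_wls_oracle(self, rng):
        for _ in range(20):
            h = random_instruments(rng, int(rng.integers(3, 15)))
            slope, intercept = mr_egger(h)
            bx = np.array([x.beta_exposure for x in h])
            by = np.array([x.beta_outcome for x in h])
            sy = np.array([x.se_outcome for x in h])
            sign = np.sign(bx)
            res = sm.WLS(by * sign, sm.add_constant(bx * sign),
                         weights=sy**-2.0).fit()
            assert slope.theta == pytest.approx(res.params[1], abs=1e-10)
            assert intercept.theta == pytest.approx(res.params[0], abs=1e-10)
            infl = math.sqrt(max(res.scale, 1.0) / res.scale)
            assert slope.se == pytest.approx(res.bse[1] * infl, rel=1e-9)
            assert intercept.se == pytest.approx(res.bse[0] * infl, rel=1e-9)

    def test_orientation_invariant_to_allele_coding(self, rng):
        h = random_instruments(rng, 6)
        ref = mr_egger(h)
        flipped = [
            HarmonizedInstrument(
                rsid=x.rsid, effect_allele=x.other_allele,
                other_allele=x.effect_allele,
                beta_exposure=-x.beta_exposure, se_exposure=x.se_exposure,
                beta_outcome=-x.beta_outcome, se_outcome=x.se_outcome,
            )
            for x in h
        ]
        alt = mr_egger(flipped)
        assert alt[0].theta == pytest.approx(ref[0].theta)
        assert alt[1].theta == pytest.approx(ref[1].theta)

    def test_too_few_or_degenerate_inputs_rejected(self):
        with pytest.raises(EstimationError):
            mr_egger(_hs([0.1, 0.2], [0.05, 0.1], [0.01] * 2, [0.03] * 2))
        with pytest.raises(EstimationError):
            mr_egger(_hs([0.2, 0.2, -0.2], [0.1, 0.12, -0.09],
                         [0.01] * 3, [0.03] * 3))

    def test_variance_never_deflated_below_weighted_ls(self):
        # exact fit => zero residuals => scale floored at 1, not 0
        bx = [0.1, 0.2, 0.3]
        by = [0.05, 0.10, 0.15]
        slope, _ = mr_egger(_hs(bx, by, [0.01] * 3, [0.03] * 3))
        assert slope.se > 0


class TestWeightedMedian:
    def test_equal_weights_give_simple_median(self):
        h = _hs([0.1, 0.1, 0.1], [0.1 * r for r in (1.0, 2.0, 9.0)],
                [0.01] * 3, [0.05] * 3)
        est = weighted_median(h, n_boot=100, seed=0)
        assert est.theta == pytest.approx(2.0)

    def test_hand_interpolated_two_point_quantile(self):
        # ratios {1, 2}, weights {0.25, 0.75}: s = {0.125, 0.625};
        # interpolation at 0.5 gives 1 + (0.5-0.125)/0.5 = 1.75
        from ferromr.estimators import _weighted_median_point

        theta = _weighted_median_point(np.array([1.0, 2.0]),
                                       np.array([0.25, 0.75]))
        assert theta == pytest.approx(1.75)

    def test_bootstrap_se_reproducible_under_seed(self, rng):
        h = random_instruments(rng, 5)
        a = weighted_median(h, n_boot=500, seed=42)
        b = weighted_median(h, n_boot=500, seed=42)
        assert a.theta == b.theta and a.se == b.se

    def test_too_few_instruments_rejected(self):
        with pytest.raises(EstimationError):
            weighted_median(_hs([0.1, 0.2], [0.05, 0.1], [0.01] * 2, [0.05] * 2))


class TestScalesAndCompanions:
    def test_null_log_odds_maps_to_unit_or(self):
        est = MREstimate.from_theta_se("ivw_fixed", 0.0, 0.1, 3)
        or_, lo, hi = to_odds_ratio(est)
        assert or_ == pytest.approx(1.0)
        assert lo < 1 < hi

    def test_log_exp_round_trip(self):
        se = math.log(2.0) / Z_975  # CI (ln 1, ln 4)
        est = MREstimate.from_theta_se("ivw_fixed", math.log(2.0), se, 3)
        or_, lo, hi = to_odds_ratio(est)
        assert (or_, lo, hi) == pytest.approx((2.0, 1.0, 4.0))

    def test_or_scale_matches_reported_magnitude(self):
        # a log-odds estimate of 0.63658 corresponds to OR ~ 1.89
        est = MREstimate.from_theta_se("ivw_fixed", 0.63658, 0.3, 3)
        assert to_odds_ratio(est)[0] == pytest.approx(1.89, abs=0.005)

    @pytest.mark.parametrize("z,expected,tol", [
        (0.0, 1.0, 0),
        (1.959964, 0.05, 1e-7),
        (6.6, 4.1e-11, 1e-12),
    ])
    def test_two_sided_pvalue(self, z, expected, tol):
        assert pvalue_two_sided(z) == pytest.approx(expected, abs=tol)

    def test_heterogeneity_q_identical_estimates(self):
        ests = [MREstimate.from_theta_se("wald_ratio", 1.0, s, 1)
                for s in (0.1, 0.2, 0.3)]
        q, df, p = heterogeneity_q(ests, ivw_fixed(ests))
        assert q == pytest.approx(0.0) and df == 2 and p == pytest.approx(1.0)

    def test_heterogeneity_q_hand_example(self):
        ests = [MREstimate.from_theta_se("wald_ratio", t, 1.0, 1) for t in (1.0, 3.0)]
        pooled = ivw_fixed(ests)
        q, df, _ = heterogeneity_q(ests, pooled)
        assert q == pytest.approx(2.0) and df == 1

    def test_heterogeneity_needs_two_estimates(self):
        e = MREstimate.from_theta_se("wald_ratio", 1.0, 1.0, 1)
        with pytest.raises(EstimationError):
            heterogeneity_q([e], e)


class TestEstimatorInvariances:
    @pytest.mark.parametrize("n", [3, 5, 9])
    def test_negating_outcome_negates_theta_keeps_se(self, rng, n):
        h = random_instruments(rng, n)
        neg = [
            HarmonizedInstrument(
                rsid=x.rsid, effect_allele=x.effect_allele,
                other_allele=x.other_allele,
                beta_exposure=x.beta_exposure, se_exposure=x.se_exposure,
                beta_outcome=-x.beta_outcome, se_outcome=x.se_outcome,
            )
            for x in h
        ]
        ivw_a = ivw_fixed([wald_ratio(x) for x in h])
        ivw_b = ivw_fixed([wald_ratio(x) for x in neg])
        assert ivw_b.theta == pytest.approx(-ivw_a.theta)
        assert ivw_b.se == pytest.approx(ivw_a.se)
        eg_a, eg_b = mr_egger(h)[0], mr_egger(neg)[0]
        assert eg_b.theta == pytest.approx(-eg_a.theta)
        assert eg_b.se == pytest.approx(eg_a.se)
        wm_a = weighted_median(h, n_boot=400, seed=7)
        wm_b = weighted_median(neg, n_boot=400, seed=7)
        assert wm_b.theta == pytest.approx(-wm_a.theta)

    @given(c=st.floats(0.1, 10.0))
    @settings(max_examples=20, deadline=None)
    def test_exposure_rescaling_divides_theta(self, c):
        rng = np.random.default_rng(3)
        h = random_instruments(rng, 5)
        scaled = [
            HarmonizedInstrument(
                rsid=x.rsid, effect_allele=x.effect_allele,
                other_allele=x.other_allele,
                beta_exposure=c * x.beta_exposure, se_exposure=c * x.se_exposure,
                beta_outcome=x.beta_outcome, se_outcome=x.se_outcome,
            )
            for x in h
        ]
        a = ivw_fixed([wald_ratio(x) for x in h])
        b = ivw_fixed([wald_ratio(x) for x in scaled])
        assert b.theta == pytest.approx(a.theta / c, rel=1e-9)
        ea, eb = mr_egger(h)[0], mr_egger(scaled)[0]
        assert eb.theta == pytest.approx(ea.theta / c, rel=1e-9)
        wa = weighted_median(h, n_boot=50, seed=1)
        wb = weighted_median(scaled, n_boot=50, seed=1)
        assert wb.theta == pytest.approx(wa.theta / c, rel=1e-9)
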