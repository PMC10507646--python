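"""Causal-effect estimators: worked examples, oracles and invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from summarymr import (
    DegenerateInstrumentError,
    EggerRegression,
    InsufficientSNPsError,
    IVWEstimator,
    WeightedMedianEstimator,
    estimate_to_or,
    ivw,
    mr_egger,
    p_from_or_ci,
    wald_ratio,
    weighted_median,
)
from summarymr.estimators import _interp_weighted_median

from conftest import make_pair, pairs_from_ratios


class TestWaldRatio:
    def test_first_order(self):
        pair = make_pair(bx=0.1, by=0.2, sy=0.05)
        assert wald_ratio(pair, "first") == (pytest.approx(2.0), pytest.approx(0.5))

    def test_negative_exposure_beta(self):
        pair = make_pair(bx=-0.1, by=0.2, sy=0.05)
        assert wald_ratio(pair, "first") == (pytest.approx(-2.0), pytest.approx(0.5))

    def test_second_order_delta_method(self):
        pair = make_pair(bx=0.1, by=0.2, sy=0.05, sx=0.02)
        theta, se = wald_ratio(pair, "second")
        assert theta == pytest.approx(2.0)
        assert se == pytest.approx(np.sqrt(0.25 + 0.16), rel=1e-6)

    def test_zero_exposure_beta_is_degenerate(self):
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(make_pair(bx=0.0))


class TestIVW:
    def test_worked_two_snp_example(self, worked_ivw_pairs):
        est = ivw(worked_ivw_pairs, model="fixed")
        assert est.beta == pytest.approx(1.2)
        assert est.se == pytest.approx(5**-0.5, rel=1e-9)

    def test_single_snp_equals_wald_ratio(self):
        pair = make_pair(bx=0.1, by=0.2, sy=0.05)
        est = ivw([pair], model="fixed")
        theta, se = wald_ratio(pair)
        assert est.beta == theta and est.se == se

    def test_random_effects_floor_under_homogeneity(self):
        pairs = pairs_from_ratios([1.5, 1.5, 1.5], [0.5, 0.7, 0.9])
        fixed, random = ivw(pairs, "fixed"), ivw(pairs, "random")
        assert random.beta == fixed.beta and random.se == fixed.se

    def test_random_effects_inflates_under_heterogeneity(self):
        pairs = pairs_from_ratios([0.0, 5.0, -3.0, 8.0], [0.2, 0.2, 0.2, 0.2])
        fixed, random = ivw(pairs, "fixed"), ivw(pairs, "random")
        assert random.beta == fixed.beta and random.se > fixed.se

    def test_random_requires_two_snps(self):
        with pytest.raises(InsufficientSNPsError, match="2"):
            ivw([make_pair()], model="random")

    def test_fixed_equals_weighted_origin_wls_oracle(self, rng):
        """IVW fixed is algebraically the weighted least-squares slope of
        beta_Y on beta_X through the origin with weights 1/se_Y^2."""
        import statsmodels.api as sm

        for _ in range(100):
            n = rng.integers(2, 30)
            bx = rng.normal(0.05, 0.02, n)
            bx[np.abs(bx) < 1e-4] = 0.05
            by = rng.normal(0.0, 0.05, n)
            sy = rng.uniform(0.005, 0.05, n)
            est = IVWEstimator(model="fixed").fit(bx[:, None], by, outcome_se=sy)
            wls = sm.WLS(by, bx[:, None], weights=1.0 / sy**2).fit()
            assert est.effect_ == pytest.approx(wls.params[0], rel=1e-10)


class TestEgger:
    def test_exact_line_through_origin(self):
        pairs = [
            make_pair(snp_id=f"rs{i}", bx=float(i), sx=0.01, by=float(i), sy=1.0)
            for i in (1, 2, 3)
        ]
        res = mr_egger(pairs)
        assert res.slope.beta == pytest.approx(1.0, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)

    def test_minimum_three_snps(self):
        pairs = pairs_from_ratios([1.0, 2.0], [0.5, 1.0])
        with pytest.raises(InsufficientSNPsError, match="3"):
            mr_egger(pairs)

    def test_matches_simple_regression_oracle(self):
        # Equal outcome SEs make weighted LS coincide with ordinary LS:
        # closed form slope = Sxy/Sxx = 1.5, intercept = ybar - slope*xbar.
        pts = [(1.0, 2.0), (2.0, 3.0), (3.0, 5.0)]
        pairs = [
            make_pair(snp_id=f"rs{i}", bx=x, sx=0.01, by=y, sy=1.0)
            for i, (x, y) in enumerate(pts)
        ]
        res = mr_egger(pairs)
        assert res.slope.beta == pytest.approx(1.5, rel=1e-9)
        assert res.intercept == pytest.approx(1.0 / 3.0, rel=1e-9)

    def test_collinear_exposure_betas_rejected(self):
        pairs = [
            make_pair(snp_id=f"rs{i}", bx=0.05, sx=0.01, by=y, sy=0.02)
            for i, y in enumerate((0.01, 0.02, 0.03))
        ]
        with pytest.raises(ValueError, match="collinear"):
            mr_egger(pairs)

    def test_orientation_makes_result_sign_convention_free(self):
        """Flipping the reported allele of individual SNPs (joint sign flip
        of beta_X and beta_Y) must not change the Egger slope."""
        rng = np.random.default_rng(5)
        bx = rng.normal(0.05, 0.01, 10)
        by = 0.4 * bx + rng.normal(0, 0.01, 10)
        sy = np.full(10, 0.01)
        pairs = [make_pair(snp_id=f"rs{i}", bx=bx[i], sx=0.005, by=by[i], sy=sy[i])
                 for i in range(10)]
        flip = [make_pair(snp_id=f"rs{i}", bx=-bx[i], sx=0.005, by=-by[i], sy=sy[i])
                for i in range(10)]
        a, b = mr_egger(pairs), mr_egger(flip)
        assert a.slope.beta == pytest.approx(b.slope.beta, rel=1e-12)
        assert a.intercept == pytest.approx(b.intercept, rel=1e-12)


class TestWeightedMedian:
    def test_equal_weights_odd_count_is_plain_median(self):
        pairs = pairs_from_ratios([1.0, 2.0, 3.0], [0.5, 0.5, 0.5])
        est = weighted_median(pairs, n_boot=10, seed=0)
        assert est.beta == pytest.approx(2.0)

    def test_midpoint_interpolation_rule(self):
        # Normalized weights (0.4, 0.6) give scores (0.2, 0.7); interpolating
        # to 0.5 lands at 1.6.
        theta = np.array([1.0, 2.0])
        w = np.array([0.4, 0.6])
        assert _interp_weighted_median(theta, w) == pytest.approx(1.6)

    def test_dominant_weight_pins_the_estimate(self):
        theta = np.array([1.0, 2.0, 3.0])
        w = np.array([0.2, 0.6, 0.2])
        assert _interp_weighted_median(theta, w) == pytest.approx(2.0)

    def test_minimum_three_snps(self):
        with pytest.raises(InsufficientSNPsError):
            weighted_median(pairs_from_ratios([1.0, 2.0], [0.5, 1.0]), n_boot=10, seed=0)

    def test_bootstrap_se_is_seeded(self, simulated_pairs):
        a = weighted_median(simulated_pairs, n_boot=200, seed=42)
        b = weighted_median(simulated_pairs, n_boot=200, seed=42)
        c = weighted_median(simulated_pairs, n_boot=200, seed=43)
        assert a.se == b.se
        assert a.se != c.se and a.beta == c.beta

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.lists(st.tuples(st.floats(-5, 5), st.floats(0.1, 2.0)), min_size=3, max_size=12))
    def test_estimate_lies_within_ratio_range(self, ratios):
        theta = [t for t, _ in ratios]
        sigma = [s for _, s in ratios]
        est = weighted_median(pairs_from_ratios(theta, sigma), n_boot=2, seed=0)
        assert min(theta) - 1e-9 <= est.beta <= max(theta) + 1e-9


class TestJointSignEquivariance:
    @pytest.mark.parametrize("fit", [
        lambda p: ivw(p, "fixed").beta,
        lambda p: ivw(p, "random").beta,
        lambda p: mr_egger(p).slope.beta,
        lambda p: weighted_median(p, n_boot=5, seed=0).beta,
    ], ids=["ivw_fixed", "ivw_random", "egger", "weighted_median"])
    def test_jointly_negating_all_pairs_preserves_estimate(self, fit, simulated_pairs):
        negated = [
            make_pair(snp_id=p.snp_id, bx=-p.beta_exposure, sx=p.se_exposure,
                      by=-p.beta_outcome, sy=p.se_outcome)
            for p in simulated_pairs
        ]
        assert fit(negated) == pytest.approx(fit(simulated_pairs), rel=1e-9)


class TestORConversion:
    def test_null_beta_gives_unit_or(self):
        or_value, lo, hi, p = estimate_to_or(0.0, 0.1)
        assert or_value == 1.0 and p == 1.0
        assert lo * hi == pytest.approx(1.0, rel=1e-9)  # symmetric about 1

    def test_worked_or_ci(self):
        or_value, lo, hi, _ = estimate_to_or(0.6931, 0.1)
        assert or_value == pytest.approx(2.000, abs=5e-4)
        assert lo == pytest.approx(1.644, abs=5e-4)
        assert hi == pytest.approx(2.433, abs=5e-4)

    def test_zero_se_conventions(self):
        or_value, lo, hi, p = estimate_to_or(0.5, 0.0)
        assert lo == or_value == hi and p == 0.0
        assert estimate_to_or(0.0, 0.0)[3] == 1.0

    def test_reported_triple_reproduces_reported_p(self):
        # A published strongly significant association: OR 2.578 (1.611-4.127),
        # p = 7.920e-5; inverting the CI reproduces the p-value.
        beta = np.log(2.578)
        se = (np.log(4.127) - np.log(1.611)) / (2 * 1.959964)
        _, _, _, p = estimate_to_or(beta, se)
        assert p == pytest.approx(7.920e-5, rel=0.05)


class TestPFromORCI:
    @pytest.mark.parametrize("triple, expected", [
        ((2.015, 1.082, 3.753), 0.027),
        ((1.426, 1.133, 1.795), 2.469e-3),
    ])
    def test_published_triples(self, triple, expected):
        assert p_from_or_ci(*triple) == pytest.approx(expected, rel=0.05)

    def test_null_or_gives_p_one(self):
        assert p_from_or_ci(1.0, 1 / 1.2, 1.2) == pytest.approx(1.0)

    def test_ordering_violation_rejected(self):
        with pytest.raises(ValueError):
            p_from_or_ci(2.0, 1.0, 1.5)


class TestSklearnInterface:
    def test_get_set_params_round_trip(self):
        est = IVWEstimator(model="random")
        params = est.get_params()
        assert params["model"] == "random"
        est.set_params(model="fixed")
        assert est.model == "fixed"

    def test_fitted_attributes_and_predict(self, simulated_pairs):
        bx = np.array([p.beta_exposure for p in simulated_pairs])
        by = np.array([p.beta_outcome for p in simulated_pairs])
        sy = np.array([p.se_outcome for p in simulated_pairs])
        est = IVWEstimator().fit(bx[:, None], by, outcome_se=sy)
        assert est.nsnp_ == len(bx)
        pred = est.predict(bx[:, None])
        assert pred == pytest.approx(est.effect_ * bx)
        egger = EggerRegression().fit(bx[:, None], by, outcome_se=sy)
        assert egger.predict(bx[:2, None]) == pytest.approx(
            egger.intercept_ + egger.effect_ * bx[:2]
        )

    def test_missing_outcome_se_is_error(self):
        with pytest.raises(ValueError, match="outcome_se"):
            IVWEstimator().fit([[0.1]], [0.05])

    def test_weighted_median_estimator_class(self, simulated_pairs):
        bx = np.array([p.beta_exposure for p in simulated_pairs])
        by = np.array([p.beta_outcome for p in simulated_pairs])
        sy = np.array([p.se_outcome for p in simulated_pairs])
        est = WeightedMedianEstimator(n_boot=100, random_state=0).fit(
            bx[:, None], by, outcome_se=sy
        )
        assert 0.3 < est.effect_ < 0.7  # recovers the simulated effect of 0.5
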