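import math

import numpy as np
import pytest
from scipy import stats

from hypothesis import given, settings
from hypothesis import strategies as st

from hydrovigor import (
    NEVER,
    GerminationTimeCourse,
    HydrotimeParams,
    ThetaSearchConfig,
    build_probit_points,
    fit_hydrotime,
    goodness_of_fit,
    predict_fraction,
    predicted_max_germination,
    probit_regression_at_theta,
    simulate_time_course,
    time_to_fraction,
)
from hydrovigor.errors import (
    FitFailureError,
    IdentifiabilityError,
    InsufficientDataError,
    UndefinedStatisticError,
)
from hydrovigor.hydrotime_fit import ProbitPoint

LOT12 = HydrotimeParams(theta_H=8.799, psi_b50=-0.522, sigma_phib=0.299)
LOT2 = HydrotimeParams(theta_H=14.770, psi_b50=-0.278, sigma_phib=0.276)

params_strategy = st.builds(
    HydrotimeParams,
    theta_H=st.floats(1.0, 100.0),
    psi_b50=st.floats(-1.5, -0.05),
    sigma_phib=st.floats(0.05, 0.8),
)


def tc(psi, times, counts, n=30):
    return GerminationTimeCourse(
        lot_id="x", psi=psi, replicate="r1", n_sown=n,
        times_h=np.asarray(times, float), cum_germinated=np.asarray(counts, float),
    )


class TestProbitPoints:
    def test_median_fraction_maps_to_zero_probit(self):
        course = tc(-0.2, [10.0, 20.0, 30.0], [3.0, 15.0, 20.0])
        points = build_probit_points([course, tc(0.0, [10.0, 20.0], [5.0, 20.0])], 10.0)
        p = next(pt for pt in points if pt.fraction == 0.5)
        assert p.predictor_x == pytest.approx(-0.2 - 10.0 / 20.0)
        assert p.probit_g == pytest.approx(0.0)

    def test_all_zero_fractions_is_insufficient_data(self):
        courses = [tc(p, [8.0, 16.0, 24.0], [0, 0, 0]) for p in (0.0, -0.4)]
        with pytest.raises(InsufficientDataError):
            build_probit_points(courses, 10.0)

    def test_single_water_potential_is_unidentifiable(self):
        courses = [tc(-0.2, [8.0, 16.0, 24.0, 48.0], [1, 5, 9, 12])]
        with pytest.raises(IdentifiabilityError):
            build_probit_points(courses, 10.0)

    def test_replicates_pool_by_summed_counts(self):
        a = tc(-0.2, [24.0], [10.0], n=30)
        b = tc(-0.2, [24.0], [20.0], n=30)
        other = tc(0.0, [24.0, 48.0], [15.0, 25.0], n=30)
        points = build_probit_points([a, b, other], 10.0)
        pooled = next(p for p in points if p.psi == -0.2)
        assert pooled.fraction == pytest.approx(0.5)  # (10+20)/60

    def test_noiseless_panel_is_exactly_collinear_at_true_theta(self):
        courses = [
            simulate_time_course(LOT12, psi, 90, noise_mode="noiseless", fractional=True)
            for psi in (0.0, -0.2, -0.4, -0.6, -0.8)
        ]
        points = build_probit_points(courses, LOT12.theta_H)
        x = np.array([p.predictor_x for p in points])
        z = np.array([p.probit_g for p in points])
        np.testing.assert_allclose(
            z, (x - LOT12.psi_b50) / LOT12.sigma_phib, atol=1e-8
        )


class TestProbitRegression:
    def make_points(self, x, z):
        return [
            ProbitPoint(psi=0.0, time_h=1.0, fraction=0.5, predictor_x=xi, probit_g=zi)
            for xi, zi in zip(x, z)
        ]

    def test_exact_line_inverts_to_parameters(self):
        x = np.array([-0.8, -0.5, -0.2, 0.0])
        z = (x + 0.522) / 0.299
        psi_b50, sigma, r2 = probit_regression_at_theta(self.make_points(x, z))
        assert psi_b50 == pytest.approx(-0.522)
        assert sigma == pytest.approx(0.299)
        assert r2 == pytest.approx(1.0)

    def test_negative_slope_is_fit_failure(self):
        x = np.array([-0.5, -0.2, 0.0])
        with pytest.raises(FitFailureError):
            probit_regression_at_theta(self.make_points(x, -2.0 * x))

    def test_zero_predictor_variance_is_error(self):
        with pytest.raises(IdentifiabilityError):
            probit_regression_at_theta(
                self.make_points([0.1, 0.1, 0.1], [0.0, 0.5, 1.0])
            )

    def test_wrong_theta_scores_below_perfect(self):
        courses = [
            simulate_time_course(LOT12, psi, 90, noise_mode="noiseless", fractional=True)
            for psi in (0.0, -0.2, -0.4, -0.6, -0.8)
        ]
        _, _, r2_true = probit_regression_at_theta(
            build_probit_points(courses, LOT12.theta_H)
        )
        _, _, r2_wrong = probit_regression_at_theta(
            build_probit_points(courses, 2.0 * LOT12.theta_H)
        )
        assert r2_true == pytest.approx(1.0, abs=1e-12)
        assert r2_wrong < r2_true


class TestFit:
    @pytest.mark.parametrize(
        "truth, tol_theta, tol_psi, tol_sigma",
        [(LOT12, 0.05, 0.005, 0.005), (LOT2, 0.05, 0.005, 0.005)],
        ids=["lot12", "lot2"],
    )
    def test_noiseless_panel_recovers_generating_parameters(
        self, truth, tol_theta, tol_psi, tol_sigma, noiseless_panel_factory
    ):
        fit = fit_hydrotime(noiseless_panel_factory(truth))
        assert fit.theta_H == pytest.approx(truth.theta_H, abs=tol_theta)
        assert fit.psi_b50 == pytest.approx(truth.psi_b50, abs=tol_psi)
        assert fit.sigma_phib == pytest.approx(truth.sigma_phib, abs=tol_sigma)
        assert fit.r2 == pytest.approx(1.0, abs=1e-6)

    def test_single_water_potential_panel_unidentifiable(self):
        course = simulate_time_course(LOT12, -0.2, 90, noise_mode="noiseless",
                                      fractional=True)
        with pytest.raises(IdentifiabilityError):
            fit_hydrotime([course])

    def test_profile_attains_unity_only_near_true_theta(self, noiseless_panel_factory):
        """r2(theta) profile peaks at the generating theta within search tol."""
        courses = noiseless_panel_factory(LOT12)
        fit = fit_hydrotime(courses, ThetaSearchConfig(tol=1e-4))
        assert abs(fit.theta_H - LOT12.theta_H) <= 1e-3


class TestPredict:
    def test_median_seed_germinates_at_theta_over_excess(self):
        t50 = LOT12.theta_H / (0.0 - LOT12.psi_b50)
        assert predict_fraction(LOT12, 0.0, t50) == pytest.approx(0.5)

    def test_at_psi_b50_fraction_stays_below_half(self):
        assert predict_fraction(LOT12, LOT12.psi_b50, 1e6) < 0.5
        assert predict_fraction(LOT12, LOT12.psi_b50, 1e12) == pytest.approx(0.5, abs=1e-3)

    def test_long_run_fraction_matches_normal_cdf_oracle(self):
        expected = stats.norm.cdf(0.522 / 0.299)
        assert predict_fraction(LOT12, 0.0, 1e12) == pytest.approx(expected, abs=1e-4)
        assert expected == pytest.approx(0.9596, abs=5e-4)

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            predict_fraction(LOT12, 0.0, 0.0)

    @pytest.mark.parametrize(
        "params, psi, expected",
        [
            (LOT12, LOT12.psi_b50, 0.5),
            (LOT2, -0.8, stats.norm.cdf((-0.8 + 0.278) / 0.276)),
            (LOT12, LOT12.psi_b50 + 3 * LOT12.sigma_phib, stats.norm.cdf(3.0)),
        ],
    )
    def test_predicted_max_germination(self, params, psi, expected):
        assert predicted_max_germination(params, psi) == pytest.approx(expected)

    def test_lot2_near_zero_germination_at_low_psi(self):
        # consistent with the near-zero observed germination at -0.8 MPa
        assert predicted_max_germination(LOT2, -0.8) == pytest.approx(0.029, abs=0.001)


class TestTimeToFraction:
    def test_median_time_from_division(self):
        assert time_to_fraction(LOT12, 0.0, 0.5) == pytest.approx(8.799 / 0.522, abs=0.01)

    def test_subthreshold_fraction_returns_never_sentinel(self):
        g_high = 0.99  # psi_b(0.99) > -0.2 for lot 12
        assert time_to_fraction(LOT12, -0.2, g_high) is NEVER or math.isinf(
            time_to_fraction(LOT12, -0.2, g_high)
        )

    @pytest.mark.parametrize("g", [0.0, 1.0, -0.1, 1.5])
    def test_fraction_outside_open_interval_rejected(self, g):
        with pytest.raises(ValueError):
            time_to_fraction(LOT12, 0.0, g)


class TestGoodnessOfFit:
    def test_noiseless_self_data_scores_one(self, noiseless_panel_factory):
        courses = noiseless_panel_factory(LOT12)
        assert goodness_of_fit(LOT12, courses) == pytest.approx(1.0, abs=1e-12)

    def test_perturbed_psi_b50_scores_strictly_lower(self, noiseless_panel_factory):
        courses = noiseless_panel_factory(LOT12)
        perturbed = HydrotimeParams(
            theta_H=LOT12.theta_H,
            psi_b50=LOT12.psi_b50 + 0.2,
            sigma_phib=LOT12.sigma_phib,
        )
        assert goodness_of_fit(perturbed, courses) < goodness_of_fit(LOT12, courses)

    def test_constant_observed_fractions_undefined(self):
        courses = [tc(p, [8.0, 16.0], [3.0, 3.0]) for p in (0.0, -0.2)]
        with pytest.raises(UndefinedStatisticError):
            goodness_of_fit(LOT12, courses)


@given(params=params_strategy, psi=st.floats(-1.0, 0.0),
       t1=st.floats(1.0, 500.0), t2=st.floats(1.0, 500.0))
@settings(deadline=None, max_examples=200)
def test_predict_fraction_monotone_in_time_and_psi(params, psi, t1, t2):
    lo, hi = sorted((t1, t2))
    assert predict_fraction(params, psi, lo) <= predict_fraction(params, psi, hi)
    assert predict_fraction(params, psi, hi) <= predict_fraction(params, 0.0, hi)


@given(params=params_strategy, psi=st.floats(-1.0, 0.0), g=st.floats(0.01, 0.99))
@settings(deadline=None, max_examples=200)
def test_time_to_fraction_inverts_predict_fraction(params, psi, g):
    t = time_to_fraction(params, psi, g)
    if math.isinf(t):
        return
    assert predict_fraction(params, psi, t) == pytest.approx(g, abs=1e-9)
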