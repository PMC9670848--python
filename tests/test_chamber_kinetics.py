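"""Unit and property tests for the relative-rate kinetics machinery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from semifate.chamber_kinetics import (
    DecaySeries,
    DegenerateFitError,
    RateConstant,
    ReferenceCompound,
    RelativeRateFit,
    corrected_log_loss,
    fit_first_order_loss,
    ratio_to_rate_constant,
    reference_consistency_check,
    relative_rate_fit,
    weighted_average,
)
from semifate.synthetic_data import ChamberRecipe, generate_chamber_pair


def make_series(k, n=16, dt=60.0, c0=5e13, label="x"):
    t = np.arange(n) * dt
    return DecaySeries(label, t, c0 * np.exp(-k * t))


class TestDecaySeries:
    def test_validation(self):
        with pytest.raises(ValueError):
            DecaySeries("x", [0, 60], [1e13, 1e13])  # too few points
        with pytest.raises(ValueError):
            DecaySeries("x", [0, 60, 30], [1e13] * 3)  # not increasing
        with pytest.raises(ValueError):
            DecaySeries("x", [0, 60, 120], [1e13, 0.0, 1e13])  # non-positive

    def test_log_depletion_starts_at_zero(self, exp_series):
        assert exp_series.log_depletion()[0] == 0.0


class TestFirstOrderLossFit:
    def test_constant_series_gives_zero_rate(self):
        s = DecaySeries("flat", np.arange(5) * 60.0, np.full(5, 4e13))
        fit = fit_first_order_loss(s)
        assert fit.k_loss == 0.0

    def test_noise_free_exponential_recovered_exactly(self, exp_series):
        fit = fit_first_order_loss(exp_series)
        assert fit.k_loss == pytest.approx(5e-4, rel=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.sigma_k == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_wall_loss_recovery_with_noise(self):
        # synthetic run at the measured wall-loss constant, 2% noise, 30 pts
        k_wl = 3.1e-4
        rng = np.random.default_rng(7)
        t = np.arange(30) * 60.0
        sigma = np.sqrt(np.log1p(0.02**2))
        noise = rng.lognormal(-0.5 * sigma**2, sigma, 30)
        s = DecaySeries("wl", t, 5e13 * np.exp(-k_wl * t) * noise)
        fit = fit_first_order_loss(s)
        assert abs(fit.k_loss - k_wl) <= 2 * fit.sigma_k
        assert fit.sigma_k > 0


class TestCorrectedLogLoss:
    def test_zero_correction_is_identity(self, exp_series):
        out = corrected_log_loss(exp_series, 0.0)
        np.testing.assert_allclose(out[:, 1], exp_series.log_depletion())

    def test_exact_cancellation_of_pure_wall_loss(self):
        k_wl = 3.1e-4
        s = make_series(k_wl)
        out = corrected_log_loss(s, k_wl)
        np.testing.assert_allclose(out[:, 1], 0.0, atol=1e-12)

    def test_residual_slope_after_partial_correction(self):
        # combined OH-equivalent + wall loss; subtracting wall loss leaves OH
        s = make_series(2e-4 + 3.1e-4)
        out = corrected_log_loss(s, 3.1e-4)
        slope = np.polyfit(out[:, 0], out[:, 1], 1)[0]
        assert slope == pytest.approx(2e-4, rel=1e-10)

    def test_negative_correction_rejected(self, exp_series):
        with pytest.raises(ValueError):
            corrected_log_loss(exp_series, -1e-5)


class TestRelativeRateFit:
    def test_self_comparison_gives_unit_slope(self, exp_series):
        fit = relative_rate_fit(exp_series, exp_series)
        assert fit.slope == pytest.approx(1.0, rel=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)

    def test_noise_free_pair_recovers_ratio_exactly(self):
        target, ref = generate_chamber_pair(
            ChamberRecipe(true_ratio=1.55, noise_cv=0.0)
        )
        fit = relative_rate_fit(target, ref, k_wl_target=3.1e-4)
        assert fit.slope == pytest.approx(1.55, rel=1e-10)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)

    def test_noisy_pair_recovers_ratio_within_2_sigma(self):
        r = ChamberRecipe(
            true_ratio=0.45, k_ref_oh=6.38e-12, duration=1440.0, seed=42
        )
        target, ref = generate_chamber_pair(r)
        fit = relative_rate_fit(target, ref, k_wl_target=3.1e-4)
        assert fit.n_points == 25
        assert abs(fit.slope - 0.45) <= 2 * fit.sigma_slope

    def test_slope_invariant_to_oh_history(self):
        # same true ratio, constant vs strongly ramped OH: identical slope
        common = dict(true_ratio=1.55, noise_cv=0.0, k_wl_target=0.0)
        f1 = relative_rate_fit(
            *generate_chamber_pair(ChamberRecipe(oh_profile=2e8, **common))
        )
        ramp = np.linspace(0.5e8, 4e8, 30)
        f2 = relative_rate_fit(
            *generate_chamber_pair(ChamberRecipe(oh_profile=ramp, **common))
        )
        assert f1.slope == pytest.approx(f2.slope, rel=1e-10)

    def test_disjoint_time_grids_rejected(self, exp_series):
        other = DecaySeries(
            "y", exp_series.times + 7.0, exp_series.concentrations
        )
        with pytest.raises(ValueError, match="common"):
            relative_rate_fit(exp_series, other)

    def test_non_decaying_reference_is_degenerate(self, exp_series):
        flat = DecaySeries(
            "flat", exp_series.times, np.full(exp_series.times.size, 3e13)
        )
        with pytest.raises(DegenerateFitError):
            relative_rate_fit(exp_series, flat)


class TestRatioToRateConstant:
    def test_cyhex_determination(self):
        # ratio 0.81 +- 0.07 against cyclohexane
        fit = RelativeRateFit(0.81, 0.07, 0.0, 1.0)
        k = ratio_to_rate_constant(fit, ReferenceCompound("CyHex", 6.38e-12))
        assert k.value == pytest.approx(5.17e-12, abs=0.005e-12)
        assert k.sigma == pytest.approx(0.68e-12, abs=0.005e-12)

    def test_identity_with_exact_reference(self):
        fit = RelativeRateFit(1.0, 0.0, 0.0, 1.0)
        k = ratio_to_rate_constant(fit, ReferenceCompound("r", 1e-12, rel_unc=0.0))
        assert k.value == 1e-12
        assert k.sigma == 0.0

    def test_quadrature_propagation(self):
        fit = RelativeRateFit(2.0, 0.2, 0.0, 1.0)
        k = ratio_to_rate_constant(fit, ReferenceCompound("r", 1e-12))
        assert k.value == pytest.approx(2e-12)
        assert k.sigma == pytest.approx(2e-12 * np.sqrt(0.02), rel=1e-12)

    def test_non_positive_slope_rejected(self):
        fit = RelativeRateFit(-0.1, 0.05, 0.0, 1.0)
        with pytest.raises(ValueError):
            ratio_to_rate_constant(fit, ReferenceCompound("r", 1e-12))

    @given(
        slope=st.floats(0.1, 10),
        sigma=st.floats(0.0, 1.0),
        rel_unc=st.floats(0.01, 0.5),
    )
    def test_relative_uncertainty_floor(self, slope, sigma, rel_unc):
        # the reference's own uncertainty is an irreducible floor
        fit = RelativeRateFit(slope, sigma, 0.0, 1.0)
        k = ratio_to_rate_constant(fit, ReferenceCompound("r", 1e-12, rel_unc))
        assert k.sigma / k.value >= rel_unc * (1 - 1e-12)


class TestWeightedAverage:
    def test_three_determination_mean(self):
        vals = [
            RateConstant(4.40e-12, 0.53e-12, "cm^3 molecule^-1 s^-1"),
            RateConstant(5.17e-12, 0.70e-12, "cm^3 molecule^-1 s^-1"),
            RateConstant(4.63e-12, 0.71e-12, "cm^3 molecule^-1 s^-1"),
        ]
        avg = weighted_average(vals)
        assert avg.value == pytest.approx(4.67e-12, rel=0.01)
        assert avg.sigma == pytest.approx(0.36e-12, rel=0.01)

    def test_single_value_unchanged(self):
        v = RateConstant(3e-12, 0.3e-12, "cm^3 molecule^-1 s^-1")
        avg = weighted_average([v])
        assert avg.value == v.value
        assert avg.sigma == pytest.approx(v.sigma)

    def test_duplicate_halves_variance(self):
        v = RateConstant(3e-12, 0.3e-12, "cm^3 molecule^-1 s^-1")
        avg = weighted_average([v, v])
        assert avg.value == pytest.approx(v.value)
        assert avg.sigma == pytest.approx(v.sigma / np.sqrt(2))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            weighted_average([])
        with pytest.raises(ValueError, match="mixed units"):
            weighted_average(
                [
                    RateConstant(1e-12, 1e-13, "cm^3 molecule^-1 s^-1"),
                    RateConstant(0.4, 0.04, "day^-1"),
                ]
            )
        with pytest.raises(ValueError):
            weighted_average([RateConstant(1e-12, 0.0, "s^-1")])

    @given(
        st.lists(
            st.tuples(st.floats(0.1, 10), st.floats(0.01, 2.0)),
            min_size=1,
            max_size=8,
        )
    )
    def test_mean_bounded_and_sigma_shrinks(self, entries):
        vals = [RateConstant(v, s, "day^-1") for v, s in entries]
        avg = weighted_average(vals)
        assert min(v.value for v in vals) <= avg.value <= max(v.value for v in vals)
        assert avg.sigma <= min(v.sigma for v in vals) + 1e-15


class TestRateConstantUnits:
    def test_day_second_round_trip_uses_86400(self):
        k = RateConstant(5.311e-6, 1e-7, "s^-1")
        per_day = k.to("day^-1")
        assert per_day.value == pytest.approx(5.311e-6 * 86400, rel=1e-15)
        back = per_day.to("s^-1")
        assert back.value == pytest.approx(k.value, rel=1e-15)

    def test_second_order_units_not_convertible(self):
        k = RateConstant(4.7e-12, 0.0, "cm^3 molecule^-1 s^-1")
        with pytest.raises(ValueError):
            k.to("day^-1")


class TestReferenceConsistency:
    def test_literature_ratio_cyhex_over_dme(self):
        chk = reference_consistency_check(
            RelativeRateFit(1.95, 0.23, 0.0, 1.0),
            ReferenceCompound("CyHex", 6.38e-12),
            ReferenceCompound("DME", 2.83e-12),
        )
        assert chk.literature_ratio == pytest.approx(2.25, abs=0.005)
        assert chk.relative_deviation == pytest.approx(0.135, abs=0.005)
        assert chk.relative_deviation < 0.15  # "within 15%" acceptance

    def test_exact_agreement_has_zero_deviation(self):
        a = ReferenceCompound("a", 4.0e-12)
        b = ReferenceCompound("b", 2.0e-12)
        chk = reference_consistency_check(RelativeRateFit(2.0, 0.1, 0.0, 1.0), a, b)
        assert chk.relative_deviation == 0.0
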