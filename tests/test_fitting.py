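"""Dose-response, growth-rate and calibration fitting."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import sulfostat as ss
from sulfostat import (
    DoseResponse,
    GradientPlate,
    GrowthCurveSet,
    NoiseModel,
    StrainParams,
    dose_response_from_growth_rates,
    estimate_growth_rate,
    fit_dose_response,
    fit_sulfide_calibration,
    gen_growth_curves,
    gen_plate_gradient,
    ic50_fold_change,
    inhibition_fraction,
    normalize_to_control,
    sulfide_from_srm,
)

TWOFOLD = np.append(500.0 / 2.0 ** np.arange(12), 0.0)


class TestGradientPlate:
    def test_control_required(self):
        with pytest.raises(ValueError):
            GradientPlate((10.0, 5.0), (0.5, 0.8))

    def test_non_twofold_grid_warns(self):
        with pytest.warns(UserWarning, match="two-fold"):
            GradientPlate((0.0, 10.0, 7.0, 3.0), (1.0, 0.5, 0.6, 0.8))

    def test_twofold_grid_accepted_silently(self, community):
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            gen_plate_gradient(community)


class TestNormalizeToControl:
    def test_uniform_plate_maps_to_one(self):
        plate = GradientPlate((0.0, 10.0, 20.0, 40.0), (2.0, 2.0, 2.0, 2.0))
        norm = normalize_to_control(plate)
        np.testing.assert_allclose(norm["response"], 1.0)

    def test_half_of_control_maps_to_half(self):
        plate = GradientPlate((0.0, 10.0), (2.0, 1.0))
        norm = normalize_to_control(plate)
        assert norm.loc[norm["concentration_mM"] == 10.0, "response"].iloc[0] == 0.5

    def test_noise_free_plate_recovers_inhibition_curve(self, community):
        plate = gen_plate_gradient(community, control_signal=3.7)
        norm = normalize_to_control(plate)
        nz = norm[norm["concentration_mM"] > 0]
        np.testing.assert_allclose(
            nz["response"],
            inhibition_fraction(nz["concentration_mM"].to_numpy(), community),
            rtol=1e-12,
        )

    def test_zero_control_rejected(self):
        plate = GradientPlate((0.0, 10.0), (0.0, 1.0))
        with pytest.raises(ValueError):
            normalize_to_control(plate)


class TestDoseResponseFit:
    @pytest.mark.parametrize("preset", ["community", "bmsr"])
    def test_noise_free_self_recovery(self, preset):
        strain = ss.get_strain_preset(preset)
        resp = inhibition_fraction(TWOFOLD, strain)
        res = fit_dose_response(TWOFOLD, resp)
        assert res.log_ic50 == pytest.approx(strain.log_ic50, abs=1e-6)
        assert res.hill_slope == pytest.approx(strain.hill_slope, abs=1e-6)
        assert res.n_points == 12
        assert res.source == "endpoint"

    @settings(max_examples=25)
    @given(
        log_ic50=st.floats(np.log10(1e-3), np.log10(0.2)),  # IC50 in [1, 200] mM
        hill=st.floats(-4.0, -0.5),
    )
    def test_self_recovery_over_random_strains(self, log_ic50, hill):
        strain = StrainParams("rand", mu_max=0.1, log_ic50=log_ic50,
                              hill_slope=hill)
        resp = inhibition_fraction(TWOFOLD, strain)
        res = fit_dose_response(TWOFOLD, resp)
        assert res.log_ic50 == pytest.approx(log_ic50, abs=1e-4)
        assert res.hill_slope == pytest.approx(hill, abs=1e-4)

    def test_unit_shift_moves_log_ic50_exactly(self, community):
        resp = inhibition_fraction(TWOFOLD, community)
        base = fit_dose_response(TWOFOLD, resp)
        shifted = fit_dose_response(TWOFOLD * 10.0, resp)
        assert shifted.log_ic50 - base.log_ic50 == pytest.approx(1.0, abs=1e-6)
        assert shifted.hill_slope == pytest.approx(base.hill_slope, abs=1e-6)

    def test_requires_four_nonzero_concentrations(self):
        with pytest.raises(ValueError):
            fit_dose_response([0.0, 10.0, 20.0, 40.0], [1.0, 0.8, 0.5, 0.2])

    def test_rejects_unnormalized_responses(self):
        with pytest.raises(ValueError):
            fit_dose_response([5.0, 10.0, 20.0, 40.0], [900.0, 700.0, 400.0, 100.0])

    def test_confidence_interval_brackets_estimate(self, community):
        plate = gen_plate_gradient(community, noise=NoiseModel(sd=0.05, seed=3),
                                   replicates=3)
        res = DoseResponse.from_plate(plate).fit()
        lo, hi = res.log_ic50_ci
        assert lo <= res.log_ic50 <= hi

    def test_bootstrap_ci_available(self, community):
        plate = gen_plate_gradient(community, noise=NoiseModel(sd=0.05, seed=3),
                                   replicates=3)
        res = DoseResponse.from_plate(plate).fit(ci_method="bootstrap",
                                                 n_boot=100, seed=0)
        lo, hi = res.log_ic50_ci
        assert lo < hi
        assert abs(res.log_ic50 - community.log_ic50) < 0.2

    def test_summary_mentions_both_parameters(self, community):
        resp = inhibition_fraction(TWOFOLD, community)
        text = fit_dose_response(TWOFOLD, resp).summary()
        assert "LogIC50" in text and "HillSlope" in text and "IC50" in text

    def test_noisy_recovery_envelope(self, community):
        errs = []
        for seed in range(30):
            plate = gen_plate_gradient(
                community, noise=NoiseModel(sd=0.05, seed=seed), replicates=3
            )
            norm = normalize_to_control(plate)
            res = fit_dose_response(
                norm["concentration_mM"], np.clip(norm["response"], -0.1, 1.2)
            )
            errs.append(abs(res.log_ic50 - community.log_ic50))
        assert np.median(errs) < 0.05


class TestGrowthRateEstimation:
    def test_pure_exponential_recovers_rate(self):
        t = np.arange(0.0, 24.0, 2.0)
        df = pd.DataFrame(
            {"time_h": t, "perchlorate_mM": 0.0, "replicate": 1,
             "measurement": 0.01 * np.exp(0.13 * t)}
        )
        rates = estimate_growth_rate(GrowthCurveSet(df))
        assert rates["rate_per_h"].iloc[0] == pytest.approx(0.13, abs=1e-9)
        assert not rates["flagged"].iloc[0]

    def test_logistic_early_window_recovers_intrinsic_rate(self, bmsr):
        curves = gen_growth_curves(bmsr, [0.0], duration_h=48.0, dt_h=2.0,
                                   replicates=3, n0=0.005)
        rates = estimate_growth_rate(curves)
        assert rates["rate_per_h"].iloc[0] == pytest.approx(0.2, abs=0.01)

    def test_flat_curve_is_flagged(self):
        t = np.arange(0.0, 24.0, 2.0)
        df = pd.DataFrame(
            {"time_h": t, "perchlorate_mM": 0.0, "replicate": 1,
             "measurement": np.full(t.size, 0.5)}
        )
        with pytest.warns(UserWarning):
            rates = estimate_growth_rate(GrowthCurveSet(df))
        assert rates["flagged"].iloc[0]
        assert rates["rate_per_h"].iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_curve_needs_four_points(self):
        df = pd.DataFrame(
            {"time_h": [0.0, 2.0, 4.0], "perchlorate_mM": 0.0,
             "replicate": 1, "measurement": [0.1, 0.2, 0.4]}
        )
        with pytest.raises(ValueError):
            GrowthCurveSet(df)


class TestGrowthRateDoseResponse:
    def test_exact_rates_recover_strain_constants(self, community):
        levels = TWOFOLD[TWOFOLD > 0]
        rates = {p: 0.13 * inhibition_fraction(p, community) for p in levels}
        rates[0.0] = 0.13
        res = dose_response_from_growth_rates(rates)
        assert res.log_ic50 == pytest.approx(community.log_ic50, abs=1e-6)
        assert res.hill_slope == pytest.approx(community.hill_slope, abs=1e-6)
        assert res.source == "growth_rate"

    def test_duplicate_control_rates_averaged(self, community):
        df = pd.DataFrame(
            {
                "perchlorate_mM": [0.0, 0.0, 5.0, 10.0, 20.0, 40.0],
                "rate_per_h": [0.12, 0.14]
                + [0.13 * inhibition_fraction(p, community)
                   for p in (5.0, 10.0, 20.0, 40.0)],
            }
        )
        res = dose_response_from_growth_rates(df)
        assert abs(res.log_ic50 - community.log_ic50) < 0.02

    def test_control_rate_required(self, community):
        with pytest.raises(ValueError):
            dose_response_from_growth_rates(
                {p: 0.1 for p in (5.0, 10.0, 20.0, 40.0)}
            )

    def test_full_pipeline_from_noisy_curves(self, community):
        levels = np.append(500.0 / 2.0 ** np.arange(10), 0.0)
        curves = gen_growth_curves(
            community, levels, duration_h=48.0, dt_h=2.0, replicates=3,
            n0=0.005, noise=NoiseModel(kind="additive-gaussian", sd=0.002,
                                       seed=7),
        )
        rates = estimate_growth_rate(curves)
        res = dose_response_from_growth_rates(rates)
        assert abs(res.log_ic50 - community.log_ic50) < 0.1


class TestSulfideCalibrationFit:
    def test_exact_self_recovery(self, calib):
        srm = np.array([0.5, 1.0, 5.0, 10.0, 20.0, 40.0])
        s = sulfide_from_srm(srm, calib)
        fit = fit_sulfide_calibration(srm, s)
        assert fit.slope == pytest.approx(0.6786, abs=1e-10)
        assert fit.intercept == pytest.approx(-0.7375, abs=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.fit_on == "all_points"

    def test_two_points_insufficient(self):
        with pytest.raises(ValueError):
            fit_sulfide_calibration([1.0, 10.0], [0.2, 1.0])

    def test_non_positive_values_rejected(self):
        with pytest.raises(ValueError):
            fit_sulfide_calibration([0.0, 1.0, 10.0], [0.1, 0.2, 1.0])

    def test_replicate_means_mode_recorded(self, calib):
        srm = np.array([1.0, 1.0, 10.0, 10.0, 30.0, 30.0])
        s = sulfide_from_srm(srm, calib) * np.array([0.9, 1.1, 0.9, 1.1, 0.9, 1.1])
        fit = fit_sulfide_calibration(srm, s, on_means=True)
        assert fit.fit_on == "replicate_means"
        assert fit.n_points == 3

    def test_r_squared_is_log_space_sse_ratio(self, calib):
        rng = np.random.default_rng(11)
        srm = 10.0 ** rng.uniform(-0.3, 1.6, 40)
        s = sulfide_from_srm(srm, calib) * 10.0 ** rng.normal(0.0, 0.19, 40)
        fit = fit_sulfide_calibration(srm, s)
        ly = np.log10(s)
        pred = fit.slope * np.log10(srm) + fit.intercept
        sse = np.sum((ly - pred) ** 2)
        sst = np.sum((ly - ly.mean()) ** 2)
        assert fit.r_squared == pytest.approx(1.0 - sse / sst, abs=1e-12)

    def test_noisy_slope_recovery_at_published_scatter(self, calib):
        # log-space noise chosen to give R^2 near the published 0.79
        errs, r2s = [], []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            srm = 10.0 ** rng.uniform(-0.3, 1.6, 30)
            s = sulfide_from_srm(srm, calib) * 10.0 ** rng.normal(0.0, 0.19, 30)
            fit = fit_sulfide_calibration(srm, s)
            errs.append(abs(fit.slope - 0.6786))
            r2s.append(fit.r_squared)
        assert np.median(errs) < 0.1
        assert 0.6 < np.mean(r2s) < 0.95


class TestIC50FoldChange:
    def test_identical_fits_give_unity(self, community):
        resp = inhibition_fraction(TWOFOLD, community)
        fit = fit_dose_response(TWOFOLD, resp)
        assert ic50_fold_change(fit, fit) == pytest.approx(1.0)

    def test_log_arithmetic(self, community):
        resp = inhibition_fraction(TWOFOLD, community)
        base = fit_dose_response(TWOFOLD, resp)
        shifted = StrainParams("adapted", mu_max=0.13,
                               log_ic50=community.log_ic50 + 0.3,
                               hill_slope=community.hill_slope)
        fit_s = fit_dose_response(TWOFOLD, inhibition_fraction(TWOFOLD, shifted))
        assert ic50_fold_change(fit_s, base) == pytest.approx(10.0 ** 0.3,
                                                              rel=1e-4)

    def test_adapted_strain_through_plate_pipeline(self, community):
        adapted = StrainParams("adapted", mu_max=0.13,
                               log_ic50=community.log_ic50 + 0.2,
                               hill_slope=community.hill_slope)
        fits = []
        for strain in (adapted, community):
            plate = gen_plate_gradient(strain)
            fits.append(DoseResponse.from_plate(plate).fit())
        assert ic50_fold_change(*fits) == pytest.approx(10.0 ** 0.2, rel=1e-3)
        assert ic50_fold_change(*fits) == pytest.approx(1.58, abs=0.01)
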