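"""Cohort generator, gamma-variate curve generator, frame-stack renderer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from icgperf.curve_kinetics import OnsetConfig, extract_parameters, roi_time_series
from icgperf.cutoff_regression import fit_parameter_regression
from icgperf.synthetic_data import (
    ConfigError,
    InfeasibleTargetError,
    SyntheticCohortConfig,
    alpha_for_time_ratio,
    gamma_variate_rise,
    generate_cohort,
    generate_curve,
    generate_frame_stack,
)


# ------------------------------------------------------------------ cohort

def test_cohort_shape_and_bitwise_determinism():
    cfg = SyntheticCohortConfig(n_patients=2, points_per_patient=5, seed=42)
    a = generate_cohort(cfg)
    b = generate_cohort(cfg)
    assert len(a) == 10
    pd.testing.assert_frame_equal(a, b)
    c = generate_cohort(SyntheticCohortConfig(n_patients=2, points_per_patient=5,
                                              seed=43))
    assert not a.drop(columns=["patient_id", "point_id"]).equals(
        c.drop(columns=["patient_id", "point_id"]))


def test_cohort_respects_physical_bounds(default_cohort):
    df = default_cohort
    assert df.sto2_pct.between(0, 100).all()
    assert (df.t_half_s > 0).all() and (df.t_max_s > 0).all()
    assert ((df.perfusion_tr > 0) & (df.perfusion_tr <= 1)).all()
    assert np.allclose(df.perfusion_tr, df.t_half_s / df.t_max_s)
    assert df.f_max_au.between(7.62, 199.01).all()
    assert df.nir_index.between(0, 100).all()
    # low-StO2 contamination near the emulated 11/340 rate
    assert 0.01 <= (df.sto2_pct < 60).mean() <= 0.07


def test_noiseless_cohort_roundtrips_regression_truth():
    cfg = SyntheticCohortConfig(
        seed=5, patient_sd_pct=0.0,
        noise_sd={"t_half_s": 0.0, "t_max_s": 0.0, "slope_au_per_s": 0.0,
                  "nir_index": 0.0})
    df = generate_cohort(cfg)
    for name, coeffs in cfg.regression_truth.items():
        fit = fit_parameter_regression(df, name)
        np.testing.assert_allclose(fit.coefficients, coeffs, rtol=1e-8)
        assert fit.r_squared == pytest.approx(1.0)


def test_default_cohort_recovers_t_max_regression(default_cohort):
    import statsmodels.api as sm

    fit = fit_parameter_regression(default_cohort, "t_max_s")
    X = sm.add_constant(default_cohort.sto2_pct.to_numpy())
    se = sm.OLS(default_cohort.t_max_s.to_numpy(), X).fit().bse
    assert abs(fit.coefficients[1] - (-0.785)) < 3 * se[1]
    assert abs(fit.r_squared - 0.250) <= 0.1


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        SyntheticCohortConfig(n_patients=0)
    with pytest.raises(ConfigError):
        SyntheticCohortConfig(sto2_low_fraction=1.5)
    with pytest.raises(ConfigError):
        SyntheticCohortConfig(target_r2={"t_half_s": 0.0})


# ------------------------------------------------------------------ curves

def test_curve_construction_identities_noiseless():
    curve = generate_curve((20.0, 10.0, 100.0), t0_s=8.0, baseline_au=10.0)
    # maximum equals baseline + F_MAX, attained from t0 + T_MAX onward
    assert curve.intensity_au.max() == pytest.approx(110.0)
    at_peak = curve.intensity_au[curve.time_s >= 28.0]
    np.testing.assert_allclose(at_peak, 110.0)
    # analytic half-max value at t0 + T_1/2MAX is exactly baseline + F_MAX/2
    alpha = alpha_for_time_ratio(0.5)
    assert 10.0 + 100.0 * gamma_variate_rise(np.array([0.5]), alpha)[0] == \
        pytest.approx(60.0, abs=1e-9)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(tr=st.floats(0.02, 0.98))
def test_alpha_solves_half_max_condition_for_any_feasible_ratio(tr):
    alpha = alpha_for_time_ratio(tr)
    assert gamma_variate_rise(np.array([tr]), alpha)[0] == pytest.approx(0.5, abs=1e-12)


def test_alpha_matches_dense_grid_half_crossing():
    # dense-grid (1e5-point) upcrossing of the closed form, T_MAX = 20 s
    for tr in (0.2, 0.5, 0.7):
        alpha = alpha_for_time_ratio(tr)
        x = np.linspace(0, 1, 100_000)
        g = gamma_variate_rise(x, alpha)
        j = int(np.argmax(g >= 0.5))
        frac = (0.5 - g[j - 1]) / (g[j] - g[j - 1])
        x_half = x[j - 1] + frac * (x[j] - x[j - 1])
        assert abs(x_half * 20.0 - tr * 20.0) < 1e-3


def test_infeasible_time_ratio_raises():
    with pytest.raises(InfeasibleTargetError):
        alpha_for_time_ratio(1.0)
    with pytest.raises(InfeasibleTargetError):
        generate_curve((20.0, 20.0, 100.0))
    with pytest.raises(InfeasibleTargetError):
        generate_curve((20.0, -1.0, 100.0))


def test_curve_seed_determinism():
    a = generate_curve((20.0, 8.0, 100.0), noise_sd_au=2.0, seed=9)
    b = generate_curve((20.0, 8.0, 100.0), noise_sd_au=2.0, seed=9)
    np.testing.assert_array_equal(a.intensity_au, b.intensity_au)


def test_noisy_extraction_recovers_parameters_within_precision_limits():
    """At 2% noise, recovery errors stay within the estimator's analytic
    precision limits: the threshold-onset detection delay (time for the rise
    to clear k_sd noise SDs) plus sampling quantisation, and for the peak
    time additionally the plateau argmax jitter."""
    rng = np.random.default_rng(77)
    dt = 0.25
    plateau = 2.0
    for _ in range(100):
        t_max = float(rng.uniform(2.0, 40.0))
        tr = float(rng.uniform(0.12, 0.35))
        f_max = float(rng.uniform(50.0, 199.0))
        duration = 8.0 + t_max + plateau
        curve = generate_curve((t_max, tr * t_max, f_max), t0_s=8.0,
                               duration_s=duration,
                               noise_sd_au=0.02 * f_max,
                               seed=int(rng.integers(2 ** 31)))
        p = extract_parameters(curve, OnsetConfig(smooth_window_s=1.0))
        # detection delay: earliest x with g(x) >= k_sd * noise / F_MAX
        alpha = alpha_for_time_ratio(tr)
        x = np.linspace(0.0, 1.0, 20_000)
        g = gamma_variate_rise(x, alpha)
        delay = t_max * float(x[np.argmax(g >= 3.0 * 0.02)])
        # peak argmax jitter: the smoothed curve is within ~3 smoothed-noise
        # SDs of the maximum wherever alpha*(1-x)^2/2 < 3*sigma_s/F_MAX
        sigma_s_rel = 0.02 / np.sqrt(5.0)  # 1 s window at 4 Hz
        peak_jitter = t_max * np.sqrt(2.0 * 3.0 * sigma_s_rel / alpha)
        # the factor 1.5 covers the consecutive-run requirement and the
        # sampling error of the estimated baseline SD in the threshold
        assert abs(p.t_half_s - tr * t_max) <= 1.5 * delay + 2 * dt
        assert abs(p.t_max_s - t_max) <= 1.5 * delay + plateau + peak_jitter + 2 * dt
        assert p.f_max_au == pytest.approx(f_max, rel=0.08)


# ------------------------------------------------------------ frame stacks

def test_constant_curve_renders_to_constant_roi_mean():
    t = np.arange(0, 5, 0.5)
    from icgperf.curve_kinetics import FluorescenceCurve
    curve = FluorescenceCurve(t, np.full_like(t, 40.0), point_id="1")
    stack = generate_frame_stack([curve], [("1", 20.0, 20.0, 4.0)],
                                 background_au=5.0)
    got = roi_time_series(stack.frames, stack.time_s, (20.0, 20.0), 4.0)
    np.testing.assert_allclose(got.intensity_au, 40.0, atol=0.5)


def test_stack_roundtrip_reproduces_curves_within_quantisation():
    curves = [generate_curve((15.0, 6.0, 120.0), duration_s=40.0, point_id="1"),
              generate_curve((25.0, 10.0, 80.0), duration_s=40.0, point_id="2")]
    rois = [("1", 15.0, 32.0, 5.0), ("2", 45.0, 32.0, 5.0)]
    stack = generate_frame_stack(curves, rois, background_au=5.0)
    for curve, (pid, x, y, r) in zip(curves, rois):
        got = roi_time_series(stack.frames, stack.time_s, (x, y), r, point_id=pid)
        np.testing.assert_allclose(got.intensity_au, curve.intensity_au, atol=0.5)
        np.testing.assert_array_equal(got.time_s, curve.time_s)


def test_zero_noise_zero_background_leaves_non_roi_pixels_exactly_zero():
    curve = generate_curve((10.0, 4.0, 90.0), duration_s=25.0, baseline_au=10.0,
                           point_id="1")
    stack = generate_frame_stack([curve], [("1", 32.0, 32.0, 6.0)],
                                 background_au=0.0, noise_sd_au=0.0)
    from icgperf.curve_kinetics import disc_mask
    outside = ~disc_mask((64, 64), (32.0, 32.0), 6.0)
    assert (stack.frames[:, outside] == 0).all()


def test_overlapping_rois_and_mismatched_grids_rejected():
    c1 = generate_curve((10.0, 4.0, 90.0), duration_s=25.0, point_id="1")
    c2 = generate_curve((12.0, 5.0, 80.0), duration_s=25.0, point_id="2")
    with pytest.raises(ConfigError):
        generate_frame_stack([c1, c2], [("1", 20.0, 20.0, 5.0),
                                        ("2", 24.0, 20.0, 5.0)])
    c3 = generate_curve((12.0, 5.0, 80.0), duration_s=30.0, point_id="3")
    with pytest.raises(ConfigError):
        generate_frame_stack([c1, c3], [("1", 15.0, 20.0, 4.0),
                                        ("3", 45.0, 20.0, 4.0)])


def test_full_pipeline_roundtrip_stack_to_regression():
    """Stack -> ROI curves -> kinetics: extracted parameters match the
    rendered targets despite 8-bit quantisation."""
    targets = [(12.0, 5.0, 120.0), (20.0, 8.0, 150.0), (30.0, 12.0, 90.0)]
    curves = [generate_curve(tg, duration_s=55.0, point_id=str(i))
              for i, tg in enumerate(targets)]
    rois = [(str(i), 12.0 + 20.0 * i, 32.0, 5.0) for i in range(3)]
    stack = generate_frame_stack(curves, rois, background_au=3.0)
    for (t_max, t_half, f_max), (pid, x, y, r) in zip(targets, rois):
        trace = roi_time_series(stack.frames, stack.time_s, (x, y), r)
        p = extract_parameters(trace)
        # 8-bit quantisation hides the sub-0.5-AU tails of the rise at both
        # ends: first attainment of the peak can lead the true peak by
        # t_max * sqrt(2 * q / (alpha * F_MAX)), and onset detection lags by
        # the time the rise needs to clear one quantum q = 0.5 AU
        alpha = alpha_for_time_ratio(t_half / t_max)
        quant_lead = t_max * np.sqrt(2 * 0.5 / (alpha * f_max))
        x = np.linspace(0.0, 1.0, 20_000)
        g = gamma_variate_rise(x, alpha)
        onset_lag = t_max * float(x[np.argmax(g >= 0.5 / f_max)])
        assert abs(p.t_max_s - t_max) <= quant_lead + onset_lag + 0.5
        assert abs(p.t_half_s - t_half) <= onset_lag + 0.5
        assert p.f_max_au == pytest.approx(f_max, rel=0.02)
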