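"""Curve smoothing, onset detection, parameter extraction, ROI traces."""

import numpy as np
import pytest

from icgperf.curve_kinetics import (
    CurveError,
    DegenerateCurveError,
    FluorescenceCurve,
    InvalidWindowError,
    NoOnsetError,
    OnsetConfig,
    OutOfBoundsError,
    PerfusionParameters,
    detect_onset,
    extract_parameters,
    roi_time_series,
    smooth_curve,
)
from icgperf.synthetic_data import generate_curve


def _gamma_curve(t_max=20.0, t_half=8.0, f_max=100.0, **kw):
    return generate_curve((t_max, t_half, f_max), **kw)


# ---------------------------------------------------------------- smoothing

def test_smoothing_preserves_constant_curve():
    t = np.arange(0, 30, 0.5)
    curve = FluorescenceCurve(t, np.full_like(t, 50.0))
    out = smooth_curve(curve, 2.0)
    np.testing.assert_allclose(out.intensity_au, 50.0)
    np.testing.assert_array_equal(out.time_s, t)


def test_smoothing_preserves_linear_ramp_in_interior():
    t = np.arange(0, 30, 0.5)
    y = 3.0 * t + 7.0
    out = smooth_curve(FluorescenceCurve(t, y), 4.0)
    interior = (t >= 2.0) & (t <= t[-1] - 2.0)
    np.testing.assert_allclose(out.intensity_au[interior], y[interior], atol=1e-9)


def test_smoothing_matches_bruteforce_windowed_mean_and_reduces_noise():
    clean = _gamma_curve(noise_sd_au=0.0)
    noisy = _gamma_curve(noise_sd_au=2.0, seed=7)
    out = smooth_curve(noisy, 1.0)
    # oracle: direct windowed mean at every sample
    t, y = noisy.time_s, noisy.intensity_au
    expected = np.array([y[np.abs(t - ti) <= 0.5].mean() for ti in t])
    np.testing.assert_allclose(out.intensity_au, expected, rtol=1e-12)
    dev_raw = np.max(np.abs(noisy.intensity_au - clean.intensity_au))
    dev_smooth = np.max(np.abs(out.intensity_au - clean.intensity_au))
    assert dev_smooth < dev_raw


def test_smoothing_zero_window_returns_input_and_long_window_raises():
    curve = _gamma_curve()
    assert smooth_curve(curve, 0.0) is curve
    with pytest.raises(InvalidWindowError):
        smooth_curve(curve, curve.span_s + 1)


# ----------------------------------------------------------------- onset

def test_onset_of_step_function_is_first_post_step_sample():
    t = np.arange(0, 12, 0.5)
    y = np.where(t < 5.25, 10.0, 100.0)
    onset = detect_onset(FluorescenceCurve(t, y), baseline_window_s=5.0,
                         k_sd=3.0, min_run=2)
    assert onset == 5.5


def test_onset_missing_for_flat_curve():
    t = np.arange(0, 12, 0.5)
    with pytest.raises(NoOnsetError):
        detect_onset(FluorescenceCurve(t, np.full_like(t, 10.0)))


def test_onset_matches_bruteforce_scan_on_noisy_bolus():
    # steep-rising bolus (TR = 0.2) so arrival is detectable at the first
    # post-onset sample despite the noise floor
    curve = _gamma_curve(t_max=20.0, t_half=4.0, t0_s=8.0, noise_sd_au=1.0, seed=3)
    k_sd, min_run, bw = 3.0, 3, 5.0
    onset = detect_onset(curve, bw, k_sd, min_run)
    # oracle: exhaustive scan over every candidate start index
    base = curve.intensity_au[curve.time_s <= curve.time_s[0] + bw]
    threshold = base.mean() + k_sd * base.std(ddof=1)
    y = curve.intensity_au
    expected = None
    for i in range(y.size - min_run + 1):
        if np.all(y[i:i + min_run] > threshold):
            expected = curve.time_s[i]
            break
    assert onset == expected
    assert abs(onset - 8.0) <= 0.25  # within one sampling interval of truth


# -------------------------------------------------------------- extraction

def test_extraction_of_linear_ramp_then_plateau():
    t = np.arange(0, 40, 0.25)
    y = np.clip(5.0 * t, 0.0, 100.0)
    params = extract_parameters(FluorescenceCurve(t, y),
                                OnsetConfig(fixed_onset_s=0.0, fixed_baseline_au=0.0))
    assert params.f_max_au == pytest.approx(100.0)
    assert params.t_max_s == pytest.approx(20.0)
    assert params.t_half_s == pytest.approx(10.0)
    assert params.perfusion_tr == pytest.approx(0.5)
    assert params.slope_au_per_s == pytest.approx(5.0)


def test_defining_identities_at_the_published_cutoff_values():
    # TR and slope follow from their definitions at T_1/2MAX = 10 s,
    # T_MAX = 30 s, F_MAX = 150 AU
    p = PerfusionParameters.from_times(t_onset_s=0.0, t_max_s=30.0,
                                       t_half_s=10.0, f_max_au=150.0)
    assert p.perfusion_tr == pytest.approx(10.0 / 30.0)
    assert p.slope_au_per_s == pytest.approx(5.0)


@pytest.mark.parametrize("seed", range(6))
def test_extraction_matches_dense_grid_oracle(seed):
    rng = np.random.default_rng(seed)
    t_max = float(rng.uniform(5.0, 60.0))
    tr = float(rng.uniform(0.15, 0.55))
    f_max = float(rng.uniform(40.0, 190.0))
    curve = _gamma_curve(t_max, tr * t_max, f_max)
    params = extract_parameters(curve)
    dt = 0.25
    # oracle: dense-grid (1e4 points) evaluation of the analytic rise
    from icgperf.synthetic_data import alpha_for_time_ratio, gamma_variate_rise
    alpha = alpha_for_time_ratio(tr)
    x = np.linspace(0.0, 1.0, 10_000)
    g = gamma_variate_rise(x, alpha)
    x_half = x[np.argmax(g >= 0.5)]
    assert abs(params.t_max_s - t_max) <= dt
    # one sampling interval, plus the second-order chord bias of the
    # interpolated half-max crossing on a convex rise
    assert abs(params.t_half_s - x_half * t_max) <= 1.05 * dt
    assert params.f_max_au == pytest.approx(f_max, rel=1e-6)


@pytest.mark.parametrize("factor", [0.5, 3.0, 17.0])
def test_scale_invariance_of_time_parameters(factor):
    base = _gamma_curve(noise_sd_au=0.5, seed=11)
    scaled = FluorescenceCurve(base.time_s, base.intensity_au * factor)
    p0 = extract_parameters(base)
    p1 = extract_parameters(scaled)
    assert p1.t_onset_s == p0.t_onset_s
    assert p1.t_max_s == pytest.approx(p0.t_max_s)
    assert p1.t_half_s == pytest.approx(p0.t_half_s)
    assert p1.perfusion_tr == pytest.approx(p0.perfusion_tr)
    assert p1.f_max_au == pytest.approx(p0.f_max_au * factor)
    assert p1.slope_au_per_s == pytest.approx(p0.slope_au_per_s * factor)


@pytest.mark.parametrize("shift", [2.5, 40.0])
def test_time_shift_invariance(shift):
    base = _gamma_curve(noise_sd_au=0.5, seed=13)
    shifted = FluorescenceCurve(base.time_s + shift, base.intensity_au)
    p0 = extract_parameters(base)
    p1 = extract_parameters(shifted)
    assert p1.t_onset_s == pytest.approx(p0.t_onset_s + shift)
    for attr in ("t_max_s", "t_half_s", "perfusion_tr", "f_max_au", "slope_au_per_s"):
        assert getattr(p1, attr) == pytest.approx(getattr(p0, attr))


def test_extraction_identities_hold_on_every_curve():
    for seed in range(10):
        rng = np.random.default_rng(seed)
        t_max = float(rng.uniform(4, 50))
        curve = _gamma_curve(t_max,
                             float(rng.uniform(0.15, 0.5)) * t_max,
                             float(rng.uniform(30, 190)),
                             noise_sd_au=1.0, seed=seed)
        p = extract_parameters(curve, OnsetConfig(smooth_window_s=1.0))
        assert p.perfusion_tr * p.t_max_s == pytest.approx(p.t_half_s)
        assert p.slope_au_per_s * p.t_max_s == pytest.approx(p.f_max_au)


def test_truncated_rising_curve_is_degenerate():
    full = _gamma_curve(t_max=30.0, t_half=12.0)
    cut = full.time_s < 8.0 + 0.6 * 30.0  # window ends before the peak
    truncated = FluorescenceCurve(full.time_s[cut], full.intensity_au[cut])
    with pytest.raises(DegenerateCurveError):
        extract_parameters(truncated)


def test_fixed_onset_outside_window_rejected():
    curve = _gamma_curve()
    with pytest.raises(CurveError):
        extract_parameters(curve, OnsetConfig(fixed_onset_s=-5.0))


# ------------------------------------------------------------------- ROI

def test_roi_mean_of_uniform_frames():
    frames = np.stack([np.full((16, 16), v) for v in (10.0, 20.0, 30.0)])
    curve = roi_time_series(frames, [0.0, 1.0, 2.0], (8, 8), 3.0)
    np.testing.assert_allclose(curve.intensity_au, [10.0, 20.0, 30.0])


def test_roi_radius_zero_is_single_pixel_trace():
    rng = np.random.default_rng(0)
    frames = rng.uniform(0, 100, size=(5, 12, 12))
    curve = roi_time_series(frames, np.arange(5.0), (7, 4), 0.0)
    np.testing.assert_allclose(curve.intensity_au, frames[:, 4, 7])


def test_roi_mean_matches_bruteforce_pixel_loop():
    rng = np.random.default_rng(1)
    frames = rng.uniform(0, 50, size=(4, 20, 20))
    cx, cy, r = 9.0, 11.0, 4.0
    frames[:, :, :] = 7.0
    # disc pixels get background + 5
    for yy in range(20):
        for xx in range(20):
            if (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2:
                frames[:, yy, xx] = 12.0
    curve = roi_time_series(frames, np.arange(4.0), (cx, cy), r)
    expected = []
    for k in range(4):
        acc = []
        for yy in range(20):
            for xx in range(20):
                if (xx - cx) ** 2 + (yy - cy) ** 2 <= r ** 2:
                    acc.append(frames[k, yy, xx])
        expected.append(np.mean(acc))
    np.testing.assert_allclose(curve.intensity_au, expected)
    np.testing.assert_allclose(curve.intensity_au, 12.0)


def test_roi_outside_frame_raises():
    frames = np.zeros((3, 16, 16))
    with pytest.raises(OutOfBoundsError):
        roi_time_series(frames, [0, 1, 2], (15, 8), 3.0)
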