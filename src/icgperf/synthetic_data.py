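"""Seeded synthetic cohorts, bolus curves, and fluorescence frame stacks.

The source cohort (68 patients x 5 colonic assessment points) is not
deposited, so every pipeline stage is exercised on synthetic data built to
the published study conditions: StO2 mostly between 60 and 98% with ~3% of
points below 60%, each ICG parameter generated from its published
regression on StO2 with Gaussian noise calibrated to reproduce the
published R^2, F_MAX drawn independently of StO2 (it showed no
discrimination in the source cohort), and clinical covariates at roughly
the published prevalences.

Curves are gamma-variate bolus transits — the standard indicator-dilution
shape — whose shape exponent is chosen in closed form so the analytic
half-maximum upcrossing lands exactly at the requested T_1/2MAX; after the
peak the trace is held at F_MAX, a flat stand-in for the recirculation
plateau (the kinetic parameters depend only on the rise phase).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .curve_kinetics import FluorescenceCurve, PerfusionParameters, disc_mask
from . import study_values as sv

__all__ = [
    "SyntheticCohortConfig",
    "FrameStack",
    "ConfigError",
    "InfeasibleTargetError",
    "generate_cohort",
    "generate_curve",
    "generate_frame_stack",
    "gamma_variate_rise",
    "alpha_for_time_ratio",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


class InfeasibleTargetError(ValueError):
    """No gamma-variate exponent realises the requested time ratio."""


def _default_truth() -> dict[str, tuple[float, ...]]:
    return {name: tuple(sv.REGRESSION_EQUATIONS[name]["linear"]["coefficients"])
            for name in (sv.T_HALF, sv.T_MAX, sv.SLOPE, sv.NIR_INDEX)}


def _default_r2() -> dict[str, float]:
    return {name: sv.REGRESSION_EQUATIONS[name]["linear"]["r_squared"]
            for name in (sv.T_HALF, sv.T_MAX, sv.SLOPE, sv.NIR_INDEX)}


def _default_floors() -> dict[str, float]:
    return {sv.T_HALF: sv.PARAMETER_SUMMARIES[sv.T_HALF]["range"][0],
            sv.T_MAX: sv.PARAMETER_SUMMARIES[sv.T_MAX]["range"][0],
            sv.SLOPE: sv.PARAMETER_SUMMARIES[sv.SLOPE]["range"][0]}


def _default_covariates() -> dict[str, float]:
    # patient-level binary prevalences, loosely following the source cohort
    return {"male": 47 / 68, "age_ge_70": 30 / 68, "bmi_ge_25": 23 / 68,
            "asa_ge_3": 9 / 68, "high_ligation": 40 / 68, "pcrt": 9 / 68,
            "diverting_ileostomy": 24 / 68, "athero_risk_ge_20": 15 / 68,
            "anastomotic_complication": 5 / 68}


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort.

    StO2 is a two-component mixture: a dominant truncated normal around 80%
    (the 60–95% bulk) and a low-oxygenation component around 48% hit with
    probability ``sto2_low_fraction``, sized so ~3.2% of points fall below
    the 60% criterion, matching the 11/340 low points of the source cohort.
    A patient-level random intercept (``patient_sd_pct``) induces the
    within-patient clustering of the five points.  Per-parameter residual
    SDs are either given in ``noise_sd`` or calibrated at generation time
    (bisection on the realised, post-floor fit) so each induced R^2 matches
    ``target_r2``.
    """

    n_patients: int = 68
    points_per_patient: int = 5
    seed: int = 0
    sto2_mean: float = 80.0
    sto2_sd: float = 7.0
    sto2_max: float = 95.0
    sto2_low_fraction: float = 0.028
    sto2_low_mean: float = 48.0
    sto2_low_sd: float = 8.0
    sto2_low_bounds: tuple[float, float] = (20.0, 60.0)
    patient_sd_pct: float = 4.0
    kinetic_noise_corr: float = 0.7
    regression_truth: dict = field(default_factory=_default_truth)
    target_r2: dict = field(default_factory=_default_r2)
    noise_sd: Optional[dict] = None
    f_max_mean: float = sv.PARAMETER_SUMMARIES[sv.F_MAX]["mean"]
    f_max_sd: float = sv.PARAMETER_SUMMARIES[sv.F_MAX]["sd"]
    f_max_range: tuple[float, float] = sv.PARAMETER_SUMMARIES[sv.F_MAX]["range"]
    floors: dict = field(default_factory=_default_floors)
    covariate_prevalence: dict = field(default_factory=_default_covariates)

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.points_per_patient < 1:
            raise ConfigError("cohort size must be positive")
        if not (0.0 <= self.sto2_low_fraction < 1.0):
            raise ConfigError("sto2_low_fraction must lie in [0, 1)")
        if not (-1.0 <= self.kinetic_noise_corr <= 1.0):
            raise ConfigError("kinetic_noise_corr must lie in [-1, 1]")
        if self.sto2_sd <= 0 or self.sto2_low_sd <= 0:
            raise ConfigError("StO2 SDs must be > 0")
        for name, r2 in self.target_r2.items():
            if not (0.0 < r2 < 1.0):
                raise ConfigError(f"target R^2 for {name} must lie in (0, 1)")
        if self.f_max_range[0] >= self.f_max_range[1] or self.f_max_sd <= 0:
            raise ConfigError("invalid F_MAX distribution")


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, high: float, size: int) -> np.ndarray:
    a, b = (low - mean) / sd, (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _evaluate_truth(coeffs: Sequence[float], sto2: np.ndarray) -> np.ndarray:
    out = np.full_like(sto2, coeffs[0], dtype=float)
    for k, c in enumerate(coeffs[1:], start=1):
        out += c * sto2 ** k
    return out


def _induced_r_squared(values: np.ndarray, sto2: np.ndarray, order: int) -> float:
    X = np.column_stack([sto2 ** k for k in range(order + 1)])
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ beta
    tss = float(np.sum((values - values.mean()) ** 2))
    return 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0


def _calibrate_noise_sd(predicted: np.ndarray, sto2: np.ndarray, z: np.ndarray,
                        floor: Optional[float], clip: Optional[tuple[float, float]],
                        target_r2: float, order: int,
                        cap: Optional[np.ndarray] = None) -> float:
    """Residual SD whose *realised* (post-floor) fit attains the target R^2.

    Flooring (and, for T_1/2MAX, capping at the point's T_MAX) censors the
    noise, so the naive analytic SD, sd(signal) * sqrt((1 - R^2) / R^2),
    misses the target wherever those bounds bind; a bisection on the actual
    noise draws ``z`` lands on it exactly.
    """
    def realise(s: float) -> np.ndarray:
        v = predicted + s * z
        if floor is not None:
            v = np.maximum(v, floor)
        if clip is not None:
            v = np.clip(v, *clip)
        if cap is not None:
            v = np.minimum(v, cap)
        return v

    signal_sd = float(predicted.std())
    if signal_sd == 0:
        raise ConfigError("regression truth is constant over the drawn StO2")
    s0 = signal_sd * math.sqrt((1.0 - target_r2) / target_r2)
    f = lambda s: _induced_r_squared(realise(s), sto2, order) - target_r2
    # R^2(s) decreases with noise until extreme censoring flattens (and can
    # slightly raise) it again, so bracket the *first* downward crossing on a
    # geometric grid and bisect inside it.
    grid = s0 * np.geomspace(1.0 / 50.0, 50.0, 60)
    fvals = [f(s) for s in grid]
    bracket = None
    for i in range(len(grid) - 1):
        if fvals[i] >= 0 >= fvals[i + 1]:
            bracket = (grid[i], grid[i + 1])
            break
    if bracket is None:  # target R^2 unattainable under these bounds
        return float(grid[int(np.argmin(np.abs(fvals)))])
    lo, hi = bracket
    for _ in range(60):
        mid = math.sqrt(lo * hi)
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


def generate_cohort(config: SyntheticCohortConfig = SyntheticCohortConfig()) -> pd.DataFrame:
    """One synthetic cohort as a tidy assessment-point table.

    Returns ``n_patients x points_per_patient`` rows with StO2, the NIR
    perfusion index, the five ICG parameters and patient covariates.  Each
    regression-linked parameter is its truth equation evaluated at StO2 plus
    calibrated Gaussian noise, floored at its physical bound; the time
    ratio is recomputed as T_1/2MAX / T_MAX after flooring (and therefore
    always lies in (0, 1]).  Identical config and seed give a bit-identical
    table.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients * cfg.points_per_patient

    # StO2: bulk component + low-oxygenation contamination + patient intercept
    if cfg.patient_sd_pct > 0:
        patient_effect = rng.normal(0.0, cfg.patient_sd_pct, size=cfg.n_patients)
    else:
        patient_effect = np.zeros(cfg.n_patients)
    base = _truncated_normal(rng, cfg.sto2_mean, cfg.sto2_sd, 0.0, cfg.sto2_max, n)
    low = _truncated_normal(rng, cfg.sto2_low_mean, cfg.sto2_low_sd,
                            *cfg.sto2_low_bounds, size=n)
    is_low = rng.random(n) < cfg.sto2_low_fraction
    sto2 = np.where(is_low, low, base)
    sto2 = sto2 + np.repeat(patient_effect, cfg.points_per_patient)
    sto2 = np.clip(sto2, 0.0, 100.0)

    cols: dict[str, np.ndarray] = {
        "patient_id": np.repeat(np.arange(1, cfg.n_patients + 1), cfg.points_per_patient),
        "point_id": np.tile(np.arange(1, cfg.points_per_patient + 1), cfg.n_patients),
        "sto2_pct": sto2,
    }

    # generate T_MAX before T_1/2MAX so the kinetic cap t_half <= t_max can
    # enter the latter's noise calibration
    order_of_draw = sorted(cfg.regression_truth,
                           key=lambda nm: 0 if nm == sv.T_MAX else 1)
    z_tmax: Optional[np.ndarray] = None
    for name in order_of_draw:
        coeffs = cfg.regression_truth[name]
        predicted = _evaluate_truth(coeffs, sto2)
        floor = cfg.floors.get(name)
        clip = (0.0, 100.0) if name == sv.NIR_INDEX else None
        cap = cols.get(sv.T_MAX) if name == sv.T_HALF else None
        z = rng.standard_normal(n)
        if name == sv.T_MAX:
            z_tmax = z
        elif name == sv.T_HALF and z_tmax is not None:
            # the two transit times delay jointly when inflow is poor
            rho = cfg.kinetic_noise_corr
            z = rho * z_tmax + math.sqrt(1.0 - rho ** 2) * z
        if cfg.noise_sd is not None and name in cfg.noise_sd:
            noise_sd = float(cfg.noise_sd[name])
        else:
            noise_sd = _calibrate_noise_sd(predicted, sto2, z, floor, clip,
                                           cfg.target_r2[name],
                                           order=len(coeffs) - 1, cap=cap)
        values = predicted + noise_sd * z
        if floor is not None:
            values = np.maximum(values, floor)
        if clip is not None:
            values = np.clip(values, *clip)
        if cap is not None:
            values = np.minimum(values, cap)
        cols[name] = values

    # F_MAX carries no StO2 information in the emulated cohort
    cols[sv.F_MAX] = _truncated_normal(rng, cfg.f_max_mean, cfg.f_max_sd,
                                       *cfg.f_max_range, size=n)

    # kinetic ordering holds by construction; the time ratio follows by identity
    cols[sv.T_HALF] = np.minimum(cols[sv.T_HALF], cols[sv.T_MAX])
    cols[sv.PERFUSION_TR] = cols[sv.T_HALF] / cols[sv.T_MAX]

    df = pd.DataFrame(cols)
    for name, prev in cfg.covariate_prevalence.items():
        draw = (rng.random(cfg.n_patients) < prev).astype(int)
        df[name] = np.repeat(draw, cfg.points_per_patient)
    df["age_yr"] = np.repeat(np.round(
        _truncated_normal(rng, 64.0, 10.0, 19.0, 80.0, cfg.n_patients)), cfg.points_per_patient)
    # patient flagged for transection-line change when any point is under 60%
    low_patient = df.groupby("patient_id")["sto2_pct"].transform(lambda s: (s < 60).any())
    df["transection_line_change"] = low_patient.astype(int)
    return df


def alpha_for_time_ratio(time_ratio: float) -> float:
    """Gamma-variate shape exponent realising a half-max time ratio.

    The normalised rise g(x) = x^alpha * exp(alpha * (1 - x)) peaks at
    x = 1; requiring g(x) = 1/2 at x = TR gives
    alpha = ln(1/2) / (ln TR + 1 - TR) in closed form.  TR at or above 1
    (or at/below 0) is infeasible for this family.
    """
    x = float(time_ratio)
    if not (0.0 < x < 1.0):
        raise InfeasibleTargetError("time ratio must lie strictly inside (0, 1)")
    denom = math.log(x) + 1.0 - x
    alpha = math.log(0.5) / denom
    if not math.isfinite(alpha) or alpha <= 0 or alpha > 1e6:
        raise InfeasibleTargetError(f"no usable gamma-variate exponent for TR={x}")
    return alpha


def gamma_variate_rise(x: np.ndarray, alpha: float) -> np.ndarray:
    """Normalised gamma-variate rise g(x) on x = (t - t0) / T_MAX, clamped at 1 after the peak."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    rising = (x > 0) & (x < 1)
    xr = x[rising]
    out[rising] = np.exp(alpha * (np.log(xr) + 1.0 - xr))
    out[x >= 1] = 1.0
    return out


def generate_curve(target: Union[PerfusionParameters, tuple[float, float, float]],
                   t0_s: float = 8.0,
                   duration_s: Optional[float] = None,
                   frame_rate_hz: float = 4.0,
                   noise_sd_au: float = 0.0,
                   baseline_au: float = 10.0,
                   seed: Optional[int] = None,
                   point_id: str = "") -> FluorescenceCurve:
    """Sample a gamma-variate bolus curve realising the target parameters.

    ``target`` is a :class:`PerfusionParameters` or a ``(t_max_s, t_half_s,
    f_max_au)`` triple.  The noiseless curve sits at ``baseline_au`` before
    the onset ``t0_s``, reaches ``baseline_au + f_max_au`` at ``t0_s +
    t_max_s``, crosses the half-maximum exactly at ``t0_s + t_half_s``, and
    is held at the maximum afterwards.  Seeded Gaussian noise is added and
    the trace clipped at zero.
    """
    if isinstance(target, PerfusionParameters):
        t_max, t_half, f_max = target.t_max_s, target.t_half_s, target.f_max_au
    else:
        t_max, t_half, f_max = map(float, target)
    if t_max <= 0 or f_max <= 0 or not (0 < t_half <= t_max):
        raise InfeasibleTargetError("target must satisfy 0 < t_half <= t_max, f_max > 0")
    alpha = alpha_for_time_ratio(t_half / t_max)
    if t0_s < 0:
        raise ConfigError("t0_s must be >= 0")
    if duration_s is None:
        duration_s = t0_s + 1.25 * t_max + 5.0
    if duration_s < t0_s + t_max:
        raise ConfigError("duration must cover onset + T_MAX")
    t = np.arange(0.0, duration_s, 1.0 / frame_rate_hz)
    y = baseline_au + f_max * gamma_variate_rise((t - t0_s) / t_max, alpha)
    if noise_sd_au > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd_au, size=y.size)
    return FluorescenceCurve(t, np.clip(y, 0.0, None), point_id=point_id)


@dataclass(frozen=True)
class FrameStack:
    """A synthetic fluorescence video: frames, timestamps, and ROI table."""

    frames: np.ndarray  # (n_frames, h, w) uint8
    time_s: np.ndarray
    rois: pd.DataFrame  # point_id, x_px, y_px, radius_px


def generate_frame_stack(curves: Sequence[FluorescenceCurve],
                         roi_specs: Sequence[tuple[str, float, float, float]],
                         frame_shape: tuple[int, int] = (64, 64),
                         background_au: float = 5.0,
                         noise_sd_au: float = 0.0,
                         seed: Optional[int] = None) -> FrameStack:
    """Render curves into disc ROIs of an 8-bit frame stack.

    Every curve must share the same time grid; ROIs (point_id, x, y, radius)
    must be pairwise disjoint and fully inside the frame.  Each frame's
    disc-ROI mean reproduces its curve within quantisation (+/- 0.5 AU) and
    noise; with zero noise and zero background, non-ROI pixels are exactly 0.
    """
    if len(curves) != len(roi_specs):
        raise ConfigError("one ROI spec per curve is required")
    if len(curves) == 0:
        raise ConfigError("at least one curve is required")
    t0 = curves[0].time_s
    for c in curves[1:]:
        if c.time_s.shape != t0.shape or not np.allclose(c.time_s, t0):
            raise ConfigError("all curves must share one time grid")
    h, w = frame_shape
    for pid, x, y, r in roi_specs:
        if x - r < 0 or x + r > w - 1 or y - r < 0 or y + r > h - 1:
            raise ConfigError(f"ROI {pid} extends beyond the frame bounds")
    for i in range(len(roi_specs)):
        for j in range(i + 1, len(roi_specs)):
            _, xi, yi, ri = roi_specs[i]
            _, xj, yj, rj = roi_specs[j]
            if math.hypot(xi - xj, yi - yj) <= ri + rj:
                raise ConfigError("ROIs must be disjoint")

    n_frames = t0.size
    rng = np.random.default_rng(seed)
    frames = np.full((n_frames, h, w), float(background_au))
    if noise_sd_au > 0:
        frames += rng.normal(0.0, noise_sd_au, size=frames.shape)
    for curve, (pid, x, y, r) in zip(curves, roi_specs):
        mask = disc_mask((h, w), (x, y), r)
        frames[:, mask] = curve.intensity_au[:, None]
        if noise_sd_au > 0:
            frames[:, mask] += rng.normal(0.0, noise_sd_au,
                                          size=(n_frames, int(mask.sum())))
    frames = np.clip(np.rint(frames), 0, 255).astype(np.uint8)
    rois = pd.DataFrame(roi_specs, columns=["point_id", "x_px", "y_px", "radius_px"])
    return FrameStack(frames=frames, time_s=t0.copy(), rois=rois)
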