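"""Kinetic quantification of ICG bolus time–fluorescence curves.

After an intravenous indocyanine green (ICG) bolus, the near-infrared
fluorescence intensity in a tissue region of interest rises from a dark
baseline to a maximum as the dye transits the local vasculature.  The rise
phase is summarised by five quantities measured from the time–intensity
curve:

* ``t_max_s`` (T_MAX) — elapsed time from the first fluorescence increase
  (bolus onset) to the maximal intensity;
* ``t_half_s`` (T_1/2MAX) — elapsed time from onset to half of the maximal
  intensity;
* ``perfusion_tr`` — the time ratio T_1/2MAX / T_MAX, in (0, 1];
* ``f_max_au`` (F_MAX) — maximal intensity above baseline, in arbitrary
  camera units (AU);
* ``slope_au_per_s`` — the mean rise rate F_MAX / T_MAX.

Short times and steep slopes indicate brisk arterial inflow; delayed times
indicate compromised perfusion of the bowel segment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FluorescenceCurve",
    "PerfusionParameters",
    "OnsetConfig",
    "CurveError",
    "InvalidWindowError",
    "NoOnsetError",
    "DegenerateCurveError",
    "OutOfBoundsError",
    "smooth_curve",
    "detect_onset",
    "extract_parameters",
    "roi_time_series",
]


class CurveError(ValueError):
    """Base class for curve-analysis failures."""


class InvalidWindowError(CurveError):
    """Smoothing window is as long as (or longer than) the observation span."""


class NoOnsetError(CurveError):
    """No sustained fluorescence increase above baseline was found.

    Signals a flat or non-perfused trace rather than a software fault.
    """


class DegenerateCurveError(CurveError):
    """Curve has no usable rise phase (peak at/before onset, or F_MAX <= 0)."""


class OutOfBoundsError(CurveError):
    """ROI disc extends beyond the frame bounds."""


@dataclass(frozen=True)
class FluorescenceCurve:
    """A sampled time–intensity trace for one assessment point.

    ``time_s`` must be strictly increasing with at least 3 samples;
    intensities are finite, non-negative arbitrary units.  Sampling need not
    be uniform; all interpolation is linear in time.
    """

    time_s: np.ndarray
    intensity_au: np.ndarray
    point_id: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        y = np.asarray(self.intensity_au, dtype=float)
        if t.ndim != 1 or y.ndim != 1 or t.size != y.size:
            raise CurveError("time_s and intensity_au must be 1-D and equal length")
        if t.size < 3:
            raise CurveError("a curve needs at least 3 samples")
        if not np.all(np.isfinite(t)) or not np.all(np.diff(t) > 0):
            raise CurveError("time_s must be finite and strictly increasing")
        if not np.all(np.isfinite(y)) or np.any(y < 0):
            raise CurveError("intensity_au must be finite and >= 0")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "intensity_au", y)

    @property
    def span_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    def __len__(self) -> int:
        return int(self.time_s.size)


@dataclass(frozen=True)
class PerfusionParameters:
    """The five ICG perfusion quantities plus the absolute onset time.

    Invariants: ``0 < t_half_s <= t_max_s``, ``perfusion_tr = t_half_s /
    t_max_s`` in (0, 1], ``slope_au_per_s = f_max_au / t_max_s`` and
    ``f_max_au > 0``.
    """

    t_onset_s: float
    t_max_s: float
    t_half_s: float
    perfusion_tr: float
    f_max_au: float
    slope_au_per_s: float
    point_id: str = ""

    def __post_init__(self) -> None:
        if not (0.0 < self.t_half_s <= self.t_max_s):
            raise CurveError("require 0 < t_half_s <= t_max_s")
        if self.f_max_au <= 0.0:
            raise CurveError("require f_max_au > 0")
        if not np.isclose(self.perfusion_tr, self.t_half_s / self.t_max_s,
                          rtol=1e-9, atol=1e-12):
            raise CurveError("perfusion_tr must equal t_half_s / t_max_s")
        if not np.isclose(self.slope_au_per_s, self.f_max_au / self.t_max_s,
                          rtol=1e-9, atol=1e-12):
            raise CurveError("slope_au_per_s must equal f_max_au / t_max_s")

    @classmethod
    def from_times(cls, t_onset_s: float, t_max_s: float, t_half_s: float,
                   f_max_au: float, point_id: str = "") -> "PerfusionParameters":
        """Build from the measured quantities, deriving TR and slope."""
        return cls(
            t_onset_s=t_onset_s,
            t_max_s=t_max_s,
            t_half_s=t_half_s,
            perfusion_tr=t_half_s / t_max_s,
            f_max_au=f_max_au,
            slope_au_per_s=f_max_au / t_max_s,
            point_id=point_id,
        )


@dataclass(frozen=True)
class OnsetConfig:
    """How the bolus onset ("first fluorescence increase") is detected.

    Baseline statistics are taken over the first ``baseline_window_s``
    seconds; onset is the earliest sample exceeding baseline mean +
    ``k_sd`` x baseline SD for ``min_run`` consecutive samples.  An explicit
    ``fixed_onset_s`` / ``fixed_baseline_au`` overrides detection, for
    traces where the injection time or dark level is known externally.
    ``smooth_window_s`` > 0 applies a centred moving average before
    detection and extraction.
    """

    baseline_window_s: float = 5.0
    k_sd: float = 3.0
    min_run: int = 3
    smooth_window_s: float = 0.0
    fixed_onset_s: Optional[float] = None
    fixed_baseline_au: Optional[float] = None


def smooth_curve(curve: FluorescenceCurve, window_s: float) -> FluorescenceCurve:
    """Centred moving-average smoothing over a time window.

    Each output sample is the mean of all samples within ``window_s / 2``
    seconds of it, so non-uniform sampling is handled naturally.
    ``window_s = 0`` returns the input unchanged.
    """
    if window_s < 0:
        raise InvalidWindowError("window_s must be >= 0")
    if window_s == 0:
        return curve
    if window_s >= curve.span_s:
        raise InvalidWindowError(
            f"window ({window_s} s) must be shorter than the observation span "
            f"({curve.span_s} s)")
    t = curve.time_s
    y = curve.intensity_au
    half = window_s / 2.0
    lo = np.searchsorted(t, t - half, side="left")
    hi = np.searchsorted(t, t + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(y)])
    smoothed = (csum[hi] - csum[lo]) / (hi - lo)
    return replace(curve, intensity_au=smoothed)


def _baseline_stats(curve: FluorescenceCurve, baseline_window_s: float) -> tuple[float, float]:
    t = curve.time_s
    mask = t <= t[0] + baseline_window_s
    if mask.sum() < 3:
        raise CurveError("baseline window must contain at least 3 samples")
    base = curve.intensity_au[mask]
    return float(base.mean()), float(base.std(ddof=1))


def detect_onset(curve: FluorescenceCurve, baseline_window_s: float = 5.0,
                 k_sd: float = 3.0, min_run: int = 3) -> float:
    """Time of the first sustained fluorescence increase (bolus arrival).

    Returns the earliest time t0 at which the intensity exceeds baseline
    mean + ``k_sd`` x baseline SD for ``min_run`` consecutive samples.
    Raises :class:`NoOnsetError` when no sample run satisfies the criterion
    (flat / non-perfused trace).
    """
    if min_run < 1:
        raise CurveError("min_run must be >= 1")
    mean, sd = _baseline_stats(curve, baseline_window_s)
    threshold = mean + k_sd * sd
    above = curve.intensity_au > threshold
    if min_run == 1:
        run_ok = above
    else:
        # run_ok[i] <=> above[i:i+min_run] all True
        window = np.lib.stride_tricks.sliding_window_view(above, min_run)
        run_ok = np.zeros_like(above)
        run_ok[: window.shape[0]] = window.all(axis=1)
    idx = np.flatnonzero(run_ok)
    if idx.size == 0:
        raise NoOnsetError("no sustained increase above baseline threshold")
    return float(curve.time_s[idx[0]])


def extract_parameters(curve: FluorescenceCurve,
                       onset_config: OnsetConfig = OnsetConfig()) -> PerfusionParameters:
    """Measure the five ICG perfusion parameters from one curve.

    F_MAX is the maximum intensity above the baseline mean (removing the
    ambient-light offset); T_MAX is the time of *first* attainment of the
    maximum (robust to saturation plateaus), measured from onset; T_1/2MAX is
    the first upward crossing of baseline + F_MAX/2, linearly interpolated
    between the bracketing samples, measured from onset.  TR and slope follow
    from their defining identities.
    """
    cfg = onset_config
    work = smooth_curve(curve, cfg.smooth_window_s) if cfg.smooth_window_s > 0 else curve
    t = work.time_s
    y = work.intensity_au

    if cfg.fixed_onset_s is not None:
        t_onset = float(cfg.fixed_onset_s)
        if t_onset < t[0] or t_onset > t[-1]:
            raise CurveError("fixed onset lies outside the observation window")
    else:
        # onset on the *raw* trace: smoothing correlates neighbouring samples,
        # which defeats the consecutive-run criterion's noise protection
        t_onset = detect_onset(curve, cfg.baseline_window_s, cfg.k_sd, cfg.min_run)

    if cfg.fixed_baseline_au is not None:
        baseline = float(cfg.fixed_baseline_au)
    else:
        baseline = _baseline_stats(work, cfg.baseline_window_s)[0]

    after = t >= t_onset
    y_after = y[after]
    t_after = t[after]
    y_max = float(y_after.max())
    i_max = int(np.argmax(y_after))  # first attainment of the maximum
    f_max = y_max - baseline
    if f_max <= 0:
        raise DegenerateCurveError("maximum does not exceed baseline")
    t_max = float(t_after[i_max] - t_onset)
    if t_max <= 0:
        raise DegenerateCurveError("maximum occurs at or before onset")
    if i_max == y_after.size - 1:
        # maximum at the final sample: truncated pre-peak only if the trace
        # is still climbing materially (beyond noise) at the window's end
        span = t_after[-1] - t_after[0]
        ref = min(int(np.searchsorted(t_after, t_after[-1] - 0.10 * span)),
                  y_after.size - 2)
        if y_max - y_after[ref] > 0.05 * f_max:
            raise DegenerateCurveError("observation window ends before the peak")

    half_level = baseline + f_max / 2.0
    t_half = _first_upward_crossing(t_after, y_after, half_level) - t_onset
    if t_half <= 0:
        raise DegenerateCurveError("half-maximum reached at onset (step-like trace)")
    # interpolation can land a hair past the sampled peak time on steep curves
    t_half = min(t_half, t_max)

    return PerfusionParameters.from_times(
        t_onset_s=t_onset, t_max_s=t_max, t_half_s=t_half, f_max_au=f_max,
        point_id=curve.point_id)


def _first_upward_crossing(t: np.ndarray, y: np.ndarray, level: float) -> float:
    """Time of the first upward crossing of ``level``, linearly interpolated."""
    reached = np.flatnonzero(y >= level)
    if reached.size == 0:
        raise DegenerateCurveError("curve never reaches the half-maximum level")
    j = int(reached[0])
    if j == 0:
        return float(t[0])
    y0, y1 = y[j - 1], y[j]
    if y1 == y0:
        return float(t[j])
    frac = (level - y0) / (y1 - y0)
    return float(t[j - 1] + frac * (t[j] - t[j - 1]))


def disc_mask(shape: tuple[int, int], center_xy: tuple[float, float],
              radius_px: float) -> np.ndarray:
    """Boolean mask of pixels within Euclidean distance ``radius_px`` of the centre."""
    h, w = shape
    cx, cy = center_xy
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - cx) ** 2 + (yy - cy) ** 2 <= radius_px ** 2


def roi_time_series(frames: np.ndarray | Sequence[np.ndarray],
                    time_s: Sequence[float],
                    center_xy: tuple[float, float],
                    radius_px: float,
                    point_id: str = "") -> FluorescenceCurve:
    """Mean intensity over a disc ROI, per frame, as a fluorescence curve.

    ``frames`` is a (n_frames, height, width) stack; ``time_s`` the frame
    timestamps.  The disc of pixels with Euclidean distance <= ``radius_px``
    from ``center_xy`` (x, y in pixel coordinates) must lie fully inside the
    frame; ``radius_px = 0`` degenerates to the single-pixel trace.
    """
    stack = np.asarray(frames, dtype=float)
    if stack.ndim != 3:
        raise CurveError("frames must be a (n_frames, height, width) stack")
    if stack.shape[0] < 3:
        raise CurveError("need at least 3 frames")
    h, w = stack.shape[1:]
    cx, cy = center_xy
    if (cx - radius_px < 0 or cx + radius_px > w - 1
            or cy - radius_px < 0 or cy + radius_px > h - 1):
        raise OutOfBoundsError("ROI disc extends beyond the frame bounds")
    mask = disc_mask((h, w), center_xy, radius_px)
    if not mask.any():
        raise OutOfBoundsError("ROI disc contains no pixels")
    trace = stack[:, mask].mean(axis=1)
    return FluorescenceCurve(np.asarray(time_s, dtype=float), trace, point_id=point_id)
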