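"""Safe-cutoff derivation by inverse regression against tissue oxygenation.

Each ICG perfusion parameter is regressed (OLS, linear or quadratic in StO2)
on hyperspectral tissue oxygen saturation over the pooled assessment points.
The regression is then read *inversely*: the predicted mean parameter value
at a chosen StO2 level (60–80%) is taken as the cutoff separating
acceptable from compromised oxygenation, reported with the 95% CI of the
mean response.  Parameters whose scatter against StO2 carries no usable
trend (perfusion TR, F_MAX in the source cohort) instead get a descriptive
cutoff from the sample's central 95% coverage interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "RegressionFit",
    "CutoffEstimate",
    "DegenerateDesignError",
    "InsufficientDataError",
    "fit_parameter_regression",
    "predict_cutoff",
    "cutoff_schedule",
    "descriptive_cutoff",
    "round_to_grid",
]

ModelForm = Literal["linear", "quadratic"]


class DegenerateDesignError(ValueError):
    """Design matrix is rank deficient (e.g. constant StO2)."""


class InsufficientDataError(ValueError):
    """Too few finite observations for the requested estimate."""


@dataclass(frozen=True)
class RegressionFit:
    """An OLS fit of one perfusion parameter on StO2 (and optionally StO2^2).

    Carries the design summaries (X'X inverse, residual variance, residual
    degrees of freedom) needed to compute the CI of the mean response at any
    StO2 level without re-touching the data.
    """

    parameter_name: str
    model_form: ModelForm
    coefficients: np.ndarray  # (intercept, b_sto2[, b_sto2sq])
    r_squared: float
    n_points: int
    residual_variance: float
    df_resid: int
    xtx_inv: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")
        if self.n_points < len(self.coefficients) + 1:
            raise ValueError("n_points must exceed the number of coefficients")

    def design_row(self, sto2_level: float) -> np.ndarray:
        x = [1.0, sto2_level]
        if self.model_form == "quadratic":
            x.append(sto2_level ** 2)
        return np.asarray(x)

    def predict_mean(self, sto2_level: float) -> float:
        """Mean parameter value the fit predicts at an StO2 level (%)."""
        return float(self.design_row(sto2_level) @ self.coefficients)

    @classmethod
    def from_coefficients(cls, parameter_name: str, coefficients: Sequence[float],
                          r_squared: float = 0.0, n_points: int = 340) -> "RegressionFit":
        """Wrap an externally reported equation (no residual information).

        Used to evaluate published equations; CIs from such a fit have zero
        width because the residual variance is unknown (taken as 0).
        """
        coefficients = np.asarray(coefficients, dtype=float)
        form: ModelForm = "quadratic" if coefficients.size == 3 else "linear"
        k = coefficients.size
        return cls(parameter_name=parameter_name, model_form=form,
                   coefficients=coefficients, r_squared=r_squared,
                   n_points=n_points, residual_variance=0.0,
                   df_resid=n_points - k, xtx_inv=np.zeros((k, k)))


@dataclass(frozen=True)
class CutoffEstimate:
    """Predicted mean parameter value at one StO2 level, with 95% CI of the mean."""

    parameter_name: str
    sto2_level: float
    mean_value: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.mean_value <= self.ci_high):
            raise ValueError("require ci_low <= mean_value <= ci_high")


def _design_matrix(sto2: np.ndarray, model_form: ModelForm) -> np.ndarray:
    cols = [np.ones_like(sto2), sto2]
    if model_form == "quadratic":
        cols.append(sto2 ** 2)
    return np.column_stack(cols)


def fit_parameter_regression(points: pd.DataFrame, parameter_name: str,
                             model_form: ModelForm = "linear",
                             sto2_column: str = "sto2_pct",
                             outlier_filter: bool = False) -> RegressionFit:
    """OLS of a perfusion parameter (response) on StO2 (predictor).

    Non-finite rows are dropped.  ``outlier_filter=True`` additionally drops
    points with |externally studentized residual| > 4 and refits once (the
    source analysis excluded a handful of points for two parameters without
    stating its rule; this filter is an explicit, documented stand-in).
    """
    y = pd.to_numeric(points[parameter_name], errors="coerce").to_numpy(dtype=float)
    x = pd.to_numeric(points[sto2_column], errors="coerce").to_numpy(dtype=float)
    keep = np.isfinite(y) & np.isfinite(x)
    y, x = y[keep], x[keep]
    if y.size < 10:
        raise InsufficientDataError("need >= 10 finite (parameter, StO2) pairs")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("StO2 is constant; regression design is rank deficient")

    def _fit(xv: np.ndarray, yv: np.ndarray):
        X = _design_matrix(xv, model_form)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise DegenerateDesignError("rank-deficient regression design")
        return sm.OLS(yv, X).fit(), X

    res, X = _fit(x, y)
    if outlier_filter:
        influence = res.get_influence()
        keep2 = np.abs(influence.resid_studentized_external) <= 4
        if keep2.sum() >= 10 and not keep2.all():
            x, y = x[keep2], y[keep2]
            res, X = _fit(x, y)

    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = float(res.rsquared) if tss > 0 else 0.0
    return RegressionFit(
        parameter_name=parameter_name,
        model_form=model_form,
        coefficients=np.asarray(res.params, dtype=float),
        r_squared=max(0.0, min(1.0, r2)),
        n_points=int(y.size),
        residual_variance=float(res.mse_resid) if res.df_resid > 0 else 0.0,
        df_resid=int(res.df_resid),
        xtx_inv=np.linalg.inv(X.T @ X),
    )


def predict_cutoff(fit: RegressionFit, sto2_level: float,
                   alpha: float = 0.05) -> CutoffEstimate:
    """Cutoff at an StO2 level: predicted mean with the CI of the mean response.

    The CI uses the t distribution on the fit's residual degrees of freedom
    and the standard error of the mean response,
    se = sqrt(sigma^2 * x0' (X'X)^-1 x0).  A fit built from published
    coefficients has no residual information and yields a zero-width CI.
    """
    if not (40.0 <= sto2_level <= 100.0):
        raise ValueError("sto2_level must lie within [40, 100] percent")
    x0 = fit.design_row(sto2_level)
    mean = float(x0 @ fit.coefficients)
    se = math.sqrt(max(0.0, fit.residual_variance * float(x0 @ fit.xtx_inv @ x0)))
    if se > 0:
        tcrit = float(stats.t.ppf(1 - alpha / 2, fit.df_resid))
        half = tcrit * se
    else:
        half = 0.0
    return CutoffEstimate(parameter_name=fit.parameter_name,
                          sto2_level=float(sto2_level), mean_value=mean,
                          ci_low=mean - half, ci_high=mean + half)


def cutoff_schedule(fit: RegressionFit,
                    levels: Sequence[float] = (60, 65, 70, 75, 80)) -> pd.DataFrame:
    """Cutoff estimates over a ladder of StO2 levels, as a tidy table."""
    rows = []
    for lv in levels:
        est = predict_cutoff(fit, lv)
        rows.append({"parameter": fit.parameter_name, "sto2_level": est.sto2_level,
                     "cutoff_mean": est.mean_value, "ci_low": est.ci_low,
                     "ci_high": est.ci_high})
    return pd.DataFrame(rows)


def descriptive_cutoff(values: Sequence[float], direction: Literal["le", "ge"],
                       grid: Optional[float] = None,
                       method: Literal["percentile", "normal"] = "percentile") -> float:
    """Cutoff from the sample's 95% coverage interval (trend-free parameters).

    ``direction="le"`` returns the upper bound (97.5th percentile; values at
    or below it are "within range"), ``"ge"`` the lower bound (2.5th
    percentile).  ``method="normal"`` uses mean +/- 1.96 SD instead of
    percentiles.  ``grid`` rounds the bound to the nearest multiple (e.g.
    0.1 for the dimensionless time ratio, 5 for intensities).
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 10:
        raise InsufficientDataError("need >= 10 finite values for a descriptive cutoff")
    if direction not in ("le", "ge"):
        raise ValueError("direction must be 'le' or 'ge'")
    if method == "percentile":
        bound = float(np.percentile(v, 97.5 if direction == "le" else 2.5))
    elif method == "normal":
        mean, sd = float(v.mean()), float(v.std(ddof=1))
        bound = mean + 1.96 * sd if direction == "le" else mean - 1.96 * sd
    else:
        raise ValueError("method must be 'percentile' or 'normal'")
    return round_to_grid(bound, grid) if grid else bound


def round_to_grid(value: float, grid: float) -> float:
    """Round to the nearest multiple of ``grid`` (presentation-layer only)."""
    if grid <= 0:
        raise ValueError("grid must be > 0")
    return float(round(value / grid) * grid)
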