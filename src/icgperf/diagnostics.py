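"""Diagnostic evaluation of safe cutoffs against the StO2 >= 60% criterion.

Each assessment point is dichotomised twice: by whether the ICG parameter
falls within its safe range (the *test*) and by whether hyperspectral tissue
oxygen saturation is at least 60% (the *condition*).  The resulting 2x2
tables yield sensitivity, specificity, predictive values and accuracy with
exact (Clopper–Pearson) confidence intervals, association tests (Fisher's
exact when any expected cell is below 5, else Pearson chi-square), and ROC
analysis with DeLong confidence intervals for the AUC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "ContingencyTable2x2",
    "MetricEstimate",
    "DiagnosticMetrics",
    "AssociationResult",
    "RocResult",
    "EmptyTableError",
    "UndefinedRocError",
    "dichotomize",
    "diagnostic_metrics",
    "association_test",
    "roc_analysis",
    "LOWER_IS_POSITIVE",
]

Direction = Literal["le", "ge", "lt", "gt"]

#: Parameters for which *smaller* values indicate good perfusion; their
#: scores are negated before ROC analysis so that larger = more likely
#: StO2 >= 60%.
LOWER_IS_POSITIVE = frozenset({"t_half_s", "t_max_s", "perfusion_tr"})


class EmptyTableError(ValueError):
    """No points to cross-classify."""


class UndefinedRocError(ValueError):
    """ROC needs both StO2 classes present."""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of points by safe-range membership vs StO2 >= 60%.

    Test-positive means the parameter lies within its safe range;
    condition-positive means StO2 >= 60%.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be >= 0")
        if self.total == 0:
            raise EmptyTableError("contingency table is empty")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        """Rows: test within/outside range; columns: StO2 >= 60 / < 60."""
        return np.array([[self.tp, self.fp], [self.fn, self.tn]])


@dataclass(frozen=True)
class MetricEstimate:
    """One diagnostic proportion (percent) with its 95% CI.

    ``defined`` is False when the denominator is zero; the value and CI are
    then NaN rather than raising.
    """

    value: float
    ci_low: float
    ci_high: float
    defined: bool = True


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    accuracy: MetricEstimate

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name).value
                for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy")}


@dataclass(frozen=True)
class AssociationResult:
    test_name: Literal["fisher_exact", "pearson_chi2"]
    p_value: float
    statistic: Optional[float] = None


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_positive: int
    n_negative: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError("AUC must lie in [0, 1]")


def _within_safe_range(values: np.ndarray, cutoff: float, direction: Direction) -> np.ndarray:
    if direction == "le":
        return values <= cutoff
    if direction == "ge":
        return values >= cutoff
    if direction == "lt":
        return values < cutoff
    if direction == "gt":
        return values > cutoff
    raise ValueError(f"unknown direction {direction!r}")


def dichotomize(points: pd.DataFrame, parameter_name: str, cutoff: float,
                direction: Direction, sto2_column: str = "sto2_pct",
                sto2_threshold: float = 60.0) -> ContingencyTable2x2:
    """Cross-classify points by safe-range membership vs StO2 >= threshold.

    Ties at the cutoff fall on the within-range side for the inclusive
    directions ("le"/"ge"); "gt"/"lt" are strict, mirroring the published
    inequality for each parameter.
    """
    if not math.isfinite(cutoff):
        raise ValueError("cutoff must be finite")
    vals = pd.to_numeric(points[parameter_name], errors="coerce").to_numpy(dtype=float)
    sto2 = pd.to_numeric(points[sto2_column], errors="coerce").to_numpy(dtype=float)
    keep = np.isfinite(vals) & np.isfinite(sto2)
    vals, sto2 = vals[keep], sto2[keep]
    if vals.size == 0:
        raise EmptyTableError("no points with finite parameter and StO2 values")
    test_pos = _within_safe_range(vals, cutoff, direction)
    cond_pos = sto2 >= sto2_threshold
    return ContingencyTable2x2(
        tp=int(np.sum(test_pos & cond_pos)),
        fp=int(np.sum(test_pos & ~cond_pos)),
        fn=int(np.sum(~test_pos & cond_pos)),
        tn=int(np.sum(~test_pos & ~cond_pos)),
    )


def _proportion(count: int, nobs: int, ci_method: str) -> MetricEstimate:
    if nobs == 0:
        return MetricEstimate(float("nan"), float("nan"), float("nan"), defined=False)
    method = {"clopper-pearson": "beta", "wilson": "wilson"}[ci_method]
    lo, hi = proportion_confint(count, nobs, alpha=0.05, method=method)
    return MetricEstimate(100.0 * count / nobs, 100.0 * float(lo), 100.0 * float(hi))


def diagnostic_metrics(table: ContingencyTable2x2,
                       ci_method: Literal["clopper-pearson", "wilson"] = "clopper-pearson",
                       ) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy (percent) with 95% CIs.

    Defaults to exact Clopper–Pearson intervals.  A metric with a zero
    denominator is reported as undefined (NaN, ``defined=False``) rather
    than raising.
    """
    t = table
    return DiagnosticMetrics(
        sensitivity=_proportion(t.tp, t.tp + t.fn, ci_method),
        specificity=_proportion(t.tn, t.tn + t.fp, ci_method),
        ppv=_proportion(t.tp, t.tp + t.fp, ci_method),
        npv=_proportion(t.tn, t.tn + t.fn, ci_method),
        accuracy=_proportion(t.tp + t.tn, t.total, ci_method),
    )


def association_test(table: ContingencyTable2x2) -> AssociationResult:
    """Fisher's exact (two-sided) when any expected cell < 5, else Pearson chi-square.

    The chi-square variant is uncorrected (no Yates continuity correction),
    matching the conventional large-sample Pearson test.
    """
    obs = table.as_array()
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        # a zero margin: chi-square is undefined, Fisher degenerates to p = 1
        return AssociationResult("fisher_exact", 1.0)
    expected = stats.contingency.expected_freq(obs)
    if expected.min() < 5:
        _, p = stats.fisher_exact(obs, alternative="two-sided")
        return AssociationResult("fisher_exact", float(p))
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
    return AssociationResult("pearson_chi2", float(p), statistic=float(chi2))


def _delong_variance(pos_scores: np.ndarray, neg_scores: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance from oriented scores."""
    m, n = pos_scores.size, neg_scores.size
    # structural components: per-positive and per-negative placement values
    v10 = np.empty(m)
    for i, x in enumerate(pos_scores):
        v10[i] = (np.sum(x > neg_scores) + 0.5 * np.sum(x == neg_scores)) / n
    v01 = np.empty(n)
    for j, y in enumerate(neg_scores):
        v01[j] = (np.sum(pos_scores > y) + 0.5 * np.sum(pos_scores == y)) / m
    auc = float(v10.mean())
    s10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    s01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return auc, s10 / m + s01 / n


def roc_analysis(points: pd.DataFrame, parameter_name: str,
                 sto2_column: str = "sto2_pct", sto2_threshold: float = 60.0,
                 lower_is_positive: Optional[bool] = None) -> RocResult:
    """ROC AUC of one parameter for predicting StO2 >= threshold.

    Time parameters and the perfusion time ratio are negated before scoring
    (shorter is better) so AUC > 0.5 always means informative ordering.  The
    CI and the p-value against AUC = 0.5 use DeLong's method (normal
    approximation on the placement-value variance).
    """
    vals = pd.to_numeric(points[parameter_name], errors="coerce").to_numpy(dtype=float)
    sto2 = pd.to_numeric(points[sto2_column], errors="coerce").to_numpy(dtype=float)
    keep = np.isfinite(vals) & np.isfinite(sto2)
    vals, sto2 = vals[keep], sto2[keep]
    labels = sto2 >= sto2_threshold
    if labels.all() or not labels.any():
        raise UndefinedRocError("both StO2 classes must be present")
    if lower_is_positive is None:
        lower_is_positive = parameter_name in LOWER_IS_POSITIVE
    scores = -vals if lower_is_positive else vals

    auc = float(roc_auc_score(labels, scores))
    auc_check, var = _delong_variance(scores[labels], scores[~labels])
    assert abs(auc - auc_check) < 1e-10
    se = math.sqrt(var)
    if se > 0:
        z = (auc - 0.5) / se
        p = 2.0 * float(stats.norm.sf(abs(z)))
        lo, hi = auc - 1.959963984540054 * se, auc + 1.959963984540054 * se
    else:
        p = 0.0 if auc != 0.5 else 1.0
        lo = hi = auc
    return RocResult(auc=auc, ci_low=max(0.0, lo), ci_high=min(1.0, hi),
                     p_value=p, n_positive=int(labels.sum()),
                     n_negative=int((~labels).sum()))
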