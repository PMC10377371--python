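"""Intraoperative perfusion decision rules.

Two rule sets are implemented.  The *protocol* combines hyperspectral StO2
with the ICG half-rise time at the planned transection line: good perfusion
(StO2 > 60% and T_1/2MAX < 10 s) proceeds to anastomosis; poor perfusion
(StO2 < 50% and T_1/2MAX > 25 s) moves the transection line proximally and
triggers re-evaluation; at the second evaluation StO2 >= 60% with T_1/2MAX
within 25 s is accepted.  Everything in between is an intermediate status
left to the surgeon's judgement.

The *stepwise prediction* uses the ICG parameters alone to predict the StO2
class: both time parameters within their safe ranges predicts StO2 >= 60%;
both outside predicts < 60%; discordant cases are adjudicated by the slope
(at least 5 AU/s predicts >= 60%).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Union

from .curve_kinetics import PerfusionParameters

__all__ = [
    "Stage",
    "PerfusionCategory",
    "ProtocolAction",
    "PerfusionAssessment",
    "Decision",
    "SafeRanges",
    "StO2Class",
    "intraoperative_protocol",
    "stepwise_prediction",
]


class Stage(str, Enum):
    FIRST = "first"
    SECOND = "second"


class PerfusionCategory(str, Enum):
    GOOD = "good"
    ACCEPTABLE_INTERMEDIATE = "acceptable_intermediate"
    POOR = "poor"


class ProtocolAction(str, Enum):
    PROCEED_ANASTOMOSIS = "proceed_anastomosis"
    MOVE_TRANSECTION_LINE = "move_transection_line"
    SURGEON_REVIEW = "surgeon_review"


class StO2Class(str, Enum):
    """Predicted tissue-oxygenation class."""
    ADEQUATE = "sto2_ge_60"
    LOW = "sto2_lt_60"


@dataclass(frozen=True)
class PerfusionAssessment:
    """One combined HSI + ICG reading at a candidate transection line."""

    sto2_pct: float
    t_half_s: float
    stage: Stage = Stage.FIRST
    params: Optional[PerfusionParameters] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.sto2_pct <= 100.0):
            raise ValueError("sto2_pct must lie in [0, 100]")
        if self.t_half_s <= 0:
            raise ValueError("t_half_s must be > 0")


@dataclass(frozen=True)
class Decision:
    category: PerfusionCategory
    action: ProtocolAction

    def __post_init__(self) -> None:
        # poor perfusion at the first assessment always moves the line
        if (self.category is PerfusionCategory.POOR
                and self.action is ProtocolAction.PROCEED_ANASTOMOSIS):
            raise ValueError("poor perfusion cannot proceed to anastomosis")


@dataclass(frozen=True)
class SafeRanges:
    """Safe cutoffs consumed by the stepwise prediction.

    Time parameters are within range at or below their cutoff; slope at or
    above its cutoff.
    """

    t_half_max_s: float = 10.0
    t_max_max_s: float = 30.0
    slope_min_au_per_s: float = 5.0

    @classmethod
    def from_mapping(cls, cutoffs: Mapping[str, float]) -> "SafeRanges":
        try:
            return cls(t_half_max_s=float(cutoffs["t_half_s"]),
                       t_max_max_s=float(cutoffs["t_max_s"]),
                       slope_min_au_per_s=float(cutoffs["slope_au_per_s"]))
        except KeyError as exc:  # missing cutoff entry
            raise KeyError(f"safe-range registry lacks entry {exc}") from exc


def intraoperative_protocol(assessment: PerfusionAssessment) -> Decision:
    """Map one StO2 + T_1/2MAX reading to a surgical decision.

    First stage: StO2 > 60% and T_1/2MAX < 10 s is good perfusion (proceed);
    StO2 < 50% and T_1/2MAX > 25 s is poor perfusion (move the transection
    line); any other combination is an intermediate status referred to the
    surgeon.  Second stage (after a line change): StO2 >= 60% with T_1/2MAX
    <= 25 s is acceptable (proceed); otherwise the status remains poor and
    goes back to the surgeon.
    """
    s, th = assessment.sto2_pct, assessment.t_half_s
    if assessment.stage is Stage.FIRST:
        if s > 60.0 and th < 10.0:
            return Decision(PerfusionCategory.GOOD, ProtocolAction.PROCEED_ANASTOMOSIS)
        if s < 50.0 and th > 25.0:
            return Decision(PerfusionCategory.POOR, ProtocolAction.MOVE_TRANSECTION_LINE)
        return Decision(PerfusionCategory.ACCEPTABLE_INTERMEDIATE,
                        ProtocolAction.SURGEON_REVIEW)
    # second evaluation, on the relocated transection line
    if s >= 60.0 and th <= 25.0:
        return Decision(PerfusionCategory.ACCEPTABLE_INTERMEDIATE,
                        ProtocolAction.PROCEED_ANASTOMOSIS)
    return Decision(PerfusionCategory.POOR, ProtocolAction.SURGEON_REVIEW)


def stepwise_prediction(params: Union[PerfusionParameters, Mapping[str, float]],
                        cutoffs: SafeRanges = SafeRanges()) -> StO2Class:
    """Predict the StO2 class (>= 60% vs < 60%) from ICG parameters alone.

    Both T_1/2MAX and T_MAX within their safe ranges predicts adequate
    oxygenation; both outside predicts low oxygenation; when exactly one is
    within range, the slope adjudicates (>= its cutoff predicts adequate).
    Deterministic and total over finite inputs.
    """
    if isinstance(params, PerfusionParameters):
        t_half, t_max, slope = params.t_half_s, params.t_max_s, params.slope_au_per_s
    else:
        t_half = float(params["t_half_s"])
        t_max = float(params["t_max_s"])
        slope = float(params["slope_au_per_s"])

    half_ok = t_half <= cutoffs.t_half_max_s
    tmax_ok = t_max <= cutoffs.t_max_max_s
    if half_ok and tmax_ok:
        return StO2Class.ADEQUATE
    if not half_ok and not tmax_ok:
        return StO2Class.LOW
    return StO2Class.ADEQUATE if slope >= cutoffs.slope_min_au_per_s else StO2Class.LOW
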