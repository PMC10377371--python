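"""Reference values from the prospective clinical validation study.

These are the published summary inputs of the 68-patient laparoscopic
colorectal cohort (5 assessment points per patient, 340 points) on which the
safe-value analysis was established: per-parameter regression equations of
each ICG quantity on hyperspectral tissue oxygen saturation (StO2, %), the
descriptive parameter distributions, the cross-tabulations of each safe
cutoff against the StO2 >= 60% criterion, and the published safe cutoffs
themselves.  They serve two roles here: as the *inputs* the diagnostics
pipeline is exercised on (the cross-tabulations are data, not code), and as
the default study conditions the synthetic cohort generator emulates.
"""

from __future__ import annotations

from .diagnostics import ContingencyTable2x2

# Canonical column names for the six quantities paired with StO2.
T_HALF = "t_half_s"
T_MAX = "t_max_s"
PERFUSION_TR = "perfusion_tr"
F_MAX = "f_max_au"
SLOPE = "slope_au_per_s"
NIR_INDEX = "nir_index"

PARAMETER_NAMES = (T_HALF, T_MAX, PERFUSION_TR, F_MAX, SLOPE, NIR_INDEX)

#: Published regression equations of each parameter on StO2 (%):
#: (intercept, linear StO2 coefficient[, quadratic StO2^2 coefficient]),
#: with the reported R^2 and the number of points in the fit.
REGRESSION_EQUATIONS: dict[str, dict[str, dict]] = {
    T_HALF: {
        "linear": {"coefficients": (26.351, -0.267), "r_squared": 0.183, "n": 340},
        "quadratic": {"coefficients": (82.801, -1.851, 0.011), "r_squared": 0.260, "n": 340},
    },
    T_MAX: {
        "linear": {"coefficients": (76.287, -0.785), "r_squared": 0.250, "n": 340},
        "quadratic": {"coefficients": (252.715, -5.736, 0.034), "r_squared": 0.369, "n": 340},
    },
    SLOPE: {
        "linear": {"coefficients": (-2.236, 0.144), "r_squared": 0.025, "n": 340},
        "linear_filtered": {"coefficients": (-3.087, 0.146), "r_squared": 0.043, "n": 335},
    },
    NIR_INDEX: {
        "linear": {"coefficients": (10.515, 0.699), "r_squared": 0.152, "n": 340},
        "linear_filtered": {"coefficients": (13.125, 0.683), "r_squared": 0.185, "n": 332},
    },
}

#: Descriptive distribution of each parameter over the 340 points:
#: mean, SD, and observed (min, max).
PARAMETER_SUMMARIES: dict[str, dict] = {
    T_HALF: {"mean": 4.07, "sd": 5.85, "range": (0.03, 87.67)},
    T_MAX: {"mean": 10.85, "sd": 14.68, "range": (1.57, 94.77)},
    PERFUSION_TR: {"mean": 0.43, "sd": 0.16, "range": (0.01, 1.00)},
    F_MAX: {"mean": 97.21, "sd": 37.00, "range": (7.62, 199.01)},
    SLOPE: {"mean": 9.74, "sd": 8.46, "range": (0.33, 54.95)},
    NIR_INDEX: {"mean": 68.82, "sd": 16.76, "range": (10.0, 98.0)},
}

#: Published safe cutoffs and their orientation: a point is test-positive
#: ("within the safe range") when the comparison holds.  "le"/"ge" are
#: inclusive; "gt" is strict (the published F_MAX split is <=25 vs >25).
SAFE_CUTOFFS: dict[str, tuple[str, float]] = {
    T_HALF: ("le", 10.0),
    T_MAX: ("le", 30.0),
    PERFUSION_TR: ("le", 0.8),
    F_MAX: ("gt", 25.0),
    SLOPE: ("ge", 5.0),
    NIR_INDEX: ("ge", 50.0),
}

#: Published cross-tabulations of safe-range membership against StO2 >= 60%
#: over the 340 assessment points (11 points below 60%, 329 at or above).
CONTINGENCY_TABLES: dict[str, ContingencyTable2x2] = {
    T_HALF: ContingencyTable2x2(tp=319, fp=5, fn=10, tn=6),
    T_MAX: ContingencyTable2x2(tp=322, fp=1, fn=7, tn=10),
    PERFUSION_TR: ContingencyTable2x2(tp=322, fp=8, fn=7, tn=3),
    F_MAX: ContingencyTable2x2(tp=314, fp=11, fn=15, tn=0),
    SLOPE: ContingencyTable2x2(tp=234, fp=0, fn=95, tn=11),
}

#: StO2 threshold (%) defining acceptable colonic tissue oxygenation.
STO2_SAFE_THRESHOLD = 60.0

#: Grids for presentation-layer rounding of regression cutoffs to the
#: clinically convenient safe values (e.g. 29.19 s -> 30 s).
SAFE_VALUE_GRIDS: dict[str, float] = {
    T_HALF: 1.0,
    T_MAX: 5.0,
    PERFUSION_TR: 0.1,
    F_MAX: 5.0,
    SLOPE: 5.0,
    NIR_INDEX: 5.0,
}
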