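#!/usr/bin/env python
"""Fit parameter-vs-StO2 regressions and derive the safe cutoff schedules.

For each regression-linked parameter, fits linear and quadratic OLS on the
synthetic cohort, tabulates the predicted cutoff (mean and 95% CI of the
mean response) at StO2 60–80%, and rounds the StO2-60% cutoff to its
clinically convenient safe value.  Parameters without a usable StO2 trend
(perfusion TR, F_MAX) get descriptive 95%-coverage cutoffs instead.
"""

import argparse
from pathlib import Path

import pandas as pd

from icgperf import study_values as sv
from icgperf.cutoff_regression import (cutoff_schedule, descriptive_cutoff,
                                       fit_parameter_regression, round_to_grid)
from icgperf.synthetic_data import SyntheticCohortConfig, generate_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cohort = generate_cohort(SyntheticCohortConfig(seed=args.seed))

    schedules, fits = [], []
    for name in (sv.T_HALF, sv.T_MAX, sv.SLOPE, sv.NIR_INDEX):
        for form in ("linear", "quadratic"):
            fit = fit_parameter_regression(cohort, name, form)
            fits.append({"parameter": name, "model": form, "n": fit.n_points,
                         "r_squared": fit.r_squared,
                         **{f"b{i}": c for i, c in enumerate(fit.coefficients)}})
            sched = cutoff_schedule(fit)
            sched.insert(1, "model", form)
            schedules.append(sched)
        linear = fit_parameter_regression(cohort, name, "linear")
        raw = linear.predict_mean(60.0)
        safe = round_to_grid(raw, sv.SAFE_VALUE_GRIDS[name])
        print(f"{name:>15} linear R^2={linear.r_squared:.3f}  "
              f"cutoff@60% = {raw:6.2f} -> safe value {safe:g}")

    pd.DataFrame(fits).to_csv(args.out_dir / "regression_fits.csv", index=False)
    pd.concat(schedules).to_csv(args.out_dir / "cutoff_schedules.csv", index=False)

    tr_cut = descriptive_cutoff(cohort[sv.PERFUSION_TR], "le",
                                grid=sv.SAFE_VALUE_GRIDS[sv.PERFUSION_TR])
    fmax_cut = descriptive_cutoff(cohort[sv.F_MAX], "ge",
                                  grid=sv.SAFE_VALUE_GRIDS[sv.F_MAX])
    pd.DataFrame([{"parameter": sv.PERFUSION_TR, "direction": "le", "cutoff": tr_cut},
                  {"parameter": sv.F_MAX, "direction": "ge", "cutoff": fmax_cut}]
                 ).to_csv(args.out_dir / "descriptive_cutoffs.csv", index=False)
    print(f"descriptive cutoffs: perfusion TR <= {tr_cut:g}, F_MAX >= {fmax_cut:g}")


if __name__ == "__main__":
    main()
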