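#!/usr/bin/env python
"""Render synthetic fluorescence video, extract kinetics, check the round trip.

Builds gamma-variate bolus curves for five ROIs, renders them into an 8-bit
frame stack, re-extracts the time–intensity traces from the stack, measures
the perfusion parameters, and reports the recovery error of each quantity
against the generating targets.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from icgperf.curve_kinetics import OnsetConfig, extract_parameters, roi_time_series
from icgperf.synthetic_data import generate_curve, generate_frame_stack


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(args.seed)
    targets, curves, rois = [], [], []
    for i in range(5):
        t_max = float(rng.uniform(6.0, 35.0))
        tr = float(rng.uniform(0.15, 0.5))
        f_max = float(rng.uniform(60.0, 180.0))
        targets.append((t_max, tr * t_max, f_max))
        curves.append(generate_curve((t_max, tr * t_max, f_max), duration_s=60.0,
                                     point_id=str(i + 1)))
        rois.append((str(i + 1), 12.0 + 13.0 * i, 32.0, 5.0))
    # noise-free rendering: on a long flat recirculation plateau, pixel noise
    # makes the first-attainment peak estimator ill-posed (the argmax wanders
    # across the plateau); 8-bit quantisation is kept
    stack = generate_frame_stack(curves, rois, frame_shape=(64, 80),
                                 background_au=4.0, noise_sd_au=0.0,
                                 seed=args.seed)

    rows = []
    for (t_max, t_half, f_max), (pid, x, y, r) in zip(targets, rois):
        trace = roi_time_series(stack.frames, stack.time_s, (x, y), r, point_id=pid)
        p = extract_parameters(trace, OnsetConfig(smooth_window_s=1.0))
        rows.append({"point_id": pid,
                     "t_max_target": t_max, "t_max_extracted": p.t_max_s,
                     "t_half_target": t_half, "t_half_extracted": p.t_half_s,
                     "f_max_target": f_max, "f_max_extracted": p.f_max_au,
                     "perfusion_tr": p.perfusion_tr,
                     "slope_au_per_s": p.slope_au_per_s})
    table = pd.DataFrame(rows)
    table.to_csv(args.out_dir / "curve_roundtrip.csv", index=False)

    err_t = (table.t_max_extracted - table.t_max_target).abs().max()
    err_h = (table.t_half_extracted - table.t_half_target).abs().max()
    print(table.round(2).to_string(index=False))
    print(f"worst T_MAX error {err_t:.2f} s, worst T_1/2MAX error {err_h:.2f} s "
          f"(sampling interval 0.25 s, 8-bit video)")


if __name__ == "__main__":
    main()
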