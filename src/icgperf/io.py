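"""File I/O: curve CSVs, assessment-point tables, TIFF frame stacks, ROI specs.

Curves travel as two-column CSV (``time_s,intensity_au``, one file per
point) or long-format CSV (``point_id,time_s,intensity_au``).  Frame stacks
are multi-page TIFF, one page per frame, with timestamps from a sidecar
``frame,time_s`` CSV or a constant frame rate.  ROI specs are
``point_id,x_px,y_px,radius_px`` CSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
import tifffile

from .curve_kinetics import FluorescenceCurve, PerfusionParameters
from .synthetic_data import FrameStack

PathLike = Union[str, Path]


def read_curves_csv(path: PathLike) -> dict[str, FluorescenceCurve]:
    """Read one or many curves from CSV (two-column or long format)."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"time_s", "intensity_au"} - cols:
        raise ValueError("curve CSV needs time_s and intensity_au columns")
    if "point_id" in cols:
        out = {}
        for pid, grp in df.groupby("point_id", sort=False):
            grp = grp.sort_values("time_s")
            out[str(pid)] = FluorescenceCurve(grp["time_s"].to_numpy(float),
                                              grp["intensity_au"].to_numpy(float),
                                              point_id=str(pid))
        return out
    name = Path(path).stem
    df = df.sort_values("time_s")
    return {name: FluorescenceCurve(df["time_s"].to_numpy(float),
                                    df["intensity_au"].to_numpy(float),
                                    point_id=name)}


def write_curves_csv(curves: Iterable[FluorescenceCurve], path: PathLike) -> None:
    """Write curves in long format (``point_id,time_s,intensity_au``)."""
    frames = [pd.DataFrame({"point_id": c.point_id, "time_s": c.time_s,
                            "intensity_au": c.intensity_au}) for c in curves]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def parameters_to_frame(params: Iterable[PerfusionParameters]) -> pd.DataFrame:
    return pd.DataFrame([{
        "point_id": p.point_id, "t_onset_s": p.t_onset_s, "t_max_s": p.t_max_s,
        "t_half_s": p.t_half_s, "perfusion_tr": p.perfusion_tr,
        "f_max_au": p.f_max_au, "slope_au_per_s": p.slope_au_per_s,
    } for p in params])


def read_points_csv(path: PathLike) -> pd.DataFrame:
    """Read an assessment-point table (parameters + StO2 + covariates)."""
    return pd.read_csv(path)


def read_roi_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"point_id", "x_px", "y_px", "radius_px"} - set(df.columns)
    if missing:
        raise ValueError(f"ROI CSV lacks columns: {sorted(missing)}")
    return df


def read_tiff_stack(path: PathLike, times_csv: Optional[PathLike] = None,
                    frame_rate_hz: Optional[float] = None,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Read a multi-page TIFF and its frame timestamps.

    Timestamps come from a ``frame,time_s`` sidecar CSV or, failing that,
    from a constant frame rate.
    """
    frames = tifffile.imread(str(path))
    if frames.ndim == 2:
        frames = frames[None, ...]
    n = frames.shape[0]
    if times_csv is not None:
        tdf = pd.read_csv(times_csv).sort_values("frame")
        if len(tdf) != n:
            raise ValueError("sidecar timestamp count does not match frame count")
        times = tdf["time_s"].to_numpy(float)
    elif frame_rate_hz:
        times = np.arange(n) / float(frame_rate_hz)
    else:
        raise ValueError("provide a timestamp sidecar CSV or a frame rate")
    return frames, times


def write_frame_stack(stack: FrameStack, tiff_path: PathLike,
                      times_csv: Optional[PathLike] = None,
                      roi_csv: Optional[PathLike] = None) -> None:
    tifffile.imwrite(str(tiff_path), stack.frames)
    if times_csv is not None:
        pd.DataFrame({"frame": np.arange(stack.time_s.size),
                      "time_s": stack.time_s}).to_csv(times_csv, index=False)
    if roi_csv is not None:
        stack.rois.to_csv(roi_csv, index=False)
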