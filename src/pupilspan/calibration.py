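"""False-pupil calibration: device area units -> absolute diameter in mm.

The eye tracker reports pupil size as an area in arbitrary device units.
Recording a series of artificial pupils of known diameter (2-12 mm) at the
participant's eye position gives node pairs; real pupil values are then
converted by linear interpolation after taking the square root of the
recorded area (area scales with diameter squared, so sqrt-area is close to
linear in diameter for any smooth device response).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .trace import SampleTrace

__all__ = ["CalibrationCurve", "fit_calibration", "apply_calibration"]

log = logging.getLogger(__name__)


@dataclass
class CalibrationCurve:
    """Interpolation nodes (sqrt recorded area, diameter mm), ascending."""

    sqrt_area: np.ndarray
    diameter_mm: np.ndarray

    def __post_init__(self) -> None:
        self.sqrt_area = np.asarray(self.sqrt_area, dtype=float)
        self.diameter_mm = np.asarray(self.diameter_mm, dtype=float)
        if self.sqrt_area.size < 2:
            raise ValueError("calibration curve needs at least 2 nodes")
        if np.any(np.diff(self.sqrt_area) <= 0) or \
           np.any(np.diff(self.diameter_mm) <= 0):
            raise ValueError("calibration nodes must be strictly increasing")


def fit_calibration(recordings: pd.DataFrame,
                    strict_range: bool = False) -> CalibrationCurve:
    """Build the sqrt-area -> mm interpolation curve.

    Parameters
    ----------
    recordings : DataFrame with columns ``true_mm`` and ``recorded_area``.
        Replicate rows for the same size are averaged in area space before
        taking the square root (unbiased under additive area noise).
    strict_range : bool
        When True, reject false-pupil sizes outside the 2-12 mm series.
    """
    req = {"true_mm", "recorded_area"}
    if not req.issubset(recordings.columns):
        raise ValueError(f"recordings must have columns {sorted(req)}")
    if np.any(recordings["recorded_area"].to_numpy() < 0):
        raise ValueError("recorded areas must be positive")
    mm = recordings["true_mm"].to_numpy(dtype=float)
    if strict_range and (mm.min() < 2.0 or mm.max() > 12.0):
        raise ValueError("false-pupil sizes outside the 2-12 mm series")
    mean_area = recordings.groupby("true_mm")["recorded_area"].mean()
    if len(mean_area) < 2:
        raise ValueError("need at least 2 distinct false-pupil sizes")
    sizes = mean_area.index.to_numpy(dtype=float)
    sqrt_area = np.sqrt(mean_area.to_numpy(dtype=float))
    d = np.diff(sqrt_area)
    if np.any(d <= 0):
        i = int(np.argmax(d <= 0))
        raise ValueError(
            "sqrt-area not strictly increasing between false pupils "
            f"{sizes[i]} mm and {sizes[i + 1]} mm")
    return CalibrationCurve(sqrt_area=sqrt_area, diameter_mm=sizes)


def _interp_extrapolate(x: np.ndarray, xp: np.ndarray,
                        fp: np.ndarray) -> np.ndarray:
    """Piecewise-linear interpolation, linear extrapolation from end segments."""
    y = np.interp(x, xp, fp)
    lo = x < xp[0]
    if np.any(lo):
        s = (fp[1] - fp[0]) / (xp[1] - xp[0])
        y[lo] = fp[0] + s * (x[lo] - xp[0])
    hi = x > xp[-1]
    if np.any(hi):
        s = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y[hi] = fp[-1] + s * (x[hi] - xp[-1])
    return y


def apply_calibration(curve: CalibrationCurve,
                      trace: SampleTrace) -> SampleTrace:
    """Convert a raw area-unit trace to pupil diameter in mm.

    Each sample maps through linear interpolation of sqrt(raw area) over
    the calibration nodes; values beyond the node range are linearly
    extrapolated from the terminal segments (child pupils can exceed the
    largest false pupil).  Negative raw areas on valid samples are marked
    invalid and logged; invalid samples stay invalid.
    """
    if trace.unit == "mm":
        raise ValueError("trace is already calibrated (unit == 'mm')")
    raw = trace.pupil
    valid = trace.valid.copy()
    neg = valid & (raw < 0)
    if np.any(neg):
        log.warning("%d valid samples with negative raw area marked invalid",
                    int(neg.sum()))
        valid[neg] = False
    sq = np.sqrt(np.clip(raw, 0.0, None))
    mm = _interp_extrapolate(sq, curve.sqrt_area, curve.diameter_mm)
    n_extrap = int(np.sum(valid & ((sq < curve.sqrt_area[0]) |
                                   (sq > curve.sqrt_area[-1]))))
    if valid.sum() and n_extrap / max(valid.sum(), 1) > 0.05:
        log.warning("%.1f%% of valid samples extrapolate beyond the "
                    "calibration range", 100.0 * n_extrap / valid.sum())
    return replace(trace, pupil=mm, valid=valid, unit="mm",
                   t=trace.t.copy(), gaze_x=trace.gaze_x.copy(),
                   gaze_y=trace.gaze_y.copy())
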