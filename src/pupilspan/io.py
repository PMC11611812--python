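"""Canonical file formats and run configuration.

All pipeline artifacts are plain TSV/CSV with documented headers:

* samples TSV: ``time_ms  gaze_x_deg  gaze_y_deg  pupil_raw  valid``
* events TSV: ``trial_id  condition  side  fp_on_ms  gap_on_ms  stim_on_ms``
  (plus ``participant_id`` in multi-participant files)
* participants TSV: ``id  age  sex  moca`` (empty moca = not administered)
* calibration TSV: ``true_mm  recorded_area``

The run configuration is a flat YAML file; every tunable constant of the
analysis (despike threshold, smoothing window, SRT windows, alpha, ...)
is a config field with the analysis default, and unknown keys are
rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trace import SampleTrace

__all__ = [
    "RunConfig", "load_config", "save_config",
    "read_samples", "write_samples", "read_events", "write_events",
    "read_participants", "write_participants",
    "read_calibration", "write_calibration",
]

SAMPLE_COLUMNS = ["time_ms", "gaze_x_deg", "gaze_y_deg", "pupil_raw", "valid"]
EVENT_COLUMNS = ["trial_id", "condition", "side",
                 "fp_on_ms", "gap_on_ms", "stim_on_ms"]


@dataclass
class RunConfig:
    """All analysis parameters with their standard defaults."""

    seed: int = 0
    # cleaning
    despike_threshold_mm_per_ms: float = 0.1
    smooth_half_window_samples: int = 25
    interp_max_ms: float = 200.0
    blink_pad_ms: float = 50.0
    # saccade detection / classification
    saccade_velocity_threshold_deg_s: float = 30.0
    saccade_min_duration_ms: float = 6.0
    srt_min_amplitude_deg: float = 2.0
    min_srt_ms: float = 90.0
    # measures
    baseline_window_ms: tuple[float, float] = (150.0, 200.0)
    onset_window_ms: float = 20.0
    onset_sustain_ms: float = 40.0
    dilation_window_ms: float = 50.0
    # participant screening
    moca_cutoff: float = 20.0
    min_viable_trials: int = 10
    # statistics
    alpha: float = 0.05
    loading_threshold: float = 0.3
    factor_method: str = "pearson"
    oblimin_gamma: float = 0.0
    # lifespan models
    gam_basis_dim: int = 10
    gam_grid_n: int = 200
    gam_draws: int = 10_000
    gam_deriv_eps_years: float = 0.1
    gam_min_obs: int = 50

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        d = dict(d)
        if "baseline_window_ms" in d:
            d["baseline_window_ms"] = tuple(d["baseline_window_ms"])
        return cls(**d)


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(d)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    d = dataclasses.asdict(cfg)
    d["baseline_window_ms"] = list(d["baseline_window_ms"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


# --------------------------------------------------------------------------
# samples


def write_samples(path: str | Path, trace: SampleTrace,
                  decimals: int = 4) -> None:
    df = pd.DataFrame({
        "time_ms": np.round(trace.t, decimals),
        "gaze_x_deg": np.round(trace.gaze_x, decimals),
        "gaze_y_deg": np.round(trace.gaze_y, decimals),
        "pupil_raw": np.round(trace.pupil, decimals),
        "valid": trace.valid.astype(int),
    })
    df.to_csv(path, sep="\t", index=False)


def read_samples(path: str | Path, rate: float | None = None,
                 unit: str = "area") -> SampleTrace:
    """Read a samples TSV into a trace; validates the sampling grid."""
    df = pd.read_csv(path, sep="\t")
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"samples file lacks column(s) {sorted(missing)}")
    t = df["time_ms"].to_numpy(dtype=float)
    if t.size >= 2:
        steps = np.diff(t)
        step = float(np.median(steps))
        bad = np.flatnonzero(np.abs(steps - step) > step + 1e-9)
        if bad.size:
            raise ValueError(
                f"irregular timestamps at row {int(bad[0]) + 1} "
                f"(step {steps[bad[0]]:.3f} ms, expected {step:.3f} ms)")
        inferred = 1000.0 / step
    else:
        inferred = rate or 500.0
    return SampleTrace(
        t=t,
        gaze_x=df["gaze_x_deg"].to_numpy(dtype=float),
        gaze_y=df["gaze_y_deg"].to_numpy(dtype=float),
        pupil=df["pupil_raw"].to_numpy(dtype=float),
        valid=df["valid"].to_numpy(dtype=bool),
        rate=rate or inferred, unit=unit)


# --------------------------------------------------------------------------
# events and participants


def write_events(path: str | Path, events: pd.DataFrame) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path, warn_only: bool = True) -> pd.DataFrame:
    """Read a trial-event table and validate the IPAST timeline.

    Fixation must last 1,000 ms and the gap 200 ms; deviations warn (so
    non-IPAST data can pass through) rather than fail.
    """
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events file lacks column(s) {sorted(missing)}")
    bad_cond = set(df["condition"].unique()) - {"PRO", "ANTI"}
    if bad_cond:
        raise ValueError(f"unknown condition value(s): {sorted(bad_cond)}")
    key = (["participant_id", "trial_id"] if "participant_id" in df.columns
           else ["trial_id"])
    if df.duplicated(key).any():
        raise ValueError("duplicate trial_id in events file")
    fix = df["gap_on_ms"] - df["fp_on_ms"]
    gap = df["stim_on_ms"] - df["gap_on_ms"]
    msg = None
    if not np.allclose(fix, 1000.0):
        msg = "fixation duration differs from the 1,000 ms IPAST timeline"
    elif not np.allclose(gap, 200.0):
        msg = "gap duration differs from the 200 ms IPAST timeline"
    if msg:
        if warn_only:
            warnings.warn(msg)
        else:
            raise ValueError(msg)
    return df


def write_participants(path: str | Path, participants: pd.DataFrame) -> None:
    participants.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_participants(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"id", "age", "sex"} - set(df.columns)
    if missing:
        raise ValueError(
            f"participants file lacks column(s) {sorted(missing)}")
    if "moca" not in df.columns:
        df["moca"] = np.nan
    bad_sex = set(df["sex"].unique()) - {"F", "M"}
    if bad_sex:
        raise ValueError(f"unknown sex value(s): {sorted(bad_sex)}")
    return df


def write_calibration(path: str | Path, recordings: pd.DataFrame) -> None:
    recordings.to_csv(path, sep="\t", index=False)


def read_calibration(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"true_mm", "recorded_area"} - set(df.columns)
    if missing:
        raise ValueError(
            f"calibration file lacks column(s) {sorted(missing)}")
    return df
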