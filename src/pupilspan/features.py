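"""The eight pupil measures of the IPAST fixation epoch.

The fixation-point (FP) evoked pupil response is summarized per trial by
baseline pupil size, response onset latency, constriction size, peak
constriction time, peak constriction velocity, dilation size, dilation
velocity at stimulus onset, and peak dilation velocity.  Per participant,
viable-trial medians are taken within condition, and a 14-variable row is
assembled for factor analysis: the six constriction/dilation measures
split by PRO/ANTI plus baseline size and onset latency pooled across
conditions (those two show no task modulation).

All extractors operate on whatever trace they are given; the caller
decides whether the trace has been despiked and smoothed.  Measures that
cannot be computed return NaN rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, fields

import numpy as np
import pandas as pd
from scipy import stats

from .trace import SampleTrace

__all__ = [
    "PupilMeasures", "MEASURE_NAMES", "CONDITION_SPLIT_MEASURES",
    "POOLED_MEASURES", "MEASURE_ROW_COLUMNS",
    "pupil_velocity", "baseline_size", "baseline_correct", "onset_latency",
    "constriction_features", "dilation_features", "extract_measures",
    "aggregate_participant",
]

MEASURE_NAMES = [
    "baseline_size", "onset_latency", "constriction_size",
    "peak_constriction_time", "peak_constriction_velocity",
    "dilation_size", "dilation_velocity", "peak_dilation_velocity",
]
# six measures kept separate by condition in the 14-variable row
CONDITION_SPLIT_MEASURES = [
    "constriction_size", "peak_constriction_velocity",
    "peak_constriction_time", "dilation_size", "dilation_velocity",
    "peak_dilation_velocity",
]
POOLED_MEASURES = ["baseline_size", "onset_latency"]
MEASURE_ROW_COLUMNS = (
    [f"{m}_{c}" for m in CONDITION_SPLIT_MEASURES for c in ("pro", "anti")]
    + POOLED_MEASURES)


@dataclass
class PupilMeasures:
    """Per-trial summary of the fixation-epoch pupil response.

    Times are ms relative to FP onset, sizes in mm, velocities in mm/s.
    """

    baseline_size: float = np.nan
    onset_latency: float = np.nan
    constriction_size: float = np.nan
    peak_constriction_time: float = np.nan
    peak_constriction_velocity: float = np.nan
    dilation_size: float = np.nan
    dilation_velocity: float = np.nan
    peak_dilation_velocity: float = np.nan

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def pupil_velocity(trace: SampleTrace) -> np.ndarray:
    """Pupil velocity in mm/s via central differences.

    One-sided differences at the trace ends; NaN wherever the sample or a
    neighbor involved in the difference is invalid.
    """
    p = trace.pupil
    n = p.size
    v = np.full(n, np.nan)
    if n < 2:
        return v
    dt_s = trace.dt / 1000.0
    v[1:-1] = (p[2:] - p[:-2]) / (2.0 * dt_s)
    v[0] = (p[1] - p[0]) / dt_s
    v[-1] = (p[-1] - p[-2]) / dt_s
    ok = trace.valid.copy()
    good = ok.copy()
    good[1:-1] &= ok[2:] & ok[:-2]
    if n >= 2:
        good[0] &= ok[1]
        good[-1] &= ok[-2]
    v[~good] = np.nan
    return v


def _window_mask(t: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (t >= lo) & (t <= hi)


def baseline_size(trace: SampleTrace, fp_on: float,
                  window_ms: tuple[float, float] = (150.0, 200.0)) -> float:
    """Mean pupil size 150-200 ms after FP onset (closed window).

    NaN if the window contains any invalid sample (the trial then drops
    out of baseline aggregation).
    """
    m = _window_mask(trace.t, fp_on + window_ms[0], fp_on + window_ms[1])
    if not m.any() or not trace.valid[m].all():
        return float("nan")
    return float(trace.pupil[m].mean())


def baseline_correct(trace: SampleTrace, baseline: float) -> SampleTrace:
    """Subtract the trial baseline from every sample."""
    if not np.isfinite(baseline):
        raise ValueError("baseline must be defined")
    return replace(trace, pupil=trace.pupil - baseline, t=trace.t.copy(),
                   gaze_x=trace.gaze_x.copy(), gaze_y=trace.gaze_y.copy(),
                   valid=trace.valid.copy())


def onset_latency(trace: SampleTrace, fp_on: float, stim_on: float,
                  window_ms: float = 20.0,
                  sustain_ms: float = 40.0,
                  alpha: float = 0.05,
                  baseline_window_ms: tuple[float, float] = (150.0, 200.0),
                  degenerate_eps: float = 1e-6) -> float:
    """Earliest time pupil velocity departs from the baseline epoch.

    A 20 ms window slides from 200 ms after FP onset; its velocities are
    tested against the mean baseline-epoch velocity (one-sample t-test,
    two-sided p < ``alpha``), and every window starting within the
    following ``sustain_ms`` must meet the same criterion.  When the
    baseline velocities have zero variance (noiseless traces) the test
    degenerates to an absolute mean-velocity threshold of
    ``degenerate_eps`` mm/ms.  Returns ms after FP onset, NaN when no
    qualifying window exists before stimulus onset.
    """
    v = pupil_velocity(trace)
    t = trace.t
    bm = _window_mask(t, fp_on + baseline_window_ms[0],
                      fp_on + baseline_window_ms[1])
    ref = v[bm]
    ref = ref[np.isfinite(ref)]
    if ref.size < 3:
        return float("nan")
    ref_mean, ref_sd = float(ref.mean()), float(ref.std(ddof=1))

    dt = trace.dt
    wn = max(int(round(window_ms / dt)), 2)
    i_first = int(np.searchsorted(t, fp_on + 200.0))
    i_last = int(np.searchsorted(t, stim_on - window_ms, side="right"))
    if i_last <= i_first or i_last + wn > v.size:
        return float("nan")
    windows = np.lib.stride_tricks.sliding_window_view(
        v, wn)[i_first:i_last]
    with np.errstate(invalid="ignore"):
        means = windows.mean(axis=1)        # NaN when any sample invalid
        sds = windows.std(axis=1, ddof=1)
    if ref_sd == 0.0:
        # degenerate (noise-free) reference: absolute threshold in mm/ms
        sig = np.abs(means - ref_mean) / 1000.0 > degenerate_eps
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            tstat = (means - ref_mean) / (sds / np.sqrt(wn))
            pvals = 2.0 * stats.t.sf(np.abs(tstat), wn - 1)
        sig = pvals < alpha
    sig = np.where(np.isfinite(means), sig, False)
    n_sustain = max(int(round(sustain_ms / dt)), 1)
    # window at i plus every window starting within the next sustain_ms
    # (truncated at the search end) must all be significant
    ok = sig.copy()
    for j in range(1, n_sustain + 1):
        ok[:-j] &= sig[j:]
    hits = np.flatnonzero(ok)
    if hits.size == 0:
        return float("nan")
    return float(t[i_first + hits[0]] - fp_on)


def constriction_features(trace: SampleTrace, fp_on: float, stim_on: float,
                          baseline: float,
                          search_floor_ms: float = 200.0
                          ) -> tuple[float, float, float]:
    """(constriction_size, peak_constriction_time, peak_constriction_velocity).

    Peak constriction is the pupil minimum over
    ``(fp_on + search_floor_ms, stim_on]`` (the floor excludes pre-response
    noise minima); size is baseline minus that minimum; peak constriction
    velocity is the minimum velocity over ``(fp_on, peak_time]``.  A
    monotone-dilating trace (minimum at the window start) is degenerate and
    yields NaNs.
    """
    t = trace.t
    m = (t > fp_on + search_floor_ms) & (t <= stim_on)
    if not m.any() or not np.isfinite(baseline):
        return (np.nan, np.nan, np.nan)
    p = np.where(trace.valid, trace.pupil, np.nan)
    seg = p[m]
    if np.all(np.isnan(seg)):
        return (np.nan, np.nan, np.nan)
    i_rel = int(np.nanargmin(seg))
    if i_rel == 0:
        return (np.nan, np.nan, np.nan)  # degenerate: no constriction dip
    idx = np.flatnonzero(m)[i_rel]
    peak_time_abs = float(t[idx])
    size = float(baseline - p[idx])
    v = pupil_velocity(trace)
    vm = (t > fp_on) & (t <= peak_time_abs)
    vel_seg = v[vm]
    pcv = float(np.nanmin(vel_seg)) if np.any(np.isfinite(vel_seg)) else np.nan
    return (size, peak_time_abs - fp_on, pcv)


def dilation_features(trace: SampleTrace, peak_time_abs: float,
                      stim_on: float,
                      window_ms: float = 50.0) -> tuple[float, float, float]:
    """(dilation_size, dilation_velocity, peak_dilation_velocity).

    Dilation size = mean pupil over the closed [stim_on - 50, stim_on]
    window minus the pupil at peak constriction; dilation velocity = mean
    velocity over the same window; peak dilation velocity = maximum
    velocity over (peak_time, stim_on].  Degenerate (NaN) when the peak
    falls within the pre-stimulus window or the window holds invalid
    samples.
    """
    t = trace.t
    if not np.isfinite(peak_time_abs) or \
            peak_time_abs >= stim_on - window_ms:
        return (np.nan, np.nan, np.nan)
    wm = _window_mask(t, stim_on - window_ms, stim_on)
    if not wm.any() or not trace.valid[wm].all():
        return (np.nan, np.nan, np.nan)
    i_peak = int(np.argmin(np.abs(t - peak_time_abs)))
    if not trace.valid[i_peak]:
        return (np.nan, np.nan, np.nan)
    size = float(trace.pupil[wm].mean() - trace.pupil[i_peak])
    v = pupil_velocity(trace)
    vel = float(np.nanmean(v[wm]))
    pm = (t > peak_time_abs) & (t <= stim_on)
    seg = v[pm]
    peak_vel = float(np.nanmax(seg)) if np.any(np.isfinite(seg)) else np.nan
    return (size, vel, peak_vel)


def extract_measures(trace: SampleTrace, fp_on: float,
                     stim_on: float, **kwargs) -> PupilMeasures:
    """All eight measures for one (viable) trial."""
    b = baseline_size(trace, fp_on)
    lat = onset_latency(trace, fp_on, stim_on, **kwargs)
    cs, pct, pcv = constriction_features(trace, fp_on, stim_on, b)
    peak_abs = fp_on + pct if np.isfinite(pct) else np.nan
    ds, dv, pdv = dilation_features(trace, peak_abs, stim_on)
    return PupilMeasures(
        baseline_size=b, onset_latency=lat, constriction_size=cs,
        peak_constriction_time=pct, peak_constriction_velocity=pcv,
        dilation_size=ds, dilation_velocity=dv, peak_dilation_velocity=pdv)


def aggregate_participant(trial_measures: pd.DataFrame
                          ) -> tuple[pd.DataFrame, pd.Series, bool]:
    """Condition medians and the 14-variable analysis row.

    Parameters
    ----------
    trial_measures : DataFrame
        One row per viable trial, with a ``condition`` column (PRO/ANTI)
        and the eight measure columns; NaNs allowed per measure.

    Returns
    -------
    medians : DataFrame indexed by condition, one column per measure.
    row : Series with the 14 analysis variables (six measures split by
        condition plus baseline size and onset latency pooled).
    complete : False when any of the 14 entries is undefined; such a
        participant is excluded from factor analysis.
    """
    missing = set(MEASURE_NAMES) - set(trial_measures.columns)
    if missing:
        raise ValueError(f"trial_measures lacks columns {sorted(missing)}")
    medians = trial_measures.groupby("condition")[MEASURE_NAMES].median()
    row: dict[str, float] = {}
    for m in CONDITION_SPLIT_MEASURES:
        for cond in ("PRO", "ANTI"):
            key = f"{m}_{cond.lower()}"
            row[key] = (float(medians.loc[cond, m])
                        if cond in medians.index else np.nan)
    for m in POOLED_MEASURES:
        row[m] = float(trial_measures[m].median())
    series = pd.Series(row)[MEASURE_ROW_COLUMNS]
    complete = bool(np.isfinite(series.to_numpy()).all())
    return medians, series, complete
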