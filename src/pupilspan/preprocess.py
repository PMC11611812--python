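"""Trace cleaning, event detection, trial classification and exclusions.

Implements the screening applied before any pupil measure is extracted:

* despiking (pupil change exceeding 0.1 mm/ms invalidated), gap
  interpolation and a +/-25-sample moving-average smooth;
* blink detection from tracker validity, padded 50 ms on each side;
* velocity-threshold saccade detection on the gaze channels;
* saccadic reaction time (SRT) and latency classification — anticipatory
  [-110, 90) ms, express [90, 140) ms, regular [140, 800] ms relative to
  stimulus onset — plus direction-error marking;
* pupil-viability screening (no blink or >2 deg saccade during the
  fixation-to-stimulus period, SRT > 90 ms, correct direction) and the
  participant-level rules (MoCA >= 20 for adults, at least 10 viable
  correct PRO and ANTI trials).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .trace import SampleTrace

__all__ = [
    "SaccadeEvent", "TrialRecord", "ParticipantRecord",
    "despike_and_smooth", "detect_blinks", "detect_saccades",
    "compute_srt", "classify_trial", "flag_pupil_viability",
    "filter_participants",
    "ANTICIPATORY_WINDOW", "EXPRESS_WINDOW", "REGULAR_WINDOW",
]

log = logging.getLogger(__name__)

# SRT windows (ms relative to stimulus onset), half-open except the last.
ANTICIPATORY_WINDOW = (-110.0, 90.0)
EXPRESS_WINDOW = (90.0, 140.0)
REGULAR_WINDOW = (140.0, 800.0)


@dataclass
class SaccadeEvent:
    onset_ms: float
    offset_ms: float
    amplitude: float       # deg, Euclidean displacement onset -> offset
    direction: str         # "left" | "right"
    peak_velocity: float   # deg/s

    def __post_init__(self) -> None:
        if self.offset_ms <= self.onset_ms:
            raise ValueError("saccade offset must exceed onset")
        if self.amplitude < 0:
            raise ValueError("saccade amplitude must be >= 0")


@dataclass
class TrialRecord:
    trial_id: int
    condition: str          # "PRO" | "ANTI"
    side: str               # "left" | "right"
    fp_on: float            # ms, session time
    gap_on: float
    stim_on: float
    srt: float | None = None
    latency_class: str = "none"   # anticipatory | express | regular | none
    is_direction_error: bool = False
    pupil_viable: bool = False
    exclusion_reasons: set[str] = field(default_factory=set)


@dataclass
class ParticipantRecord:
    id: str
    age: float
    sex: str
    moca: float | None = None
    trials: list[TrialRecord] = field(default_factory=list)
    retained: bool = False
    exclusion_reasons: set[str] = field(default_factory=set)


# --------------------------------------------------------------------------
# cleaning


def _masked_boxcar(x: np.ndarray, valid: np.ndarray, half: int) -> np.ndarray:
    """Centered mean over +/-half samples using valid samples only.

    The effective window shrinks at the edges and across invalid runs
    because invalid samples simply drop out of the average.
    """
    kernel = np.ones(2 * half + 1)
    num = np.convolve(np.where(valid, x, 0.0), kernel, mode="same")
    den = np.convolve(valid.astype(float), kernel, mode="same")
    out = x.copy()
    ok = valid & (den > 0)
    out[ok] = num[ok] / den[ok]
    return out


def despike_and_smooth(trace: SampleTrace,
                       rate_threshold_mm_per_ms: float = 0.1,
                       interp_max_ms: float = 200.0,
                       half_window: int = 25) -> SampleTrace:
    """Remove transient pupil artifacts and smooth the trace.

    Samples whose pupil change from the previous valid sample exceeds
    ``rate_threshold_mm_per_ms`` are invalidated; invalid gaps no longer
    than ``interp_max_ms`` are linearly interpolated (and revalidated);
    finally every valid sample is replaced by the mean of valid samples
    within +/-``half_window`` samples.  A fully invalid trace passes
    through unchanged.
    """
    if trace.unit != "mm":
        raise ValueError("despike threshold is defined on a calibrated trace")
    out = trace.copy()
    p, valid = out.pupil, out.valid
    if not valid.any():
        return out
    dt = out.dt

    # despike: compare each valid sample against the previous valid sample
    idx = np.flatnonzero(valid)
    dp = np.abs(np.diff(p[idx])) / (np.diff(out.t[idx]))
    spike = idx[1:][dp > rate_threshold_mm_per_ms]
    valid[spike] = False

    # linear interpolation across short invalid gaps
    lab, n_runs = ndimage.label(~valid)
    for run in range(1, n_runs + 1):
        run_idx = np.flatnonzero(lab == run)
        i0, i1 = run_idx[0], run_idx[-1]
        if i0 == 0 or i1 == len(p) - 1:
            continue  # edge gaps: nothing to anchor the interpolation
        span = (i1 - i0 + 1) * dt
        if span <= interp_max_ms:
            p[run_idx] = np.interp(run_idx, [i0 - 1, i1 + 1],
                                   [p[i0 - 1], p[i1 + 1]])
            valid[run_idx] = True

    out.pupil = _masked_boxcar(p, valid, half_window)
    out.valid = valid
    return out


# --------------------------------------------------------------------------
# events


def detect_blinks(trace: SampleTrace,
                  pad_ms: float = 50.0) -> list[tuple[float, float]]:
    """Blinks = maximal invalid runs padded by ``pad_ms`` on both sides.

    Padded intervals that overlap are merged (eyelid artifacts flank the
    tracker's reported data loss).
    """
    invalid = ~trace.valid
    if not invalid.any():
        return []
    lab, n_runs = ndimage.label(invalid)
    raw = []
    for run in range(1, n_runs + 1):
        ri = np.flatnonzero(lab == run)
        raw.append((trace.t[ri[0]] - pad_ms, trace.t[ri[-1]] + pad_ms))
    raw.sort()
    merged = [raw[0]]
    for on, off in raw[1:]:
        if on <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], off))
        else:
            merged.append((on, off))
    return merged


def _moving_average(x: np.ndarray, n: int) -> np.ndarray:
    kernel = np.ones(n) / n
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def detect_saccades(trace: SampleTrace,
                    velocity_threshold: float = 30.0,
                    min_duration_ms: float = 6.0,
                    smooth_samples: int = 5) -> list[SaccadeEvent]:
    """Velocity-threshold saccade detection on the gaze channels.

    2-D gaze speed (central differences on lightly smoothed position) must
    exceed ``velocity_threshold`` deg/s for at least ``min_duration_ms``.
    Amplitude is the Euclidean displacement between the samples flanking
    the event; direction is the sign of the horizontal displacement.
    """
    if len(trace) < 3:
        return []
    gx = _moving_average(trace.gaze_x, smooth_samples)
    gy = _moving_average(trace.gaze_y, smooth_samples)
    dt_s = trace.dt / 1000.0
    vx = np.gradient(gx, dt_s)
    vy = np.gradient(gy, dt_s)
    speed = np.hypot(vx, vy)
    above = speed > velocity_threshold
    if not above.any():
        return []
    lab, n_runs = ndimage.label(above)
    events: list[SaccadeEvent] = []
    n = len(trace)
    for run in range(1, n_runs + 1):
        ri = np.flatnonzero(lab == run)
        i0, i1 = int(ri[0]), int(ri[-1])
        if trace.t[i1] - trace.t[i0] < min_duration_ms:
            continue
        j0, j1 = max(i0 - 1, 0), min(i1 + 1, n - 1)
        dx = gx[j1] - gx[j0]
        dy = gy[j1] - gy[j0]
        events.append(SaccadeEvent(
            onset_ms=float(trace.t[i0]), offset_ms=float(trace.t[i1]),
            amplitude=float(np.hypot(dx, dy)),
            direction="right" if dx >= 0 else "left",
            peak_velocity=float(speed[ri].max())))
    return events


# --------------------------------------------------------------------------
# trial classification


def compute_srt(trial: TrialRecord, saccades: list[SaccadeEvent],
                min_amplitude: float = 2.0,
                window_ms: tuple[float, float] = (-110.0, 800.0)
                ) -> float | None:
    """SRT = onset of the first >=2 deg saccade in the response window.

    The window spans [stim_on - 110, stim_on + 800] ms so anticipatory
    saccades receive a (negative) SRT.  Returns None when no qualifying
    saccade exists.
    """
    lo = trial.stim_on + window_ms[0]
    hi = trial.stim_on + window_ms[1]
    for ev in sorted(saccades, key=lambda e: e.onset_ms):
        if ev.amplitude >= min_amplitude and lo <= ev.onset_ms <= hi:
            return float(ev.onset_ms - trial.stim_on)
    return None


def _first_response_saccade(trial: TrialRecord,
                            saccades: list[SaccadeEvent],
                            min_amplitude: float = 2.0
                            ) -> SaccadeEvent | None:
    lo, hi = trial.stim_on - 110.0, trial.stim_on + 800.0
    for ev in sorted(saccades, key=lambda e: e.onset_ms):
        if ev.amplitude >= min_amplitude and lo <= ev.onset_ms <= hi:
            return ev
    return None


def classify_trial(trial: TrialRecord,
                   saccades: list[SaccadeEvent]) -> TrialRecord:
    """Assign latency class and direction-error flag from the first saccade.

    Latency classes partition [-110, 800]: anticipatory [-110, 90),
    express [90, 140), regular [140, 800].  The first post-stimulus
    saccade's direction is compared against the instructed direction
    (toward the stimulus for PRO, away for ANTI).
    """
    srt = compute_srt(trial, saccades)
    trial.srt = srt
    if srt is None:
        trial.latency_class = "none"
        trial.is_direction_error = False
        return trial
    if ANTICIPATORY_WINDOW[0] <= srt < ANTICIPATORY_WINDOW[1]:
        trial.latency_class = "anticipatory"
    elif EXPRESS_WINDOW[0] <= srt < EXPRESS_WINDOW[1]:
        trial.latency_class = "express"
    elif REGULAR_WINDOW[0] <= srt <= REGULAR_WINDOW[1]:
        trial.latency_class = "regular"
    else:  # pragma: no cover - window and classes span the same range
        trial.latency_class = "none"
    ev = _first_response_saccade(trial, saccades)
    correct = trial.side if trial.condition == "PRO" else \
        ("left" if trial.side == "right" else "right")
    trial.is_direction_error = ev is not None and ev.direction != correct
    return trial


def flag_pupil_viability(trial: TrialRecord,
                         blinks: list[tuple[float, float]],
                         saccades: list[SaccadeEvent],
                         min_srt_ms: float = 90.0,
                         saccade_amp_threshold: float = 2.0) -> TrialRecord:
    """Screen a classified trial for pupil analysis.

    Viable iff no blink overlaps the fixation-to-stimulus period, no
    saccade larger than 2 deg occurs in that period, SRT is defined and
    exceeds 90 ms, and the trial is not a direction error.  Every failed
    rule is recorded in ``exclusion_reasons``.
    """
    reasons: set[str] = set()
    for on, off in blinks:
        if on <= trial.stim_on and off >= trial.fp_on:
            reasons.add("blink_in_fixation")
            break
    for ev in saccades:
        if ev.amplitude > saccade_amp_threshold and \
                ev.onset_ms <= trial.stim_on and ev.offset_ms >= trial.fp_on:
            reasons.add("saccade_in_fixation")
            break
    if trial.srt is None:
        reasons.add("no_saccade")
    elif trial.srt <= min_srt_ms:
        reasons.add("anticipatory")
    if trial.is_direction_error:
        reasons.add("direction_error")
    trial.exclusion_reasons = reasons
    trial.pupil_viable = not reasons
    return trial


# --------------------------------------------------------------------------
# participant-level screening


def filter_participants(participants: list[ParticipantRecord],
                        min_viable_trials: int = 10,
                        moca_cutoff: float = 20.0
                        ) -> list[ParticipantRecord]:
    """Apply the participant inclusion rules in place and return the list.

    Retained iff MoCA (when administered) is at or above the cut-off and
    the participant has at least ``min_viable_trials`` viable correct
    trials in each condition.
    """
    n_retained = 0
    for p in participants:
        reasons: set[str] = set()
        if p.moca is not None and not np.isnan(p.moca) and \
                p.moca < moca_cutoff:
            reasons.add("low_moca")
        n_pro = sum(1 for t in p.trials
                    if t.pupil_viable and t.condition == "PRO")
        n_anti = sum(1 for t in p.trials
                     if t.pupil_viable and t.condition == "ANTI")
        if n_pro < min_viable_trials or n_anti < min_viable_trials:
            reasons.add("insufficient_viable_trials")
        p.exclusion_reasons = reasons
        p.retained = not reasons
        n_retained += p.retained
    log.info("participant screening: %d retained / %d enrolled",
             n_retained, len(participants))
    return participants
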