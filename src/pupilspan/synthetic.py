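"""Synthetic IPAST cohorts with known ground truth.

The interleaved pro-/anti-saccade task (IPAST) presents a central fixation
point (FP) for 1,000 ms, removes it for a 200 ms gap, then lights a
peripheral stimulus 10 deg left or right.  The pupil constricts in response
to FP onset and then dilates until stimulus appearance; dilation is larger
before anti-saccades than pro-saccades, and that task modulation shrinks
with age.  This module generates cohorts with exactly that structure —
500 Hz traces, trial events, demographics, false-pupil calibration
recordings and per-participant saccade-measure tables with a latent
four-factor structure — so every downstream stage can be tested against
known parameters.

All generators are pure functions of their configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .trace import SampleTrace

__all__ = [
    "CohortConfig",
    "TrialParams",
    "AgeSchedule",
    "Cohort",
    "SessionData",
    "default_age_schedule",
    "default_device_map",
    "generate_cohort",
    "generate_trial_trace",
    "generate_calibration_recordings",
    "generate_saccade_measure_table",
    "generate_measure_rows",
    "SACCADE_MEASURES",
    "PUPIL_ROW_COLUMNS",
    "DEFAULT_SACCADE_LOADINGS",
    "DEFAULT_PUPIL_LOADINGS",
]

# IPAST timeline (ms within a trial): FP on at 0 for 1,000 ms, 200 ms gap,
# stimulus at 1,200 ms; total trial duration 3.2 s.
FIX_MS = 1000.0
GAP_MS = 200.0
STIM_MS = FIX_MS + GAP_MS
TRIAL_MS = 3200.0
STIM_ECC_DEG = 10.0


# --------------------------------------------------------------------------
# configuration


@dataclass
class CohortConfig:
    """Cohort-level generator settings.

    ``trials_per_block`` must be divisible by 4 so that conditions (PRO,
    ANTI) and stimulus sides (left, right) can be balanced exactly within
    each block.
    """

    n_participants: int = 50
    age_range: tuple[float, float] = (5.0, 93.0)
    sampling_rate: float = 500.0
    trials_per_block: int = 120
    n_blocks: int = 2
    seed: int = 0
    noise_sd: float = 0.02           # mm, additive Gaussian pupil noise
    param_jitter: float = 1.0        # scales between-trial parameter spread
    blink_rate: float = 0.10         # per-trial blink probability
    direction_error_rate: float | None = None  # None -> use AgeSchedule
    gaze_noise_sd: float = 0.05      # deg
    ages: Sequence[float] | None = None  # census list overriding uniform draw

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if self.trials_per_block % 4 != 0:
            raise ValueError(
                "trials_per_block must be divisible by 4 to balance "
                "conditions and sides")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy lo < hi")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.blink_rate <= 1:
            raise ValueError("blink_rate must be a probability")


@dataclass
class TrialParams:
    """Ground-truth parameters of one generated trial."""

    baseline_mm: float
    constriction_latency_ms: float
    constriction_amplitude_mm: float
    constriction_peak_ms: float
    dilation_rate_mm_per_s: float
    condition: str                   # "PRO" | "ANTI"
    stimulus_side: str               # "left" | "right"
    srt_ms: float
    is_direction_error: bool = False
    blink_times: list[float] = field(default_factory=list)  # onsets, ms
    blink_duration_ms: float = 150.0

    def validate(self) -> None:
        if self.constriction_amplitude_mm < 0:
            raise ValueError("constriction_amplitude_mm must be >= 0")
        if self.constriction_peak_ms <= self.constriction_latency_ms:
            raise ValueError("constriction_peak_ms must exceed latency")
        if not 2.0 <= self.baseline_mm <= 12.0:
            raise ValueError("baseline_mm must lie within 2-12 mm")
        if self.condition not in ("PRO", "ANTI"):
            raise ValueError("condition must be PRO or ANTI")
        if self.stimulus_side not in ("left", "right"):
            raise ValueError("stimulus_side must be left or right")
        for b in self.blink_times:
            if not 0 <= b < TRIAL_MS:
                raise ValueError("blink_times must lie within the trial span")


@dataclass
class AgeSchedule:
    """Age-dependent generative parameters.

    Each field maps age (years) to a trial-parameter mean.  The defaults
    emulate the qualitative lifespan trends of the IPAST pupil response:
    baseline pupil size declines with age, the dilation component weakens
    with age, and the ANTI-PRO dilation gap (the task modulation) shrinks
    with age while staying non-negative.
    """

    baseline_mm: Callable[[float], float]
    constriction_amplitude_mm: Callable[[float], float]
    pro_dilation_rate: Callable[[float], float]       # mm/s
    anti_effect_gap: Callable[[float], float]         # mm/s, ANTI - PRO
    srt_mean: Callable[[float, str], float]           # (age, condition) -> ms
    error_rate: Callable[[float, str], float]         # (age, condition) -> prob
    sex_baseline_gap: Callable[[float], float] = lambda age: 0.0  # F - M, mm
    # mm by which the FP-evoked constriction is weaker on ANTI trials
    anti_constriction_gap: Callable[[float], float] = lambda age: 0.0

    def dilation_rate(self, age: float, condition: str) -> float:
        base = self.pro_dilation_rate(age)
        if condition == "ANTI":
            return base + self.anti_effect_gap(age)
        return base

    def validate(self, ages: np.ndarray) -> None:
        base = np.array([self.baseline_mm(a) for a in ages])
        if np.any(np.diff(base) > 1e-9):
            raise ValueError("baseline_mm must be nonincreasing with age")
        gap = np.array([self.anti_effect_gap(a) for a in ages])
        if np.any(gap < -1e-12):
            raise ValueError("anti_effect_gap must keep ANTI >= PRO dilation")
        if np.any(np.diff(gap) > 1e-9):
            raise ValueError("anti_effect_gap must be nonincreasing with age")


def default_age_schedule() -> AgeSchedule:
    """Lifespan trends used by the cohort generator.

    Baseline declines from ~7.4 mm in young children toward ~4.7 mm in the
    oldest participants; the pro-saccade dilation rate declines steeply to
    age 20 then slowly after; the ANTI-PRO dilation gap decays
    exponentially with age; SRT follows a U-shape with ANTI slower than
    PRO; anti-saccade direction errors are high in children, low in young
    adults and elevated again in old age.
    """

    def baseline(age: float) -> float:
        return 7.5 - 0.031 * (age - 5.0)

    def amplitude(age: float) -> float:
        return max(0.55 - 0.0015 * age, 0.05)

    def pro_rate(age: float) -> float:
        return max(0.70 - 0.018 * min(age, 20.0) - 0.002 * max(age - 20.0, 0.0),
                   0.05)

    def gap(age: float) -> float:
        return 0.20 * np.exp(-age / 40.0)

    def constriction_gap(age: float) -> float:
        # ANTI constriction weaker than PRO, shrinking with age
        return 0.06 * np.exp(-age / 40.0)

    def srt_mean(age: float, condition: str) -> float:
        base = 330.0 - 5.0 * min(age - 5.0, 17.0) + 1.2 * max(age - 22.0, 0.0)
        return base + (60.0 if condition == "ANTI" else 0.0)

    def error_rate(age: float, condition: str) -> float:
        if condition == "PRO":
            return 0.05
        u = 0.12 + 0.18 * np.exp(-(age - 5.0) / 10.0) \
            + 0.10 / (1.0 + np.exp(-(age - 65.0) / 6.0))
        return min(u, 0.6)

    def sex_gap(age: float) -> float:
        # females smaller than males before ~18 years, no difference after
        return -0.35 if age < 18.0 else 0.0

    return AgeSchedule(
        baseline_mm=baseline,
        constriction_amplitude_mm=amplitude,
        pro_dilation_rate=pro_rate,
        anti_effect_gap=gap,
        anti_constriction_gap=constriction_gap,
        srt_mean=srt_mean,
        error_rate=error_rate,
        sex_baseline_gap=sex_gap,
    )


def default_device_map(diameter_mm: np.ndarray | float):
    """Tracker model: recorded pupil area in device units for a diameter.

    Quadratic in diameter, so the square root of recorded area is exactly
    linear in mm and the piecewise-linear calibration is exact everywhere.
    """
    d = np.asarray(diameter_mm, dtype=float)
    return 25.0 * d ** 2


# --------------------------------------------------------------------------
# single-trial trace


def _raised_cosine_position(t_ms: np.ndarray, onset_ms: float,
                            duration_ms: float) -> np.ndarray:
    """Unit displacement profile with a raised-cosine velocity shape."""
    u = np.clip((t_ms - onset_ms) / duration_ms, 0.0, 1.0)
    return u - np.sin(2.0 * np.pi * u) / (2.0 * np.pi)


def _main_sequence_peak_velocity(amplitude_deg: float) -> float:
    """Saccadic main sequence: Vp = 500 (1 - exp(-A / 15)) deg/s."""
    return 500.0 * (1.0 - np.exp(-amplitude_deg / 15.0))


def generate_trial_trace(params: TrialParams, config: CohortConfig,
                         rng: np.random.Generator | None = None) -> SampleTrace:
    """Simulate one IPAST trial's 500 Hz trace, pupil in mm.

    The pupil is flat at baseline until the constriction latency, follows a
    half-cosine pulse down to ``baseline - amplitude`` at the constriction
    peak, then dilates as a linear ramp (``dilation_rate`` mm/s) to the end
    of the trial.  Gaze fixates near 0 deg and executes one main-sequence
    saccade at ``STIM_MS + srt_ms``.  Blinks invalidate samples and add
    +/-0.5 mm artifact spikes on the flanking samples.
    """
    params.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dt = 1000.0 / config.sampling_rate
    t = np.arange(0.0, TRIAL_MS, dt)
    n = t.size

    b = params.baseline_mm
    a = params.constriction_amplitude_mm
    lat = params.constriction_latency_ms
    peak = params.constriction_peak_ms
    r = params.dilation_rate_mm_per_s

    pupil = np.full(n, b)
    rise = (t >= lat) & (t <= peak)
    pupil[rise] = b - a * 0.5 * (1.0 - np.cos(np.pi * (t[rise] - lat) / (peak - lat)))
    after = t > peak
    pupil[after] = b - a + r * (t[after] - peak) / 1000.0
    if config.noise_sd > 0:
        pupil += rng.normal(0.0, config.noise_sd, n)

    # gaze: fixation noise plus one stimulus-driven saccade
    gx = rng.normal(0.0, config.gaze_noise_sd, n)
    gy = rng.normal(0.0, config.gaze_noise_sd, n)
    toward = 1.0 if params.stimulus_side == "right" else -1.0
    correct = toward if params.condition == "PRO" else -toward
    direction = -correct if params.is_direction_error else correct
    amp = STIM_ECC_DEG
    vp = _main_sequence_peak_velocity(amp)
    dur = 2.0 * amp / vp * 1000.0  # ms; raised-cosine: mean vel = Vp / 2
    onset = STIM_MS + params.srt_ms
    gx = gx + direction * amp * _raised_cosine_position(t, onset, dur)

    valid = np.ones(n, dtype=bool)
    for b_on in params.blink_times:
        if not 0 <= b_on < TRIAL_MS:
            raise ValueError("blink_times must lie within the trace span")
        b_off = min(b_on + params.blink_duration_ms, TRIAL_MS - dt)
        i0 = int(np.searchsorted(t, b_on))
        i1 = int(np.searchsorted(t, b_off, side="right"))
        valid[i0:i1] = False
        # eyelid artifact spikes flanking the tracker loss
        if i0 - 1 >= 0:
            pupil[i0 - 1] += 0.5
        if i1 < n:
            pupil[i1] -= 0.5

    return SampleTrace(t=t, gaze_x=gx, gaze_y=gy, pupil=pupil, valid=valid,
                       rate=config.sampling_rate, unit="mm")


# --------------------------------------------------------------------------
# cohort


@dataclass
class SessionData:
    """One participant's recording: concatenated trial traces + events."""

    trace: SampleTrace               # pupil in device area units
    events: pd.DataFrame             # trial_id, condition, side, fp/gap/stim onsets
    truth: pd.DataFrame              # per-trial TrialParams fields


@dataclass
class Cohort:
    participants: pd.DataFrame       # id, age, sex, moca
    sessions: dict[str, SessionData]
    calibration: pd.DataFrame        # true_mm, recorded_area
    saccade_measures: pd.DataFrame   # 12 measures per participant
    saccade_latents: pd.DataFrame    # latent 4-factor scores per participant
    config: CohortConfig


def _interleaved_conditions(rng: np.random.Generator, trials_per_block: int,
                            n_blocks: int) -> tuple[np.ndarray, np.ndarray]:
    """Pseudo-random interleaving, conditions and sides exactly balanced."""
    conds, sides = [], []
    per_cell = trials_per_block // 4
    for _ in range(n_blocks):
        cells = [(c, s) for c in ("PRO", "ANTI") for s in ("left", "right")
                 for _ in range(per_cell)]
        order = rng.permutation(len(cells))
        for i in order:
            conds.append(cells[i][0])
            sides.append(cells[i][1])
    return np.array(conds), np.array(sides)


def _draw_trial_params(rng: np.random.Generator, age: float, sex: str,
                       condition: str, side: str, schedule: AgeSchedule,
                       config: CohortConfig) -> TrialParams:
    j = config.param_jitter
    base = schedule.baseline_mm(age)
    if sex == "F":
        base += schedule.sex_baseline_gap(age)
    base = float(np.clip(base + j * rng.normal(0.0, 0.15), 2.2, 11.8))
    amp = max(schedule.constriction_amplitude_mm(age)
              + j * rng.normal(0.0, 0.04), 0.02)
    if condition == "ANTI":
        amp = max(amp - schedule.anti_constriction_gap(age), 0.02)
    lat = float(np.clip(350.0 + j * rng.normal(0.0, 25.0), 260.0, 480.0))
    peak = float(np.clip(900.0 + j * rng.normal(0.0, 40.0),
                         lat + 200.0, 1140.0))
    rate = max(schedule.dilation_rate(age, condition)
               + j * rng.normal(0.0, 0.05), 0.0)
    srt = float(np.clip(schedule.srt_mean(age, condition)
                        + j * rng.normal(0.0, 60.0), -100.0, 790.0))
    err_p = (config.direction_error_rate
             if config.direction_error_rate is not None
             else schedule.error_rate(age, condition))
    is_err = bool(rng.random() < err_p)
    blinks: list[float] = []
    if rng.random() < config.blink_rate:
        blinks.append(float(rng.uniform(100.0, 2700.0)))
    return TrialParams(
        baseline_mm=base, constriction_latency_ms=lat,
        constriction_amplitude_mm=amp, constriction_peak_ms=peak,
        dilation_rate_mm_per_s=rate, condition=condition, stimulus_side=side,
        srt_ms=srt, is_direction_error=is_err, blink_times=blinks)


def generate_cohort(config: CohortConfig,
                    schedule: AgeSchedule | None = None,
                    device_map=None) -> Cohort:
    """Generate a full synthetic IPAST cohort.

    Deterministic given ``config.seed``.  Each participant receives
    ``n_blocks * trials_per_block`` trials with conditions and sides
    pseudo-randomly interleaved at exactly equal frequency, a 500 Hz
    session trace (pupil stored in device area units, to be recovered by
    the calibration stage), demographics (MoCA for adults only), and a row
    in the 12-variable saccade-measure table.
    """
    config.validate()
    if schedule is None:
        schedule = default_age_schedule()
    if device_map is None:
        device_map = default_device_map
    lo, hi = config.age_range
    schedule.validate(np.linspace(lo, hi, 25))
    rng = np.random.default_rng(config.seed)

    n = config.n_participants
    if config.ages is not None:
        if len(config.ages) != n:
            raise ValueError("ages census list length must equal n_participants")
        ages = np.asarray(config.ages, dtype=float)
    else:
        ages = np.sort(rng.uniform(lo, hi, n))
        if n >= 2:
            ages[0], ages[-1] = lo, hi  # span the configured range
    sexes = np.where(rng.random(n) < 0.65, "F", "M")
    moca = np.full(n, np.nan)
    adults = ages > 18.0
    moca[adults] = np.clip(np.round(rng.normal(27.0, 2.0, adults.sum())), 10, 30)
    low = adults & (rng.random(n) < 0.03)
    moca[low] = rng.integers(14, 20, low.sum())

    ids = [f"P{i:04d}" for i in range(n)]
    participants = pd.DataFrame(
        {"id": ids, "age": ages, "sex": sexes, "moca": moca})

    dt = 1000.0 / config.sampling_rate
    sessions: dict[str, SessionData] = {}
    for pid, age, sex in zip(ids, ages, sexes):
        conds, sides = _interleaved_conditions(
            rng, config.trials_per_block, config.n_blocks)
        traces, ev_rows, truth_rows = [], [], []
        for k, (cond, side) in enumerate(zip(conds, sides)):
            p = _draw_trial_params(rng, age, sex, cond, side, schedule, config)
            tr = generate_trial_trace(p, config, rng)
            offset = k * TRIAL_MS
            traces.append(tr)
            ev_rows.append({
                "trial_id": k, "condition": cond, "side": side,
                "fp_on_ms": offset, "gap_on_ms": offset + FIX_MS,
                "stim_on_ms": offset + STIM_MS})
            truth_rows.append({
                "trial_id": k, "condition": cond, "side": side,
                "baseline_mm": p.baseline_mm,
                "constriction_latency_ms": p.constriction_latency_ms,
                "constriction_amplitude_mm": p.constriction_amplitude_mm,
                "constriction_peak_ms": p.constriction_peak_ms,
                "dilation_rate_mm_per_s": p.dilation_rate_mm_per_s,
                "srt_ms": p.srt_ms,
                "is_direction_error": p.is_direction_error,
                "n_blinks": len(p.blink_times)})
        t_all = np.concatenate(
            [tr.t + k * TRIAL_MS for k, tr in enumerate(traces)])
        session = SampleTrace(
            t=t_all,
            gaze_x=np.concatenate([tr.gaze_x for tr in traces]),
            gaze_y=np.concatenate([tr.gaze_y for tr in traces]),
            pupil=device_map(np.concatenate([tr.pupil for tr in traces])),
            valid=np.concatenate([tr.valid for tr in traces]),
            rate=config.sampling_rate, unit="area")
        sessions[pid] = SessionData(
            trace=session,
            events=pd.DataFrame(ev_rows),
            truth=pd.DataFrame(truth_rows))

    calibration = generate_calibration_recordings(
        list(range(2, 13)), device_map,
        seed=int(rng.integers(0, 2**31 - 1)))
    sacc, latents = generate_saccade_measure_table(
        n, seed=int(rng.integers(0, 2**31 - 1)))
    sacc.index = ids
    sacc.index.name = "id"
    latents.index = ids
    latents.index.name = "id"
    return Cohort(participants=participants, sessions=sessions,
                  calibration=calibration, saccade_measures=sacc,
                  saccade_latents=latents, config=config)


# --------------------------------------------------------------------------
# calibration recordings


def generate_calibration_recordings(sizes_mm: Sequence[float],
                                    device_map=None,
                                    noise_sd: float = 0.0,
                                    n_repeats: int = 1,
                                    seed: int = 0,
                                    strict_range: bool = True) -> pd.DataFrame:
    """False-pupil recordings: (true diameter mm, recorded area units).

    Emulates imaging a series of artificial pupils of known diameter
    (2-12 mm) through the tracker's nonlinear area response.
    """
    if device_map is None:
        device_map = default_device_map
    sizes = np.asarray(sizes_mm, dtype=float)
    if strict_range and (sizes.min() < 2.0 or sizes.max() > 12.0):
        raise ValueError("false-pupil sizes must lie within 2-12 mm")
    areas = np.asarray(device_map(sizes), dtype=float)
    if np.any(np.diff(areas[np.argsort(sizes)]) <= 0):
        raise ValueError("device_map must be strictly increasing in area")
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_repeats):
        rec = areas + (rng.normal(0.0, noise_sd, sizes.size)
                       if noise_sd > 0 else 0.0)
        rows.append(pd.DataFrame({"true_mm": sizes, "recorded_area": rec}))
    return pd.concat(rows, ignore_index=True)


# --------------------------------------------------------------------------
# factor-structured measure tables

SACCADE_MEASURES: list[tuple[str, float, float]] = [
    # (name, mean, sd) on the measure's natural scale
    ("pro_disengaged_pct", 10.0, 5.0),
    ("anti_disengaged_pct", 12.0, 6.0),
    ("anticipatory_pro_pct", 8.0, 4.0),
    ("anticipatory_anti_pct", 8.0, 4.0),
    ("srt_pro_ms", 280.0, 40.0),
    ("srt_anti_ms", 340.0, 45.0),
    ("express_pro_correct_pct", 15.0, 6.0),
    ("express_anti_error_pct", 20.0, 7.0),
    ("regular_anti_error_pct", 15.0, 6.0),
    ("vot_ms", 150.0, 30.0),
    ("velocity_pro_deg_s", 420.0, 60.0),
    ("amplitude_pro_deg", 9.5, 1.0),
]

# 12 x 4 pattern: task disengagement, visual transient, frontal
# inhibition / voluntary generation, brainstem saccade generation.
DEFAULT_SACCADE_LOADINGS = np.array([
    # F1    F2    F3    F4
    [0.80, 0.00, 0.00, 0.00],   # pro_disengaged_pct
    [0.80, 0.00, 0.00, 0.00],   # anti_disengaged_pct
    [0.65, 0.00, 0.00, 0.00],   # anticipatory_pro_pct
    [0.65, 0.00, 0.00, 0.00],   # anticipatory_anti_pct
    [0.00, 0.00, 0.60, 0.00],   # srt_pro_ms
    [0.00, 0.00, 0.70, 0.00],   # srt_anti_ms
    [0.00, 0.80, 0.00, 0.00],   # express_pro_correct_pct
    [0.00, 0.70, 0.00, 0.00],   # express_anti_error_pct
    [0.00, 0.00, 0.80, 0.00],   # regular_anti_error_pct
    [0.00, 0.60, 0.00, 0.00],   # vot_ms
    [0.00, 0.00, 0.00, 0.85],   # velocity_pro_deg_s
    [0.00, 0.00, 0.00, 0.80],   # amplitude_pro_deg
])

PUPIL_ROW_COLUMNS = [
    "constriction_size_pro", "constriction_size_anti",
    "peak_constriction_velocity_pro", "peak_constriction_velocity_anti",
    "peak_constriction_time_pro", "peak_constriction_time_anti",
    "dilation_size_pro", "dilation_size_anti",
    "dilation_velocity_pro", "dilation_velocity_anti",
    "peak_dilation_velocity_pro", "peak_dilation_velocity_anti",
    "baseline_size", "onset_latency",
]

# 14 x 3 pattern mimicking the pupil factor structure: constriction
# (visual/luminance), dilation (top-down), tonic (arousal/attention).
DEFAULT_PUPIL_LOADINGS = np.array([
    [0.85, 0.00, 0.00],   # constriction_size_pro
    [0.85, 0.00, 0.00],   # constriction_size_anti
    [-0.80, 0.00, 0.00],  # peak_constriction_velocity_pro
    [-0.80, 0.00, 0.00],  # peak_constriction_velocity_anti
    [0.00, 0.50, 0.00],   # peak_constriction_time_pro
    [0.00, 0.50, 0.00],   # peak_constriction_time_anti
    [0.00, 0.80, 0.00],   # dilation_size_pro
    [0.00, 0.80, 0.00],   # dilation_size_anti
    [0.00, 0.75, 0.00],   # dilation_velocity_pro
    [0.00, 0.75, 0.00],   # dilation_velocity_anti
    [0.00, 0.70, 0.00],   # peak_dilation_velocity_pro
    [0.00, 0.70, 0.00],   # peak_dilation_velocity_anti
    [0.00, 0.00, 0.85],   # baseline_size
    [0.00, 0.00, 0.70],   # onset_latency
])


def _common_factor_sample(loadings: np.ndarray, n: int,
                          rng: np.random.Generator
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Draw standardized measures z = F L' + E from a common-factor model."""
    p, k = loadings.shape
    if np.linalg.matrix_rank(loadings) < k:
        raise ValueError("loading matrix is rank deficient")
    h2 = np.sum(loadings ** 2, axis=1)
    if np.any(h2 >= 1.0):
        raise ValueError("row communalities must be < 1")
    scores = rng.standard_normal((n, k))
    unique = rng.standard_normal((n, p)) * np.sqrt(1.0 - h2)
    z = scores @ loadings.T + unique
    return z, scores


def generate_saccade_measure_table(n: int,
                                   loading_matrix: np.ndarray | None = None,
                                   seed: int = 0
                                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant 12-variable saccade-measure table.

    Rows follow a 4-factor common-factor model, then each standardized
    measure is mapped affinely to its natural scale and clipped to its
    physical range (percentages to [0, 100], SRTs to [90, 800] ms).
    Returns ``(table, latent_scores)``; the latent scores enable
    factor-recovery tests.
    """
    L = (DEFAULT_SACCADE_LOADINGS if loading_matrix is None
         else np.asarray(loading_matrix, dtype=float))
    if L.shape != (12, 4):
        raise ValueError("loading_matrix must be 12 x 4")
    rng = np.random.default_rng(seed)
    z, scores = _common_factor_sample(L, n, rng)
    data = {}
    for j, (name, mean, sd) in enumerate(SACCADE_MEASURES):
        x = mean + sd * z[:, j]
        if name.endswith("_pct"):
            x = np.clip(x, 0.0, 100.0)
        elif name.startswith("srt_"):
            x = np.clip(x, 90.0, 800.0)
        data[name] = x
    table = pd.DataFrame(data)
    latents = pd.DataFrame(scores,
                           columns=[f"factor_{i + 1}" for i in range(4)])
    return table, latents


def generate_measure_rows(n: int,
                          loading_matrix: np.ndarray | None = None,
                          seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic 14-variable pupil measure rows with known factor structure.

    Used to test the factor pipeline end to end: by default three latent
    factors group the constriction, dilation and tonic measures the way
    the real analysis groups them.
    """
    L = (DEFAULT_PUPIL_LOADINGS if loading_matrix is None
         else np.asarray(loading_matrix, dtype=float))
    if L.shape[0] != 14:
        raise ValueError("loading_matrix must have 14 rows")
    rng = np.random.default_rng(seed)
    z, scores = _common_factor_sample(L, n, rng)
    table = pd.DataFrame(z, columns=PUPIL_ROW_COLUMNS)
    latents = pd.DataFrame(scores,
                           columns=[f"factor_{i + 1}" for i in range(L.shape[1])])
    return table, latents
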