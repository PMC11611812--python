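"""End-to-end orchestration of the IPAST pupil pipeline.

Stages (each reads and writes the canonical files under one run
directory): ``simulate`` -> ``preprocess``/``extract`` -> ``modulation``
-> ``factors`` -> ``lifespan`` -> ``report``.  All randomness flows from
the configured seed; two runs with the same configuration produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from . import synthetic as syn
from .trace import SampleTrace
from .calibration import fit_calibration, apply_calibration
from .features import (MEASURE_NAMES, MEASURE_ROW_COLUMNS,
                       aggregate_participant, extract_measures)
from .factors import factor_factor_correlation, fit_factor_model
from .lifespan import fit_gam, sex_difference_window, smoothing_spline_fit
from .modulation import anti_effect, anti_effect_table
from .preprocess import (ParticipantRecord, TrialRecord, classify_trial,
                         despike_and_smooth, detect_blinks, detect_saccades,
                         filter_participants, flag_pupil_viability)

__all__ = ["stage_simulate", "stage_preprocess", "stage_extract",
           "stage_modulation", "stage_factors", "stage_lifespan",
           "stage_report", "run_all", "accounting"]

log = logging.getLogger(__name__)

TRIAL_MS = syn.TRIAL_MS


def _round_df(df: pd.DataFrame, decimals: int = 6) -> pd.DataFrame:
    out = df.copy()
    for c in out.columns:
        if out[c].dtype.kind == "f":
            out[c] = out[c].round(decimals)
    return out


# --------------------------------------------------------------------------
# simulate


def stage_simulate(outdir: str | Path, n_participants: int = 50,
                   seed: int = 0, trials_per_block: int = 120,
                   n_blocks: int = 2, noise_sd: float = 0.02,
                   blink_rate: float = 0.10) -> None:
    """Generate a synthetic cohort and write the canonical input files."""
    outdir = Path(outdir)
    (outdir / "samples").mkdir(parents=True, exist_ok=True)
    config = syn.CohortConfig(
        n_participants=n_participants, seed=seed,
        trials_per_block=trials_per_block, n_blocks=n_blocks,
        noise_sd=noise_sd, blink_rate=blink_rate)
    cohort = syn.generate_cohort(config)
    pio.write_participants(outdir / "participants.tsv", cohort.participants)
    pio.write_calibration(outdir / "calibration.tsv", cohort.calibration)
    cohort.saccade_measures.round(6).to_csv(
        outdir / "saccade_measures.tsv", sep="\t")
    events, truths = [], []
    for pid, sess in cohort.sessions.items():
        pio.write_samples(outdir / "samples" / f"{pid}.tsv", sess.trace)
        ev = sess.events.copy()
        ev.insert(0, "participant_id", pid)
        events.append(ev)
        tr = sess.truth.copy()
        tr.insert(0, "participant_id", pid)
        truths.append(tr)
    pio.write_events(outdir / "events.tsv", pd.concat(events,
                                                      ignore_index=True))
    _round_df(pd.concat(truths, ignore_index=True)).to_csv(
        outdir / "truth_trials.csv", index=False)
    log.info("simulated %d participants into %s", n_participants, outdir)


# --------------------------------------------------------------------------
# per-trial processing


def process_participant(trace, events: pd.DataFrame, cfg: pio.RunConfig
                        ) -> tuple[list[TrialRecord], pd.DataFrame]:
    """Clean one session and extract per-trial records and measures."""
    records: list[TrialRecord] = []
    rows = []
    for ev in events.itertuples(index=False):
        trial = TrialRecord(
            trial_id=int(ev.trial_id), condition=ev.condition, side=ev.side,
            fp_on=float(ev.fp_on_ms), gap_on=float(ev.gap_on_ms),
            stim_on=float(ev.stim_on_ms))
        # contiguous slice (searchsorted: the session grid is regular)
        i0 = int(np.searchsorted(trace.t, trial.fp_on))
        i1 = int(np.searchsorted(trace.t, trial.fp_on + TRIAL_MS - trace.dt,
                                 side="right"))
        sub = SampleTrace(
            t=trace.t[i0:i1], gaze_x=trace.gaze_x[i0:i1],
            gaze_y=trace.gaze_y[i0:i1], pupil=trace.pupil[i0:i1],
            valid=trace.valid[i0:i1], rate=trace.rate, unit=trace.unit)
        blinks = detect_blinks(sub, pad_ms=cfg.blink_pad_ms)
        saccades = detect_saccades(
            sub, velocity_threshold=cfg.saccade_velocity_threshold_deg_s,
            min_duration_ms=cfg.saccade_min_duration_ms)
        classify_trial(trial, saccades)
        flag_pupil_viability(trial, blinks, saccades,
                             min_srt_ms=cfg.min_srt_ms,
                             saccade_amp_threshold=cfg.srt_min_amplitude_deg)
        records.append(trial)
        if trial.pupil_viable:
            clean = despike_and_smooth(
                sub, rate_threshold_mm_per_ms=cfg.despike_threshold_mm_per_ms,
                interp_max_ms=cfg.interp_max_ms,
                half_window=cfg.smooth_half_window_samples)
            meas = extract_measures(clean, trial.fp_on, trial.stim_on)
            row = {"trial_id": trial.trial_id, "condition": trial.condition}
            row.update(meas.as_dict())
            rows.append(row)
    measures = pd.DataFrame(rows, columns=["trial_id", "condition",
                                           *MEASURE_NAMES])
    return records, measures


def _process(outdir: Path, cfg: pio.RunConfig):
    participants = pio.read_participants(outdir / "participants.tsv")
    events = pio.read_events(outdir / "events.tsv")
    curve = fit_calibration(pio.read_calibration(outdir / "calibration.tsv"))
    qc_rows, meas_frames, med_rows, row_rows = [], [], [], []
    precs: list[ParticipantRecord] = []
    for p in participants.itertuples(index=False):
        trace = pio.read_samples(outdir / "samples" / f"{p.id}.tsv")
        trace = apply_calibration(curve, trace)
        ev = events[events["participant_id"] == p.id]
        records, measures = process_participant(trace, ev, cfg)
        moca = None if pd.isna(p.moca) else float(p.moca)
        precs.append(ParticipantRecord(id=p.id, age=float(p.age), sex=p.sex,
                                       moca=moca, trials=records))
        for t in records:
            qc_rows.append({
                "participant_id": p.id, "trial_id": t.trial_id,
                "condition": t.condition, "side": t.side,
                "srt": np.nan if t.srt is None else t.srt,
                "latency_class": t.latency_class,
                "is_direction_error": t.is_direction_error,
                "pupil_viable": t.pupil_viable,
                "exclusion_reasons": ";".join(sorted(t.exclusion_reasons))})
        if len(measures):
            m = measures.copy()
            m.insert(0, "participant_id", p.id)
            meas_frames.append(m)
            medians, row, complete = aggregate_participant(measures)
            for cond in medians.index:
                med = {"id": p.id, "condition": cond}
                med.update(medians.loc[cond].to_dict())
                med_rows.append(med)
            rr = {"id": p.id, "age": float(p.age), "sex": p.sex,
                  "complete": complete}
            rr.update(row.to_dict())
            row_rows.append(rr)
    filter_participants(precs, min_viable_trials=cfg.min_viable_trials,
                        moca_cutoff=cfg.moca_cutoff)
    qc = pd.DataFrame(qc_rows)
    trial_measures = (pd.concat(meas_frames, ignore_index=True)
                      if meas_frames else pd.DataFrame())
    medians = pd.DataFrame(med_rows)
    rows = pd.DataFrame(row_rows)
    pqc = pd.DataFrame([{
        "id": pr.id, "age": pr.age, "sex": pr.sex,
        "moca": np.nan if pr.moca is None else pr.moca,
        "n_viable_pro": sum(1 for t in pr.trials
                            if t.pupil_viable and t.condition == "PRO"),
        "n_viable_anti": sum(1 for t in pr.trials
                             if t.pupil_viable and t.condition == "ANTI"),
        "retained": pr.retained,
        "exclusion_reasons": ";".join(sorted(pr.exclusion_reasons)),
    } for pr in precs])
    return qc, trial_measures, medians, rows, pqc


def stage_preprocess(outdir: str | Path,
                     cfg: pio.RunConfig | None = None) -> pd.DataFrame:
    """Trial QC: classification and exclusion flags for every trial."""
    outdir = Path(outdir)
    cfg = cfg or pio.RunConfig()
    qc, *_ , pqc = _process(outdir, cfg)
    _round_df(qc).to_csv(outdir / "qc_trials.csv", index=False)
    _round_df(pqc).to_csv(outdir / "participants_qc.csv", index=False)
    return qc


def stage_extract(outdir: str | Path,
                  cfg: pio.RunConfig | None = None) -> pd.DataFrame:
    """Per-trial measures, condition medians and 14-variable rows."""
    outdir = Path(outdir)
    cfg = cfg or pio.RunConfig()
    qc, trial_measures, medians, rows, pqc = _process(outdir, cfg)
    _round_df(qc).to_csv(outdir / "qc_trials.csv", index=False)
    _round_df(pqc).to_csv(outdir / "participants_qc.csv", index=False)
    _round_df(trial_measures).to_csv(outdir / "trial_measures.csv",
                                     index=False)
    _round_df(medians).to_csv(outdir / "condition_medians.csv", index=False)
    _round_df(rows).to_csv(outdir / "measure_rows.csv", index=False)
    return rows


def _retained_ids(outdir: Path) -> list[str]:
    pqc = pd.read_csv(outdir / "participants_qc.csv")
    return list(pqc.loc[pqc["retained"], "id"])


def stage_modulation(outdir: str | Path,
                     cfg: pio.RunConfig | None = None) -> pd.DataFrame:
    """ANTI-effect per measure across retained participants."""
    outdir = Path(outdir)
    cfg = cfg or pio.RunConfig()
    medians = pd.read_csv(outdir / "condition_medians.csv")
    keep = set(_retained_ids(outdir))
    medians = medians[medians["id"].isin(keep)]
    effects = anti_effect(medians)
    table = anti_effect_table(effects, alpha=cfg.alpha)
    _round_df(effects.reset_index()).to_csv(outdir / "anti_effects.csv",
                                            index=False)
    _round_df(table).to_csv(outdir / "anti_effect_tests.csv", index=False)
    return table


def stage_factors(outdir: str | Path,
                  cfg: pio.RunConfig | None = None) -> dict:
    """Factor models of the pupil and saccade tables plus their coupling."""
    outdir = Path(outdir)
    cfg = cfg or pio.RunConfig()
    keep = set(_retained_ids(outdir))
    rows = pd.read_csv(outdir / "measure_rows.csv")
    rows = rows[rows["id"].isin(keep) & rows["complete"]]
    pupil_table = rows.set_index("id")[MEASURE_ROW_COLUMNS]
    pupil_model = fit_factor_model(pupil_table, method=cfg.factor_method,
                                   gamma=cfg.oblimin_gamma)
    sacc = pd.read_csv(outdir / "saccade_measures.tsv", sep="\t",
                       index_col="id")
    sacc = sacc.loc[sacc.index.isin(keep)]
    sacc_model = fit_factor_model(sacc, method=cfg.factor_method,
                                  gamma=cfg.oblimin_gamma)
    corr = factor_factor_correlation(pupil_model.scores, sacc_model.scores,
                                     alpha=cfg.alpha)

    def dump(model, prefix):
        pd.DataFrame(model.pattern_loadings, index=model.variables,
                     columns=[f"factor_{j + 1}"
                              for j in range(model.n_factors)]
                     ).round(6).to_csv(outdir / f"{prefix}_loadings.csv")
        pd.DataFrame(model.factor_correlations).round(6).to_csv(
            outdir / f"{prefix}_factor_correlations.csv", index=False)
        model.scores.round(6).to_csv(outdir / f"{prefix}_scores.csv")
        long = model.input_correlation.stack().reset_index()
        long.columns = ["var1", "var2", "rho"]
        _round_df(long).to_csv(outdir / f"{prefix}_correlation_long.csv",
                               index=False)

    dump(pupil_model, "pupil")
    dump(sacc_model, "saccade")
    corr.rho.round(6).to_csv(outdir / "pupil_saccade_factor_corr.csv")
    summary = {
        "pupil": {
            "n": int(len(pupil_model.scores)),
            "kmo": round(pupil_model.kmo_overall, 6),
            "bartlett_chi2": round(pupil_model.bartlett_chi2, 3),
            "bartlett_df": pupil_model.bartlett_df,
            "bartlett_p": float(pupil_model.bartlett_p),
            "n_factors": pupil_model.n_factors,
            "variance_explained_pct": round(
                pupil_model.variance_explained_prerotation, 3)},
        "saccade": {
            "n": int(len(sacc_model.scores)),
            "kmo": round(sacc_model.kmo_overall, 6),
            "bartlett_df": sacc_model.bartlett_df,
            "n_factors": sacc_model.n_factors},
        "n_significant_pairs": int(corr.significant.to_numpy().sum()),
    }
    with open(outdir / "factor_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def stage_lifespan(outdir: str | Path,
                   cfg: pio.RunConfig | None = None,
                   min_obs: int | None = None) -> pd.DataFrame:
    """Age trajectories of the pupil factors, measures and sex difference."""
    outdir = Path(outdir)
    cfg = cfg or pio.RunConfig()
    min_obs = cfg.gam_min_obs if min_obs is None else min_obs
    keep = _retained_ids(outdir)
    rows = pd.read_csv(outdir / "measure_rows.csv").set_index("id")
    rows = rows.loc[rows.index.isin(keep)]
    scores = pd.read_csv(outdir / "pupil_scores.csv", index_col="id")
    joined = scores.join(rows[["age", "sex"]])

    window_rows, fit_frames = [], []
    for col in scores.columns:
        fit = fit_gam(joined["age"].to_numpy(), joined[col].to_numpy(),
                      k=cfg.gam_basis_dim, grid_n=cfg.gam_grid_n,
                      n_draws=cfg.gam_draws, seed=cfg.seed,
                      eps=cfg.gam_deriv_eps_years, min_obs=min_obs)
        df = pd.DataFrame({
            "measure": col, "age": fit.grid, "fit": fit.fit,
            "lo": fit.ci_lo, "hi": fit.ci_hi, "deriv": fit.deriv,
            "dlo": fit.deriv_lo, "dhi": fit.deriv_hi,
            "significant": (fit.deriv_lo > 0) | (fit.deriv_hi < 0)})
        fit_frames.append(df)
        for a0, a1 in fit.significant_windows:
            window_rows.append({"measure": col, "age_lo": a0, "age_hi": a1})
    _round_df(pd.concat(fit_frames, ignore_index=True)).to_csv(
        outdir / "lifespan_gam_fits.csv", index=False)
    windows = pd.DataFrame(window_rows,
                           columns=["measure", "age_lo", "age_hi"])
    _round_df(windows).to_csv(outdir / "lifespan_windows.csv", index=False)

    # qualitative smoothing-spline curves for the raw measures
    spline_rows = []
    for m in MEASURE_ROW_COLUMNS:
        curves = smoothing_spline_fit(rows["age"].to_numpy(),
                                      rows[m].to_numpy())
        grid, yhat = curves["all"]
        spline_rows.append(pd.DataFrame(
            {"measure": m, "age": grid, "fit": yhat}))
    _round_df(pd.concat(spline_rows, ignore_index=True)).to_csv(
        outdir / "lifespan_spline_fits.csv", index=False)

    # sex difference in baseline pupil size
    sexres = sex_difference_window(
        rows["age"].to_numpy(), rows["baseline_size"].to_numpy(),
        rows["sex"].to_numpy(), k=cfg.gam_basis_dim,
        grid_n=cfg.gam_grid_n, n_draws=cfg.gam_draws, seed=cfg.seed)
    _round_df(pd.DataFrame({
        "age": sexres.grid, "diff": sexres.diff,
        "lo": sexres.diff_lo, "hi": sexres.diff_hi})).to_csv(
        outdir / "lifespan_sex_difference.csv", index=False)
    _round_df(pd.DataFrame(
        [{"age_lo": a, "age_hi": b} for a, b in sexres.significant_windows],
        columns=["age_lo", "age_hi"])).to_csv(
        outdir / "lifespan_sex_windows.csv", index=False)
    return windows


# --------------------------------------------------------------------------
# reporting


def accounting(n_female: int, n_male: int, n_excluded: int) -> dict:
    """Participant-flow identities: enrolled, retained, exclusion percent."""
    enrolled = int(n_female) + int(n_male)
    if not 0 <= n_excluded <= enrolled:
        raise ValueError("excluded count must lie within [0, enrolled]")
    retained = enrolled - int(n_excluded)
    return {
        "enrolled": enrolled,
        "excluded": int(n_excluded),
        "retained": retained,
        "excluded_pct": round(100.0 * n_excluded / enrolled, 1),
    }


def stage_report(outdir: str | Path, seed: int | None = None) -> dict:
    """Reconciled participant flow and stage summaries, as JSON."""
    outdir = Path(outdir)
    pqc = pd.read_csv(outdir / "participants_qc.csv")
    n_f = int((pqc["sex"] == "F").sum())
    n_m = int((pqc["sex"] == "M").sum())
    n_exc = int((~pqc["retained"]).sum())
    flow = accounting(n_f, n_m, n_exc)
    flow["by_sex"] = {"F": n_f, "M": n_m}
    reasons = pqc.loc[~pqc["retained"], "exclusion_reasons"]
    reason_counts: dict[str, int] = {}
    for r in reasons:
        for token in str(r).split(";"):
            if token and token != "nan":
                reason_counts[token] = reason_counts.get(token, 0) + 1
    report = {"participant_flow": flow,
              "exclusion_reasons": reason_counts}
    tests_path = outdir / "anti_effect_tests.csv"
    if tests_path.exists():
        report["anti_effect"] = pd.read_csv(tests_path).to_dict("records")
    fs = outdir / "factor_summary.json"
    if fs.exists():
        with open(fs) as fh:
            report["factors"] = json.load(fh)
    wpath = outdir / "lifespan_windows.csv"
    if wpath.exists():
        report["lifespan_windows"] = pd.read_csv(wpath).to_dict("records")
    h = hashlib.sha256()
    for f in ("participants.tsv", "events.tsv"):
        p = outdir / f
        if p.exists():
            h.update(p.read_bytes())
    report["provenance"] = {"seed": seed, "input_hash": h.hexdigest()}
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def run_all(outdir: str | Path, n_participants: int = 50, seed: int = 0,
            cfg: pio.RunConfig | None = None,
            trials_per_block: int = 120,
            gam_min_obs: int = 30) -> dict:
    """Simulate and run every stage in order on one directory.

    ``gam_min_obs`` relaxes the lifespan stage's default 50-observation
    floor for small demonstration cohorts.
    """
    outdir = Path(outdir)
    cfg = cfg or pio.RunConfig(seed=seed)
    stage_simulate(outdir, n_participants=n_participants, seed=seed,
                   trials_per_block=trials_per_block)
    stage_extract(outdir, cfg)
    stage_modulation(outdir, cfg)
    stage_factors(outdir, cfg)
    stage_lifespan(outdir, cfg, min_obs=gam_min_obs)
    return stage_report(outdir, seed=seed)
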