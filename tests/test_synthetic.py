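"""Generator contracts: determinism, balance, exact trace construction."""

import numpy as np
import pandas as pd
import pytest

from pupilspan import synthetic as syn
from pupilspan.synthetic import (CohortConfig, TrialParams,
                                 default_age_schedule,
                                 generate_calibration_recordings,
                                 generate_cohort,
                                 generate_measure_rows,
                                 generate_saccade_measure_table,
                                 generate_trial_trace)


class TestCohort:
    def test_seeded_determinism(self):
        cfg = CohortConfig(n_participants=2, seed=7, trials_per_block=8,
                           n_blocks=1)
        a = generate_cohort(cfg)
        b = generate_cohort(cfg)
        pd.testing.assert_frame_equal(a.participants, b.participants)
        np.testing.assert_array_equal(a.sessions["P0000"].trace.pupil,
                                      b.sessions["P0000"].trace.pupil)
        pd.testing.assert_frame_equal(a.saccade_measures, b.saccade_measures)

    def test_default_trial_counts_and_balance(self):
        cfg = CohortConfig(n_participants=1, seed=1)
        c = generate_cohort(cfg)
        ev = c.sessions["P0000"].events
        # two blocks of 120 trials, conditions and sides interleaved equally
        assert len(ev) == 240
        assert (ev["condition"] == "PRO").sum() == 120
        assert (ev["condition"] == "ANTI").sum() == 120
        assert abs((ev["side"] == "left").sum()
                   - (ev["side"] == "right").sum()) <= 1

    def test_null_anti_gap_gives_equal_dilation_rates(self):
        sched = default_age_schedule()
        sched.anti_effect_gap = lambda age: 0.0
        for age in (6.0, 40.0, 90.0):
            assert sched.dilation_rate(age, "ANTI") == \
                sched.dilation_rate(age, "PRO")

    def test_invalid_config_rejected_by_field(self):
        with pytest.raises(ValueError, match="n_participants"):
            CohortConfig(n_participants=0).validate()
        with pytest.raises(ValueError, match="sampling_rate"):
            CohortConfig(sampling_rate=0).validate()
        with pytest.raises(ValueError, match="trials_per_block"):
            CohortConfig(trials_per_block=7).validate()

    def test_ages_span_configured_range(self):
        c = generate_cohort(CohortConfig(n_participants=10, seed=3,
                                         trials_per_block=4, n_blocks=1))
        ages = c.participants["age"]
        assert ages.min() == 5.0 and ages.max() == 93.0


class TestTrialTrace:
    def test_event_timeline(self):
        ev = generate_cohort(CohortConfig(n_participants=1, seed=0,
                                          trials_per_block=4, n_blocks=1)
                             ).sessions["P0000"].events
        # 1,000 ms fixation plus 200 ms gap before the stimulus
        assert ((ev["gap_on_ms"] - ev["fp_on_ms"]) == 1000.0).all()
        assert ((ev["stim_on_ms"] - ev["fp_on_ms"]) == 1200.0).all()

    def test_noiseless_peak_value_exact(self, noiseless_trace,
                                        default_trial_params):
        p = default_trial_params
        i = int(np.searchsorted(noiseless_trace.t, p.constriction_peak_ms))
        assert noiseless_trace.pupil[i] == pytest.approx(
            p.baseline_mm - p.constriction_amplitude_mm, abs=1e-12)

    def test_noiseless_dilation_slope(self, noiseless_trace,
                                      default_trial_params):
        t = noiseless_trace.t
        m = (t > default_trial_params.constriction_peak_ms) & (t <= 1200.0)
        slope = np.polyfit(t[m] / 1000.0, noiseless_trace.pupil[m], 1)[0]
        assert slope == pytest.approx(0.8, abs=1e-9)

    def test_blink_outside_span_rejected(self, noiseless_config):
        p = TrialParams(baseline_mm=5.0, constriction_latency_ms=400.0,
                        constriction_amplitude_mm=0.3,
                        constriction_peak_ms=900.0,
                        dilation_rate_mm_per_s=0.5, condition="PRO",
                        stimulus_side="left", srt_ms=200.0,
                        blink_times=[4000.0])
        with pytest.raises(ValueError, match="blink"):
            generate_trial_trace(p, noiseless_config)

    def test_blink_invalidates_and_spikes(self, noiseless_config,
                                          default_trial_params):
        from dataclasses import replace
        p = replace(default_trial_params, blink_times=[500.0])
        tr = generate_trial_trace(p, noiseless_config,
                                  np.random.default_rng(0))
        assert not tr.valid[int(np.searchsorted(tr.t, 560.0))]
        assert tr.valid.sum() < len(tr)


class TestCalibrationRecordings:
    def test_row_count_for_2_to_12_mm(self):
        rec = generate_calibration_recordings(list(range(2, 13)))
        assert len(rec) == 11

    def test_quadratic_map_gives_linear_sqrt(self):
        rec = generate_calibration_recordings([2, 5, 8, 12])
        sq = np.sqrt(rec["recorded_area"].to_numpy())
        ratio = sq / rec["true_mm"].to_numpy()
        assert np.allclose(ratio, ratio[0])

    def test_out_of_range_sizes_rejected(self):
        with pytest.raises(ValueError, match="2-12"):
            generate_calibration_recordings([1.0, 5.0])
        rec = generate_calibration_recordings([1.0, 5.0], strict_range=False)
        assert len(rec) == 2

    def test_non_monotone_device_map_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            generate_calibration_recordings([2, 4, 6],
                                            device_map=lambda d: -d)


class TestSaccadeMeasureTable:
    def test_seeded_determinism(self):
        a, _ = generate_saccade_measure_table(20, seed=5)
        b, _ = generate_saccade_measure_table(20, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_loadings_give_independent_measures(self):
        L = np.zeros((12, 4))
        L[0, 0] = L[1, 1] = L[2, 2] = L[3, 3] = 1e-6  # keep full rank
        table, _ = generate_saccade_measure_table(4000, loading_matrix=L,
                                                  seed=11)
        R = table.corr().to_numpy()
        off = R[~np.eye(12, dtype=bool)]
        assert np.abs(off).max() < 0.08

    def test_rank_deficient_loadings_rejected(self):
        L = np.zeros((12, 4))
        L[:, 0] = 0.5
        with pytest.raises(ValueError, match="rank"):
            generate_saccade_measure_table(10, loading_matrix=L)

    def test_measure_ranges(self):
        table, _ = generate_saccade_measure_table(500, seed=2)
        for name in table.columns:
            if name.endswith("_pct"):
                assert table[name].between(0, 100).all()
            if name.startswith("srt_"):
                assert table[name].between(90, 800).all()

    def test_strong_loadings_recovered_by_kaiser(self):
        from pupilspan.factors import choose_n_factors, correlation_matrix
        table, _ = generate_saccade_measure_table(500, seed=4)
        assert choose_n_factors(correlation_matrix(table)) == 4


class TestMeasureRowGenerator:
    def test_column_layout_matches_analysis_row(self):
        from pupilspan.features import MEASURE_ROW_COLUMNS
        table, latents = generate_measure_rows(10, seed=0)
        assert list(table.columns) == MEASURE_ROW_COLUMNS
        assert latents.shape == (10, 3)


class TestAgeSchedule:
    def test_default_schedule_invariants(self):
        sched = default_age_schedule()
        ages = np.linspace(5, 93, 50)
        sched.validate(ages)  # decreasing baseline, nonincreasing gap
        for a in ages:
            assert sched.dilation_rate(a, "ANTI") >= \
                sched.dilation_rate(a, "PRO")


class TestPlantedGapInvariants:
    def test_gap_exact_without_parameter_jitter(self):
        """With jitter off, generated ANTI-PRO dilation rates equal the
        schedule's gap exactly at every age."""
        cfg = CohortConfig(n_participants=4, seed=13, trials_per_block=8,
                           n_blocks=1, noise_sd=0.0, blink_rate=0.0,
                           param_jitter=0.0)
        sched = default_age_schedule()
        c = generate_cohort(cfg, schedule=sched)
        for pid, sess in c.sessions.items():
            age = float(
                c.participants.set_index("id").loc[pid, "age"])
            truth = sess.truth
            pro = truth.loc[truth["condition"] == "PRO",
                            "dilation_rate_mm_per_s"].unique()
            anti = truth.loc[truth["condition"] == "ANTI",
                             "dilation_rate_mm_per_s"].unique()
            assert len(pro) == 1 and len(anti) == 1
            assert anti[0] - pro[0] == pytest.approx(
                sched.anti_effect_gap(age), abs=1e-12)

    def test_extracted_mean_effect_matches_planted_gap(self):
        """The measured dilation-velocity ANTI-effect reproduces a flat
        planted 0.1 mm/s gap on noiseless traces."""
        from pupilspan import io as pio
        from pupilspan.calibration import apply_calibration, fit_calibration
        from pupilspan.pipeline import process_participant
        sched = default_age_schedule()
        sched.anti_effect_gap = lambda age: 0.1
        sched.anti_constriction_gap = lambda age: 0.0
        cfg = CohortConfig(n_participants=6, seed=19, trials_per_block=8,
                           n_blocks=1, noise_sd=0.0, blink_rate=0.0,
                           param_jitter=0.0, direction_error_rate=0.0)
        c = generate_cohort(cfg, schedule=sched)
        curve = fit_calibration(c.calibration)
        effects = []
        for pid, sess in c.sessions.items():
            trace = apply_calibration(curve, sess.trace)
            _, meas = process_participant(trace, sess.events,
                                          pio.RunConfig())
            med = meas.groupby("condition")["dilation_velocity"].median()
            effects.append(med["ANTI"] - med["PRO"])
        assert np.mean(effects) == pytest.approx(0.1, abs=0.01)
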