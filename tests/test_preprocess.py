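"""Cleaning, event detection, trial classification and exclusion rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pupilspan.preprocess import (ParticipantRecord, SaccadeEvent,
                                  TrialRecord, classify_trial, compute_srt,
                                  despike_and_smooth, detect_blinks,
                                  detect_saccades, filter_participants,
                                  flag_pupil_viability)
from pupilspan.trace import SampleTrace


def _trace(pupil, valid=None, gx=None, gy=None, rate=500.0, unit="mm"):
    n = len(pupil)
    return SampleTrace(
        t=np.arange(n) * (1000.0 / rate),
        gaze_x=np.zeros(n) if gx is None else np.asarray(gx, float),
        gaze_y=np.zeros(n) if gy is None else np.asarray(gy, float),
        pupil=np.asarray(pupil, float),
        valid=np.ones(n, bool) if valid is None else np.asarray(valid, bool),
        rate=rate, unit=unit)


def _trial(stim_on=1200.0, condition="PRO", side="right"):
    return TrialRecord(trial_id=0, condition=condition, side=side,
                       fp_on=0.0, gap_on=1000.0, stim_on=stim_on)


def _saccade(onset, amplitude=10.0, direction="right", dur=40.0):
    return SaccadeEvent(onset_ms=onset, offset_ms=onset + dur,
                        amplitude=amplitude, direction=direction,
                        peak_velocity=300.0)


class TestDespikeSmooth:
    def test_constant_unchanged(self):
        tr = despike_and_smooth(_trace(np.full(200, 5.0)))
        np.testing.assert_allclose(tr.pupil, 5.0)

    def test_spike_sample_invalidated_and_reinterpolated(self):
        p = np.full(200, 5.0)
        p[100] = 5.3  # 0.15 mm/ms at 500 Hz, above the 0.1 mm/ms threshold
        tr = despike_and_smooth(_trace(p))
        assert tr.valid[100]            # re-validated after interpolation
        np.testing.assert_allclose(tr.pupil, 5.0, atol=1e-12)

    def test_impulse_smoothed_to_boxcar(self):
        p = np.zeros(301)
        p[150] = 0.01  # below the despike threshold at 500 Hz
        tr = despike_and_smooth(_trace(p))
        np.testing.assert_allclose(tr.pupil[125:176], 0.01 / 51, atol=1e-15)
        assert tr.pupil[100] == 0.0

    def test_long_gap_stays_invalid(self):
        p = np.full(400, 5.0)
        valid = np.ones(400, bool)
        valid[100:260] = False  # 320 ms > 200 ms interpolation ceiling
        tr = despike_and_smooth(_trace(p, valid=valid))
        assert not tr.valid[150]

    def test_fully_invalid_passes_through(self):
        tr = despike_and_smooth(_trace(np.full(50, 5.0),
                                       valid=np.zeros(50, bool)))
        assert not tr.valid.any()


class TestBlinks:
    def test_no_invalid_no_blinks(self):
        assert detect_blinks(_trace(np.full(100, 5.0))) == []

    def test_padding_arithmetic(self):
        valid = np.ones(1000, bool)
        valid[500:551] = False  # invalid 1,000-1,100 ms at 500 Hz
        blinks = detect_blinks(_trace(np.full(1000, 5.0), valid=valid))
        assert blinks == [(950.0, 1150.0)]

    def test_overlapping_pads_merged(self):
        valid = np.ones(300, bool)
        valid[50:101] = False    # 100-200 ms
        valid[115:151] = False   # 230-300 ms
        blinks = detect_blinks(_trace(np.full(300, 5.0), valid=valid))
        assert blinks == [(50.0, 350.0)]


class TestSaccades:
    def test_stationary_noisy_gaze_empty(self):
        rng = np.random.default_rng(0)
        gx = rng.normal(0, 0.05, 1600)
        gy = rng.normal(0, 0.05, 1600)
        assert detect_saccades(_trace(np.full(1600, 5.0), gx=gx, gy=gy)) == []

    def test_step_amplitude_recovered(self):
        from pupilspan.synthetic import _raised_cosine_position
        t = np.arange(0, 1000, 2.0)
        gx = 10.0 * _raised_cosine_position(t, 400.0, 80.0)
        evs = detect_saccades(_trace(np.full(t.size, 5.0), gx=gx))
        assert len(evs) == 1
        assert evs[0].amplitude == pytest.approx(10.0, abs=0.5)
        assert evs[0].direction == "right"
        assert 380.0 <= evs[0].onset_ms <= 420.0

    def test_two_steps_ordered(self):
        from pupilspan.synthetic import _raised_cosine_position
        t = np.arange(0, 1600, 2.0)
        gx = 5.0 * _raised_cosine_position(t, 300.0, 60.0) \
            + 5.0 * _raised_cosine_position(t, 800.0, 60.0)
        evs = detect_saccades(_trace(np.full(t.size, 5.0), gx=gx))
        assert len(evs) == 2
        assert evs[0].onset_ms < evs[1].onset_ms


class TestSrtAndClassification:
    def test_srt_subtraction(self):
        trial = _trial()
        assert compute_srt(trial, [_saccade(1430.0)]) == 230.0

    def test_microsaccade_ignored(self):
        trial = _trial()
        assert compute_srt(trial, [_saccade(1430.0, amplitude=1.0)]) is None

    def test_anticipatory_negative_srt(self):
        trial = _trial()
        assert compute_srt(trial, [_saccade(1150.0)]) == -50.0

    @pytest.mark.parametrize("srt,expected", [
        (0.0, "anticipatory"), (85.0, "anticipatory"), (89.0, "anticipatory"),
        (90.0, "express"), (120.0, "express"), (139.0, "express"),
        (140.0, "regular"), (230.0, "regular"), (800.0, "regular"),
    ])
    def test_latency_windows(self, srt, expected):
        trial = _trial()
        classify_trial(trial, [_saccade(1200.0 + srt)])
        assert trial.latency_class == expected

    @given(st.floats(min_value=-110.0, max_value=800.0))
    @settings(max_examples=60, deadline=None)
    def test_latency_classes_partition_the_range(self, srt):
        trial = _trial()
        classify_trial(trial, [_saccade(1200.0 + srt)])
        assert trial.latency_class in ("anticipatory", "express", "regular")

    def test_anti_toward_stimulus_is_direction_error(self):
        trial = _trial(condition="ANTI", side="left")
        classify_trial(trial, [_saccade(1430.0, direction="left")])
        assert trial.is_direction_error

    def test_pro_toward_stimulus_is_correct(self):
        trial = _trial(condition="PRO", side="left")
        classify_trial(trial, [_saccade(1430.0, direction="left")])
        assert not trial.is_direction_error


class TestViability:
    def _classified(self, srt=230.0, **kw):
        trial = _trial(**kw)
        classify_trial(trial, [_saccade(1200.0 + srt)])
        return trial

    def test_blink_in_fixation_excludes(self):
        trial = self._classified()
        flag_pupil_viability(trial, [(450.0, 650.0)], [_saccade(1430.0)])
        assert not trial.pupil_viable
        assert "blink_in_fixation" in trial.exclusion_reasons

    def test_early_srt_excluded_as_anticipatory(self):
        trial = self._classified(srt=85.0)
        flag_pupil_viability(trial, [], [_saccade(1285.0)])
        assert "anticipatory" in trial.exclusion_reasons

    def test_clean_regular_trial_viable(self):
        trial = self._classified()
        flag_pupil_viability(trial, [], [_saccade(1430.0)])
        assert trial.pupil_viable and not trial.exclusion_reasons

    def test_fixation_saccade_excludes(self):
        trial = self._classified()
        flag_pupil_viability(trial, [], [_saccade(500.0), _saccade(1430.0)])
        assert "saccade_in_fixation" in trial.exclusion_reasons

    def test_monotone_adding_blink_never_revives(self):
        trial = self._classified()
        flag_pupil_viability(trial, [], [_saccade(1430.0)])
        was_viable = trial.pupil_viable
        flag_pupil_viability(trial, [(100.0, 200.0)], [_saccade(1430.0)])
        assert not trial.pupil_viable or was_viable


class TestParticipantFilter:
    def _participant(self, n_pro=15, n_anti=15, moca=None, age=30.0):
        trials = []
        for i in range(n_pro + n_anti):
            t = _trial(condition="PRO" if i < n_pro else "ANTI")
            t.pupil_viable = True
            trials.append(t)
        return ParticipantRecord(id="X", age=age, sex="F", moca=moca,
                                 trials=trials)

    def test_low_moca_excluded(self):
        p = self._participant(moca=19.0)
        filter_participants([p])
        assert not p.retained and "low_moca" in p.exclusion_reasons

    def test_insufficient_anti_trials_excluded(self):
        p = self._participant(n_pro=40, n_anti=9)
        filter_participants([p])
        assert not p.retained

    def test_child_without_moca_retained(self):
        p = self._participant(age=10.0, moca=None)
        filter_participants([p])
        assert p.retained


class TestPlantedEventRecovery:
    """Detected events on generator output match the planted events."""

    def test_planted_blinks_and_saccades_counted(self):
        from dataclasses import replace
        from pupilspan.synthetic import (CohortConfig, TrialParams,
                                         generate_trial_trace)
        cfg = CohortConfig(noise_sd=0.0, blink_rate=0.0, gaze_noise_sd=0.05)
        base = TrialParams(
            baseline_mm=5.0, constriction_latency_ms=400.0,
            constriction_amplitude_mm=0.4, constriction_peak_ms=900.0,
            dilation_rate_mm_per_s=0.6, condition="PRO",
            stimulus_side="right", srt_ms=240.0)
        rng = np.random.default_rng(2)
        for blinks, srt in [([], 180.0), ([600.0], 240.0),
                            ([300.0, 2000.0], 300.0)]:
            p = replace(base, blink_times=list(blinks), srt_ms=srt)
            tr = generate_trial_trace(p, cfg, rng)
            assert len(detect_blinks(tr)) == len(blinks)
            evs = [e for e in detect_saccades(tr) if e.amplitude >= 2.0]
            assert len(evs) == 1
            assert evs[0].onset_ms == pytest.approx(1200.0 + srt, abs=15.0)
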