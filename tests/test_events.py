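import numpy as np
import pytest

from gaitphase import (
    EventSet,
    PhaseCalibration,
    calibrate_event_phases,
    compute_time_errors,
    crossval_split,
    detect_events_from_phase,
    detect_events_ground_truth,
)
from gaitphase.circular import wrap_angle
from gaitphase.events import CalibrationError, dominant_period


class TestGroundTruthDetector:
    def test_cosine_extrema(self):
        fs = 150.0
        t = np.arange(int(5 * fs)) / fs
        events = detect_events_ground_truth(np.cos(2 * np.pi * t), fs)
        # interior extrema (boundary peaks at t=0 lack a left flank)
        assert np.allclose(events.heel_strike_times, [1, 2, 3, 4], atol=1.5 / fs)
        assert np.allclose(events.toe_off_times, [0.5, 1.5, 2.5, 3.5, 4.5], atol=1.5 / fs)

    def test_velocity_sign_change_agrees_with_peaks(self):
        fs = 150.0
        t = np.arange(int(6 * fs)) / fs
        x = np.cos(2 * np.pi * 0.9 * t)
        events = detect_events_ground_truth(x, fs)
        v = np.diff(x)
        down = np.where((v[:-1] > 0) & (v[1:] <= 0))[0] + 1
        for idx in events.heel_strike_idx:
            assert np.min(np.abs(down - idx)) <= 1

    def test_flat_series_yields_empty(self):
        events = detect_events_ground_truth(np.ones(500), 150.0)
        assert events.heel_strike_idx.size == 0 and events.toe_off_idx.size == 0

    def test_on_simulated_walk_within_one_sample(self, walk_small):
        walk = walk_small
        x = walk.noiseless_relative_x("left")
        fs = walk.config.sampling_rate
        events = detect_events_ground_truth(x, fs)
        truth = walk.true_events["left"]
        for idx in events.heel_strike_idx:
            assert np.min(np.abs(truth.heel_strike_idx - idx)) <= 1
        for idx in events.toe_off_idx:
            assert np.min(np.abs(truth.toe_off_idx - idx)) <= 1
        # every interior truth event is found
        assert events.heel_strike_idx.size >= truth.heel_strike_idx.size - 2

    def test_dominant_period_of_sinusoid(self):
        fs = 150.0
        t = np.arange(int(8 * fs)) / fs
        period = dominant_period(np.sin(2 * np.pi * t / 1.25))
        assert period == pytest.approx(1.25 * fs, rel=0.02)


class TestCalibration:
    def test_reads_reference_phase_from_events(self):
        n = 1500
        phase = wrap_angle(2 * np.pi * np.arange(n) / 150.0)  # 1 cycle/s ramp
        truth = EventSet(
            heel_strike_idx=[150, 300, 450], heel_strike_times=[1.0, 2.0, 3.0],
            toe_off_idx=[240, 390, 540], toe_off_times=[1.6, 2.6, 3.6],
        )
        cal = calibrate_event_phases(phase, np.arange(n), truth)
        assert cal.ref_phase_hs == pytest.approx(0.0, abs=1e-9)
        assert np.cos(cal.ref_phase_to - wrap_angle(2 * np.pi * 0.6)) == pytest.approx(1.0)
        assert cal.direction == 1

    def test_circular_mean_handles_wraparound(self):
        angles = np.array([np.pi - 0.1, wrap_angle(np.pi + 0.1)] * 3)
        truth = EventSet(
            heel_strike_idx=np.arange(6), heel_strike_times=np.arange(6) / 150.0,
            toe_off_idx=np.arange(6, 12), toe_off_times=np.arange(6, 12) / 150.0,
        )
        series = np.concatenate([angles, angles])
        cal = calibrate_event_phases(series, np.arange(12), truth)
        assert np.cos(cal.ref_phase_hs - np.pi) == pytest.approx(1.0, abs=1e-9)

    def test_antipodal_event_phases_rejected(self):
        series = np.array([0.0, np.pi] * 4)
        truth = EventSet(
            heel_strike_idx=np.arange(8), heel_strike_times=np.arange(8) / 150.0,
            toe_off_idx=[], toe_off_times=[],
        )
        with pytest.raises(CalibrationError):
            calibrate_event_phases(series, np.arange(8), truth)


class TestPhaseDetector:
    def _ramp(self, n=1500, fs=150.0, cycles_per_s=1.0):
        return wrap_angle(2 * np.pi * cycles_per_s * np.arange(n) / fs)

    def test_ramp_crossings_at_integer_seconds(self):
        phase = self._ramp()
        cal = PhaseCalibration(ref_phase_hs=0.0, ref_phase_to=wrap_angle(2 * np.pi * 0.6), direction=1)
        events = detect_events_from_phase(phase, np.arange(1500), cal, 150.0)
        assert np.allclose(events.heel_strike_times, [1, 2, 3, 4, 5, 6, 7, 8, 9], atol=1 / 150.0)

    def test_quarter_phase_reference(self):
        phase = self._ramp(n=600)
        cal = PhaseCalibration(ref_phase_hs=np.pi / 2, ref_phase_to=-np.pi / 2, direction=1)
        events = detect_events_from_phase(phase, np.arange(600), cal, 150.0)
        assert np.allclose(events.heel_strike_times, [0.25, 1.25, 2.25, 3.25], atol=1 / 150.0)

    def test_backward_jitter_across_reference_detected_once(self):
        fs = 150.0
        phase = np.unwrap(self._ramp(n=450))
        # jitter backwards across the reference right after the first crossing
        k = 160
        phase[k : k + 3] -= 0.2
        events = detect_events_from_phase(
            wrap_angle(phase), np.arange(450),
            PhaseCalibration(ref_phase_hs=0.0, ref_phase_to=np.pi, direction=1), fs
        )
        near_first = np.abs(events.heel_strike_times - 1.0) < 0.2
        assert near_first.sum() == 1

    def test_perfect_phase_gives_subsample_errors(self, walk_small):
        walk = walk_small
        fs = walk.config.sampling_rate
        phase = walk.true_phase["left"]
        truth = walk.true_events["left"]
        cal = PhaseCalibration(
            ref_phase_hs=0.0, ref_phase_to=wrap_angle(2 * np.pi * walk.config.duty_factor), direction=1
        )
        detected = detect_events_from_phase(phase, np.arange(len(phase)), cal, fs)
        reports = compute_time_errors(detected, truth, fs)
        for rep in reports.values():
            assert rep.mean <= 1000.0 / fs  # within one sample


class TestTimeErrors:
    def _sets(self, truth_idx, det_idx, fs=150.0):
        truth = EventSet(
            heel_strike_idx=truth_idx, heel_strike_times=np.asarray(truth_idx) / fs,
            toe_off_idx=[], toe_off_times=[],
        )
        det = EventSet(
            heel_strike_idx=det_idx, heel_strike_times=np.asarray(det_idx) / fs,
            toe_off_idx=[], toe_off_times=[], source="phase_detected",
        )
        return det, truth

    def test_one_sample_is_six_point_six_seven_ms(self):
        det, truth = self._sets([150, 300], [151, 300])
        rep = compute_time_errors(det, truth, 150.0)["heel_strike"]
        assert rep.errors_ms[0] == pytest.approx(6.67, abs=0.01)
        assert rep.errors_ms[1] == 0.0

    def test_exact_match_zero_error(self):
        det, truth = self._sets([10, 160, 310], [10, 160, 310])
        rep = compute_time_errors(det, truth, 150.0)["heel_strike"]
        assert rep.mean == 0.0 and rep.sd == 0.0 and rep.n_matched == 3

    def test_missing_detection_counted_not_scored(self):
        det, truth = self._sets([10, 160, 310], [12, 313])
        rep = compute_time_errors(det, truth, 150.0)["heel_strike"]
        assert rep.n_matched == 2
        assert rep.n_unmatched_truth == 1
        assert rep.mean == pytest.approx(np.mean([2, 3]) / 150.0 * 1000.0)

    def test_aggregates_match_bruteforce(self, rng):
        truth_idx = np.sort(rng.choice(np.arange(100, 5000, 150), size=20, replace=False))
        det_idx = truth_idx + rng.integers(-3, 4, size=20)
        det, truth = self._sets(truth_idx, np.sort(det_idx))
        rep = compute_time_errors(det, truth, 150.0)["heel_strike"]
        assert rep.mean == pytest.approx(float(np.mean(rep.errors_ms)))
        assert rep.sd == pytest.approx(float(np.std(rep.errors_ms)))


class TestCrossval:
    def test_forty_subjects_split_24_8_8(self):
        plan = crossval_split(list(range(40)), k=4, seed=0)
        assert len(plan.folds) == 4
        for fold in plan.folds:
            assert (len(fold["train"]), len(fold["validation"]), len(fold["test"])) == (24, 8, 8)

    def test_same_seed_reproduces_plan(self):
        a = crossval_split(list(range(40)), k=4, seed=9)
        b = crossval_split(list(range(40)), k=4, seed=9)
        assert a.folds == b.folds

    def test_groups_disjoint_and_tests_rotate(self):
        plan = crossval_split(list(range(40)), k=4, seed=2)
        test_sets = [frozenset(f["test"]) for f in plan.folds]
        assert len(set(test_sets)) == 4  # distinct test groups per fold
        for fold in plan.folds:
            assert not (set(fold["train"]) & set(fold["test"]))
            assert not (set(fold["train"]) & set(fold["validation"]))

    def test_uneven_subject_count_nearest_integer(self):
        plan = crossval_split(list(range(17)), k=2, seed=1)
        for fold in plan.folds:
            total = len(fold["train"]) + len(fold["validation"]) + len(fold["test"])
            assert total == 17
            assert 2 <= len(fold["test"]) <= 4

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            crossval_split([1, 2, 3], k=4)
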