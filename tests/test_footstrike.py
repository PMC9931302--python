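import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitrisk.errors import InsufficientDataError, ParameterError, ValidationError
from gaitrisk.footstrike import (
    DetectorConfig,
    FootStrikeEvents,
    FrameLabels,
    LockingPeriod,
    collapse_duplicates,
    compute_locking_period,
    detect_frames,
    detection_metrics,
    insert_missed,
    label_rule_based,
    load_detector,
    match_events,
    postprocess,
    save_detector,
    train_detector,
)
from gaitrisk.signal_io import ImuRecording, preprocess
from gaitrisk.synthetic_gait import GaitSimParams, degrade_labels, generate_walk

from conftest import strike_offsets


def pulse_recording(drop_vert_at=None, n_pulses=30, rate=50.0):
    """AP pulses every 0.5 s, each followed 0.04 s later by a vertical pulse.

    ``drop_vert_at`` suppresses the vertical pulse after that strike index.
    """
    duration = (n_pulses + 2) * 0.5
    t = np.arange(int(duration * rate)) / rate
    centers = 0.5 + np.arange(n_pulses) * 0.5
    ap = np.zeros_like(t)
    vert = np.zeros_like(t)
    for i, c in enumerate(centers):
        ap += 1.5 * np.exp(-0.5 * ((t - c) / 0.05) ** 2)
        if i != drop_vert_at:
            vert += 1.2 * np.exp(-0.5 * ((t - c - 0.04) / 0.05) ** 2)
    ml = 0.8 * np.cos(2 * np.pi * (t - centers[0]) / 1.0)
    return ImuRecording(
        timestamps=t, lin_accel_ap=ap, lin_accel_ml=ml, lin_accel_vert=vert,
        sample_rate=rate,
    ), np.round(centers * rate).astype(int)


class TestRuleBased:
    def test_noise_free_walk_fully_recovered(self, clean_walk):
        rec, truth = clean_walk
        events = label_rule_based(rec)
        offsets = strike_offsets(events.frames, truth.frames)
        assert np.all(offsets <= 1)
        assert len(events) == len(truth)

    def test_flat_signal_gives_empty_list(self):
        n = 500
        rec = ImuRecording(
            timestamps=np.arange(n) / 50.0,
            lin_accel_ap=np.zeros(n), lin_accel_vert=np.zeros(n), sample_rate=50.0,
        )
        assert len(label_rule_based(rec)) == 0

    def test_ap_peak_without_vertical_peak_is_not_an_event(self):
        rec, centers = pulse_recording(drop_vert_at=15)
        events = label_rule_based(rec)
        gaps = np.min(np.abs(events.frames[:, None] - centers[None, :]), axis=0)
        assert gaps[15] > 2  # the orphan AP peak was rejected
        assert np.all(gaps[np.arange(len(centers)) != 15] <= 1)

    def test_sides_alternate_anchored_on_ml_sway(self, clean_walk):
        rec, truth = clean_walk
        events = label_rule_based(rec)
        assert set(events.sides) == {"left", "right"}
        matched = [truth.sides[int(np.argmin(np.abs(truth.frames - f)))]
                   for f in events.frames]
        assert matched == events.sides


class TestLockingPeriod:
    def sinusoid_recording(self, freq, n=500, rate=50.0):
        t = np.arange(n) / rate
        return ImuRecording(
            timestamps=t, lin_accel_vert=np.sin(2 * np.pi * freq * t),
            sample_rate=rate,
        )

    @pytest.mark.parametrize("freq,expected", [(2.0, 12), (1.0, 25)])
    def test_sinusoid_period(self, freq, expected):
        assert compute_locking_period(self.sinusoid_recording(freq)).frames == expected

    def test_white_noise_returns_clamp_bound(self):
        rng = np.random.default_rng(0)
        rec = ImuRecording(
            timestamps=np.arange(500) / 50.0, lin_accel_vert=rng.normal(size=500),
            sample_rate=50.0,
        )
        assert compute_locking_period(rec).frames == 10

    def test_short_recording_rejected(self):
        with pytest.raises(InsufficientDataError):
            compute_locking_period(self.sinusoid_recording(2.0, n=100))

    def test_clamp_bounds_enforced_on_type(self):
        with pytest.raises(ValidationError):
            LockingPeriod(5)
        with pytest.raises(ValidationError):
            LockingPeriod(50)


class TestCollapseDuplicates:
    def test_run_collapses_to_ap_maximum(self):
        n = 400
        labels = FrameLabels.from_frames([240, 241, 242], n)
        ap = np.zeros(n)
        ap[[240, 241, 242]] = [0.5, 1.0, 0.6]
        events = collapse_duplicates(labels, ap)
        assert list(events.frames) == [241]

    def test_isolated_labels_pass_through(self):
        n = 300
        labels = FrameLabels.from_frames([50, 120, 200], n)
        events = collapse_duplicates(labels, np.zeros(n))
        assert list(events.frames) == [50, 120, 200]

    def test_all_zero_labels_give_no_events(self):
        assert len(collapse_duplicates(FrameLabels(np.zeros(100)), np.zeros(100))) == 0

    def test_equal_ap_tie_breaks_to_earliest_frame(self):
        labels = FrameLabels.from_frames([10, 11, 12], 50)
        events = collapse_duplicates(labels, np.zeros(50))
        assert list(events.frames) == [10]

    @settings(derandomize=True, max_examples=50)
    @given(data=st.data())
    def test_never_increases_events_and_idempotent(self, data):
        n = 120
        labels = np.array(data.draw(st.lists(
            st.integers(0, 1), min_size=n, max_size=n)), dtype=np.int8)
        ap = np.asarray(data.draw(st.lists(
            st.floats(-2, 2, allow_nan=False), min_size=n, max_size=n)))
        events = collapse_duplicates(FrameLabels(labels), ap)
        runs = np.flatnonzero(np.diff(np.pad(labels, 1)) == 1).size
        assert len(events) <= runs
        again = collapse_duplicates(events.to_frame_labels(n), ap)
        np.testing.assert_array_equal(again.frames, events.frames)


class TestInsertMissed:
    def test_single_missed_step_inserted_at_ap_peak(self):
        ap = np.zeros(400)
        ap[239:242] = [0.5, 1.0, 0.5]
        events = FootStrikeEvents.from_frames([100, 150, 330])
        out = insert_missed(events, ap, LockingPeriod(20))
        assert list(out.frames) == [100, 150, 240, 330]

    def test_uniform_spacing_unchanged(self):
        events = FootStrikeEvents.from_frames(list(range(50, 500, 50)))
        out = insert_missed(events, np.zeros(600), LockingPeriod(20))
        np.testing.assert_array_equal(out.frames, events.frames)

    def test_fewer_than_three_events_unchanged(self):
        events = FootStrikeEvents.from_frames([100, 330])
        out = insert_missed(events, np.zeros(400), LockingPeriod(20))
        np.testing.assert_array_equal(out.frames, events.frames)

    def test_never_removes_events(self):
        rng = np.random.default_rng(7)
        frames = np.unique(rng.integers(0, 900, 15))
        ap = rng.normal(size=1000)
        events = FootStrikeEvents.from_frames(frames)
        out = insert_missed(events, ap, LockingPeriod(10))
        assert set(frames).issubset(set(out.frames))
        assert np.all(np.diff(out.frames) > 0)


class TestPostprocess:
    def test_repairs_degraded_labels(self, noisy_walk):
        rec, truth = noisy_walk
        labels = truth.to_frame_labels(rec.n_frames)
        degraded = degrade_labels(labels, drop_rate=0.1, duplicate_rate=0.3, seed=11)
        events = postprocess(degraded, rec)
        assert match_events(events, truth, tolerance_frames=2) >= 0.90

    def test_clean_truth_labels_are_fixed_point(self, clean_walk):
        rec, truth = clean_walk
        events = postprocess(truth.to_frame_labels(rec.n_frames), rec)
        np.testing.assert_array_equal(events.frames, truth.frames)

    def test_rule_based_and_postprocessed_truth_agree_on_clean_walk(self, clean_walk):
        rec, truth = clean_walk
        via_rule = label_rule_based(rec)
        via_post = postprocess(truth.to_frame_labels(rec.n_frames), rec)
        offsets = strike_offsets(via_rule.frames, via_post.frames)
        assert np.all(offsets <= 1)

    def test_empty_labels_give_empty_events(self, noisy_walk):
        rec, _ = noisy_walk
        events = postprocess(FrameLabels(np.zeros(rec.n_frames)), rec)
        assert len(events) == 0

    def test_events_strictly_increasing_with_half_lock_separation(self, noisy_walk):
        rec, truth = noisy_walk
        degraded = degrade_labels(
            truth.to_frame_labels(rec.n_frames), 0.2, 0.4, jitter_frames=1, seed=3
        )
        events = postprocess(degraded, rec)
        lock = compute_locking_period(rec).frames
        diffs = np.diff(events.frames)
        assert np.all(diffs > 0)
        assert np.all(diffs >= lock // 2)


class TestDetectionMetrics:
    def test_perfect_prediction(self):
        truth = FrameLabels.from_frames([10, 40, 70], 100)
        assert detection_metrics(truth, truth) == (1.0, 1.0, 1.0)

    def test_all_zero_prediction_closed_form(self):
        truth = FrameLabels.from_frames([10, 40, 70], 100)
        pred = FrameLabels(np.zeros(100))
        acc, sens, spec = detection_metrics(pred, truth)
        assert acc == pytest.approx(97 / 100)
        assert sens == 0.0
        assert spec == 1.0

    def test_shifted_prediction_with_tolerance(self):
        truth = FrameLabels.from_frames([10, 40, 70], 100)
        pred = FrameLabels.from_frames([12, 42, 72], 100)
        acc, sens, spec = detection_metrics(pred, truth, tolerance_frames=2)
        assert sens == 1.0 and spec == 1.0 and acc == 1.0
        # without tolerance the same shift scores zero sensitivity
        assert detection_metrics(pred, truth)[1] == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            detection_metrics(FrameLabels(np.zeros(10)), FrameLabels(np.zeros(11)))


def small_training_walks(n_walks=3, duration=30.0, seed0=100):
    walks = []
    for i in range(n_walks):
        params = GaitSimParams(duration=duration, cadence=100.0 + 5 * i,
                               noise_sd=0.12, seed=seed0 + i)
        rec, events = generate_walk(params)
        rec = preprocess(rec)
        walks.append((rec, events.to_frame_labels(rec.n_frames)))
    return walks


FAST_CONFIG = DetectorConfig(max_iter=60)


@pytest.fixture(scope="module")
def walks():
    return small_training_walks()


@pytest.fixture(scope="module")
def model(walks):
    return train_detector(walks[:2], FAST_CONFIG, seed=7)


class TestTrainableDetector:
    def test_training_is_reproducible(self, walks, model):
        model_b = train_detector(walks[:2], FAST_CONFIG, seed=7)
        rec, _ = walks[2]
        np.testing.assert_array_equal(
            detect_frames(model, rec).labels, detect_frames(model_b, rec).labels
        )

    def test_overfit_walk_has_high_sensitivity(self, walks, model):
        rec, truth = walks[0]
        pred = detect_frames(model, rec)
        _, sens, _ = detection_metrics(pred, truth, tolerance_frames=2)
        assert sens >= 0.9

    def test_label_length_matches_frames(self, walks, model):
        rec, _ = walks[2]
        assert len(detect_frames(model, rec)) == rec.n_frames

    def test_all_zero_labels_give_constant_predictor(self, walks):
        rec, _ = walks[0]
        degenerate = [(rec, FrameLabels(np.zeros(rec.n_frames)))]
        model = train_detector(degenerate, FAST_CONFIG, seed=0)
        assert detect_frames(model, rec).labels.sum() == 0

    def test_empty_training_set_rejected(self):
        with pytest.raises(ParameterError):
            train_detector([], FAST_CONFIG, seed=0)

    def test_channel_mismatch_rejected(self, model):
        n = 600
        rec = ImuRecording(
            timestamps=np.arange(n) / 50.0,
            lin_accel_ap=np.zeros(n), lin_accel_ml=np.zeros(n),
            lin_accel_vert=np.zeros(n), sample_rate=50.0,
        )
        with pytest.raises(ValidationError, match="channels"):
            detect_frames(model, rec)

    def test_recording_shorter_than_window_rejected(self, model, walks):
        rec, _ = walks[0]
        short = ImuRecording(
            timestamps=rec.timestamps[:8],
            **{name: arr[:8] for name, arr in rec.channels()},
            sample_rate=rec.sample_rate,
        )
        with pytest.raises(ValidationError, match="window"):
            detect_frames(model, short)

    def test_model_round_trips_through_file(self, model, walks, tmp_path):
        path = tmp_path / "detector.joblib"
        save_detector(model, path)
        assert path.with_suffix(".joblib.json").exists()
        back = load_detector(path)
        rec, _ = walks[2]
        np.testing.assert_array_equal(
            detect_frames(back, rec).labels, detect_frames(model, rec).labels
        )
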