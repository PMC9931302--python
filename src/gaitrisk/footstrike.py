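"""Per-frame foot-strike detection and post-processing.

A foot strike (foot-ground contact) shows up in a pelvis-worn IMU as a peak
in anterior-posterior (AP) linear acceleration followed closely by a peak in
vertical acceleration.  Two detectors are provided:

* :func:`label_rule_based` — the peak-ordering rule applied directly to the
  filtered signals; it serves as the reference labeller.
* :class:`DetectorModel` via :func:`train_detector` / :func:`detect_frames`
  — a trainable windowed sequence labeller (multi-layer perceptron over
  sliding windows of the movement channels, with a probability peak-picking
  decoder) that learns per-frame strike probability from labelled walks.

Raw per-frame predictions are cleaned by the post-processing pipeline:
runs of consecutive positive labels collapse to the single frame of peak AP
acceleration; abnormally long inter-strike gaps (longer than 1.5x the
preceding step) are searched for a missed strike, with the search window
shrunk by half the adaptive locking period at each end; sides are assigned
by alternation anchored on the medio-lateral acceleration sign.

The adaptive locking period — a refractory interval during which no second
strike may be declared — is derived per trial from the dominant step
period of the first five seconds of filtered vertical acceleration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sp_signal
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .errors import InsufficientDataError, ParameterError, ValidationError
from .signal_io import ImuRecording

#: movement channels fed to the trainable detector, in fixed order
DETECTOR_CHANNELS = (
    "lin_accel_ap",
    "lin_accel_ml",
    "lin_accel_vert",
    "gyro_x",
    "gyro_y",
    "gyro_z",
    "tilt",
    "obliquity",
    "rotation",
)

LOCK_CLAMP = (10, 35)  # frames at 50 Hz


@dataclass
class FrameLabels:
    """Binary per-frame labels: 1 = foot strike present, 0 = absent."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValidationError("frame labels must be 0 or 1")
        self.labels = arr.astype(np.int8)

    def __len__(self) -> int:
        return int(self.labels.size)

    @property
    def strike_frames(self) -> np.ndarray:
        return np.flatnonzero(self.labels)

    @classmethod
    def from_frames(cls, frames: Sequence[int], n_frames: int) -> "FrameLabels":
        labels = np.zeros(n_frames, dtype=np.int8)
        labels[np.asarray(frames, dtype=int)] = 1
        return cls(labels)


@dataclass
class FootStrikeEvents:
    """Ordered foot-strike events: frame index, time in seconds, side."""

    frames: np.ndarray
    times: np.ndarray
    sides: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.size != self.times.size:
            raise ValidationError("frames and times must have equal length")
        if not self.sides:
            self.sides = ["unknown"] * self.frames.size
        if len(self.sides) != self.frames.size:
            raise ValidationError("sides must match the number of events")
        if self.frames.size > 1 and not (np.diff(self.frames) > 0).all():
            raise ValidationError("event frames must be strictly increasing")

    def __len__(self) -> int:
        return int(self.frames.size)

    def to_frame_labels(self, n_frames: int) -> FrameLabels:
        return FrameLabels.from_frames(self.frames, n_frames)

    @classmethod
    def from_frames(
        cls,
        frames: Sequence[int],
        timestamps: np.ndarray | None = None,
        rate: float = 50.0,
        sides: list[str] | None = None,
    ) -> "FootStrikeEvents":
        frames = np.asarray(frames, dtype=int)
        if timestamps is not None:
            times = np.asarray(timestamps, dtype=float)[frames] if frames.size else np.array([])
        else:
            times = frames / rate
        return cls(frames=frames, times=times, sides=sides or [])


@dataclass
class LockingPeriod:
    """Refractory interval (frames) after a strike; adaptive per trial."""

    frames: int

    def __post_init__(self) -> None:
        lo, hi = LOCK_CLAMP
        if not lo <= self.frames <= hi:
            raise ValidationError(
                f"locking period {self.frames} outside clamp bounds {LOCK_CLAMP}"
            )


# ---------------------------------------------------------------------------
# rule-based labelling

def compute_locking_period(
    rec: ImuRecording,
    sample_seconds: float = 5.0,
    clamp: tuple[int, int] = LOCK_CLAMP,
) -> LockingPeriod:
    """Adaptive locking period from the trial's opening vertical signal.

    The step period is estimated from the autocorrelation of the first
    ``sample_seconds`` of filtered vertical acceleration, searched over
    physiological step periods (0.25-1.2 s).  The *first* sufficiently
    prominent peak is used rather than the global maximum: with
    asymmetric gait the stride lag (where both feet's pulses align)
    correlates more strongly than the step lag, and picking it would
    double the locking period and suppress alternate strikes.  The
    locking period is half the step period (floored), clamped to
    ``clamp``.  A signal with no clear periodicity (peak autocorrelation
    below 0.25) falls back to the lower clamp bound.
    """
    rec.require("lin_accel_vert")
    if rec.sample_rate is None:
        raise ValidationError("recording must be uniformly sampled")
    fs = rec.sample_rate
    n = int(round(sample_seconds * fs))
    if rec.n_frames < n:
        raise InsufficientDataError(
            f"recording shorter than {sample_seconds} s locking sample"
        )
    x = rec.lin_accel_vert[:n] - rec.lin_accel_vert[:n].mean()
    denom = float(np.dot(x, x))
    lo, hi = clamp
    if denom <= 0:
        return LockingPeriod(lo)
    ac = np.correlate(x, x, mode="full")[n - 1 :] / denom
    lag_min = max(2, int(round(0.25 * fs)))
    lag_max = min(n - 2, int(round(1.2 * fs)))
    if lag_max <= lag_min:
        return LockingPeriod(lo)
    peaks, _ = sp_signal.find_peaks(ac[lag_min : lag_max + 1])
    if peaks.size == 0:
        return LockingPeriod(lo)
    peaks += lag_min
    strongest = float(np.max(ac[peaks]))
    if strongest < 0.25:
        return LockingPeriod(lo)
    step_lag = int(peaks[np.flatnonzero(ac[peaks] >= 0.7 * strongest)[0]])
    lock = int(np.floor(0.5 * step_lag))
    return LockingPeriod(int(np.clip(lock, lo, hi)))


def label_rule_based(
    rec: ImuRecording,
    vert_window_s: float = 0.1,
    min_prominence_sd: float = 0.5,
) -> FootStrikeEvents:
    """Reference labeller: AP peaks immediately followed by a vertical peak.

    AP local maxima separated by at least the adaptive locking period and
    prominent relative to the AP signal's spread are kept as strikes when a
    vertical local maximum occurs within ``vert_window_s`` after them.
    Flat or empty signals yield an empty event list.
    """
    rec.require("lin_accel_ap", "lin_accel_vert")
    if rec.sample_rate is None:
        raise ValidationError("recording must be uniformly sampled")
    fs = rec.sample_rate
    ap = rec.lin_accel_ap
    vert = rec.lin_accel_vert
    ap_sd = float(np.std(ap))
    if ap_sd == 0.0:
        return FootStrikeEvents.from_frames([], rec.timestamps, fs)
    lock = compute_locking_period(rec).frames
    ap_peaks, _ = sp_signal.find_peaks(
        ap, distance=lock, prominence=min_prominence_sd * ap_sd
    )
    vert_peaks, _ = sp_signal.find_peaks(vert)
    window = int(round(vert_window_s * fs))
    keep = []
    for p in ap_peaks:
        follow = vert_peaks[(vert_peaks > p) & (vert_peaks <= p + window)]
        if follow.size:
            keep.append(int(p))
    events = FootStrikeEvents.from_frames(keep, rec.timestamps, fs)
    return assign_sides(events, rec)


def assign_sides(events: FootStrikeEvents, rec: ImuRecording) -> FootStrikeEvents:
    """Attribute alternating left/right sides.

    The first strike's side is seeded by the sign of medio-lateral
    acceleration at that frame (positive = rightward sway = right foot in
    this package's body-frame convention); subsequent strikes alternate.
    With a flat or absent ML channel all sides stay ``unknown``.
    """
    if len(events) == 0:
        return events
    ml = rec.lin_accel_ml
    if ml is None:
        return events
    first_ml = float(ml[events.frames[0]])
    scale = float(np.std(ml))
    if scale == 0.0 or abs(first_ml) < 1e-3 * max(scale, 1.0):
        return events
    first = "right" if first_ml > 0 else "left"
    other = "left" if first == "right" else "right"
    sides = [first if i % 2 == 0 else other for i in range(len(events))]
    return FootStrikeEvents(frames=events.frames, times=events.times, sides=sides)


# ---------------------------------------------------------------------------
# post-processing corrections

def collapse_duplicates(
    labels: FrameLabels,
    ap: np.ndarray,
    timestamps: np.ndarray | None = None,
    rate: float = 50.0,
) -> FootStrikeEvents:
    """Collapse runs of consecutive positive labels to single events.

    Each maximal run of consecutive 1-labels becomes one event at the frame
    of maximum AP acceleration within the run (earliest frame on ties);
    isolated labels pass through unchanged.
    """
    ap = np.asarray(ap, dtype=float)
    lab = labels.labels
    if lab.size != ap.size:
        raise ValidationError("labels and AP series must have equal length")
    frames: list[int] = []
    ones = np.flatnonzero(lab)
    if ones.size:
        splits = np.flatnonzero(np.diff(ones) > 1) + 1
        for run in np.split(ones, splits):
            frames.append(int(run[np.argmax(ap[run])]))
    return FootStrikeEvents.from_frames(frames, timestamps, rate)


def insert_missed(
    events: FootStrikeEvents,
    ap: np.ndarray,
    lock: LockingPeriod,
    gap_factor: float = 1.5,
    timestamps: np.ndarray | None = None,
    rate: float = 50.0,
    max_passes: int = 20,
) -> FootStrikeEvents:
    """Insert strikes missed inside abnormally long inter-strike gaps.

    A gap longer than ``gap_factor`` times the preceding step duration is
    searched for a missed strike; the search range is shrunk by half the
    locking period at each end so a strike is never inserted on top of the
    gap's endpoints.  The inserted frame is the highest AP local peak in
    the shrunken range.  Passes repeat until no qualifying gap gains an
    event.  The preceding step for the first gap, where no earlier step
    exists, is the trial-median inter-strike interval.  Fewer than three
    events are returned unchanged (no preceding step is defined).
    """
    ap = np.asarray(ap, dtype=float)
    if len(events) < 3:
        return events
    if events.frames.max() >= ap.size:
        raise ValidationError("AP series does not cover all event frames")
    half_lock = int(np.ceil(lock.frames / 2))
    frames = list(int(f) for f in events.frames)
    for _ in range(max_passes):
        intervals = np.diff(frames)
        median_step = float(np.median(intervals))
        inserted = False
        i = 0
        while i < len(frames) - 1:
            gap = frames[i + 1] - frames[i]
            prev_step = frames[i] - frames[i - 1] if i >= 1 else median_step
            if gap > gap_factor * prev_step:
                start = frames[i] + half_lock
                end = frames[i + 1] - half_lock
                if end > start:
                    seg = ap[start : end + 1]
                    peaks, _ = sp_signal.find_peaks(seg)
                    if peaks.size:
                        cand = start + int(peaks[np.argmax(seg[peaks])])
                        frames.insert(i + 1, cand)
                        inserted = True
                        i += 1  # re-examine remaining portion of the old gap
                        continue
            i += 1
        if not inserted:
            break
    return FootStrikeEvents.from_frames(frames, timestamps, rate)


def postprocess(
    labels: FrameLabels,
    rec: ImuRecording,
    gap_factor: float = 1.5,
) -> FootStrikeEvents:
    """Full correction pipeline for raw per-frame predictions.

    collapse consecutive duplicates -> adaptive locking period ->
    missed-step insertion -> alternating side assignment.
    """
    rec.require("lin_accel_ap")
    if len(labels) != rec.n_frames:
        raise ValidationError("labels must align with the recording")
    rate = rec.sample_rate or 50.0
    events = collapse_duplicates(
        labels, rec.lin_accel_ap, timestamps=rec.timestamps, rate=rate
    )
    if len(events) >= 3:
        lock = compute_locking_period(rec)
        events = insert_missed(
            events,
            rec.lin_accel_ap,
            lock,
            gap_factor=gap_factor,
            timestamps=rec.timestamps,
            rate=rate,
        )
    return assign_sides(events, rec)


# ---------------------------------------------------------------------------
# detection metrics

def detection_metrics(
    pred: FrameLabels,
    truth: FrameLabels,
    tolerance_frames: int = 0,
) -> tuple[float, float, float]:
    """Frame-wise accuracy, sensitivity and specificity.

    With ``tolerance_frames > 0`` a predicted strike within that many
    frames of a true strike counts as correct (and the true strike as
    detected), the usual allowance for one-frame timing jitter.
    """
    p = pred.labels
    t = truth.labels
    if p.size != t.size:
        raise ValidationError("prediction and truth must have equal length")
    n = t.size
    if tolerance_frames <= 0:
        tp = int(np.sum((p == 1) & (t == 1)))
        fn = int(np.sum((p == 0) & (t == 1)))
        fp = int(np.sum((p == 1) & (t == 0)))
        tn = n - tp - fn - fp
    else:
        truth_frames = np.flatnonzero(t)
        pred_frames = np.flatnonzero(p)
        tol = tolerance_frames
        if truth_frames.size and pred_frames.size:
            # nearest-neighbour distance in frames, both directions
            d_truth = np.min(
                np.abs(truth_frames[:, None] - pred_frames[None, :]), axis=1
            )
            d_pred = np.min(
                np.abs(pred_frames[:, None] - truth_frames[None, :]), axis=1
            )
        else:
            d_truth = np.full(truth_frames.size, np.inf)
            d_pred = np.full(pred_frames.size, np.inf)
        tp = int(np.sum(d_truth <= tol))
        fn = int(truth_frames.size - tp)
        fp = int(np.sum(d_pred > tol))
        tn = n - truth_frames.size - fp
    accuracy = (tp + tn) / n
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    return accuracy, sensitivity, specificity


def match_events(
    pred: FootStrikeEvents, truth: FootStrikeEvents, tolerance_frames: int = 2
) -> float:
    """Fraction of true strikes matched by a prediction within tolerance."""
    if len(truth) == 0:
        return float("nan")
    if len(pred) == 0:
        return 0.0
    d = np.min(np.abs(truth.frames[:, None] - pred.frames[None, :]), axis=1)
    return float(np.mean(d <= tolerance_frames))


# ---------------------------------------------------------------------------
# trainable sequence labeller

@dataclass
class DetectorConfig:
    """Hyperparameters of the windowed MLP sequence labeller."""

    window_radius: int = 7
    hidden_size: int = 64
    max_iter: int = 200
    channels: tuple[str, ...] = DETECTOR_CHANNELS
    negative_ratio: float = 4.0  # negatives kept per positive during training
    peak_decode: bool = True  # decode probabilities by local-maximum picking


@dataclass
class DetectorModel:
    """Trained per-frame strike labeller (opaque weights + config + seed)."""

    config: DetectorConfig
    seed: int
    scaler: StandardScaler | None
    mlp: MLPClassifier | None
    constant_label: int | None = None  # degenerate single-class training sets
    threshold: float = 0.5


def _window_matrix(rec: ImuRecording, config: DetectorConfig) -> np.ndarray:
    rec.require(*config.channels)
    w = config.window_radius
    stack = np.stack([getattr(rec, c) for c in config.channels], axis=1)
    padded = np.pad(stack, ((w, w), (0, 0)), mode="reflect")
    n = rec.n_frames
    windows = np.lib.stride_tricks.sliding_window_view(padded, 2 * w + 1, axis=0)
    return windows.reshape(n, -1)


def train_detector(
    training: list[tuple[ImuRecording, FrameLabels]],
    config: DetectorConfig | None = None,
    seed: int = 0,
) -> DetectorModel:
    """Fit the windowed sequence labeller on labelled walks.

    Frames are featurized as standardized sliding windows of the movement
    channels.  Class imbalance (one strike frame per ~25) is handled by
    keeping every positive frame, all near-miss negatives within the
    window radius, and a seeded random subsample of the remaining
    negatives.  Training is deterministic given the seed.
    """
    if not training:
        raise ParameterError("training set must contain at least one recording")
    config = config or DetectorConfig()
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for rec, labels in training:
        if len(labels) != rec.n_frames:
            raise ValidationError("labels must align with their recording")
        X = _window_matrix(rec, config)
        y = labels.labels.astype(int)
        pos = np.flatnonzero(y)
        if pos.size:
            near = np.unique(
                np.clip(
                    pos[:, None] + np.arange(-config.window_radius, config.window_radius + 1),
                    0,
                    y.size - 1,
                )
            )
            far = np.setdiff1d(np.flatnonzero(y == 0), near, assume_unique=False)
            n_far = min(far.size, int(config.negative_ratio * pos.size))
            far = rng.choice(far, size=n_far, replace=False) if n_far else far[:0]
            idx = np.sort(np.concatenate([near, far]))
        else:
            idx = np.arange(y.size)
        xs.append(X[idx])
        ys.append(y[idx])
    X = np.concatenate(xs)
    y = np.concatenate(ys)
    if np.unique(y).size < 2:
        return DetectorModel(
            config=config, seed=seed, scaler=None, mlp=None,
            constant_label=int(y[0]) if y.size else 0,
        )
    scaler = StandardScaler().fit(X)
    mlp = MLPClassifier(
        hidden_layer_sizes=(config.hidden_size,),
        max_iter=config.max_iter,
        random_state=seed,
        early_stopping=False,
    )
    mlp.fit(scaler.transform(X), y)
    return DetectorModel(config=config, seed=seed, scaler=scaler, mlp=mlp)


MODEL_FORMAT_VERSION = 1


def save_detector(model: DetectorModel, path) -> None:
    """Persist a detector as an opaque binary with a JSON config sidecar."""
    import json
    from pathlib import Path

    import joblib

    path = Path(path)
    joblib.dump({"format_version": MODEL_FORMAT_VERSION, "model": model}, path)
    sidecar = {
        "format_version": MODEL_FORMAT_VERSION,
        "seed": model.seed,
        "window_radius": model.config.window_radius,
        "hidden_size": model.config.hidden_size,
        "max_iter": model.config.max_iter,
        "channels": list(model.config.channels),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2) + "\n"
    )


def load_detector(path) -> DetectorModel:
    import joblib

    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValidationError(f"unsupported detector model file: {path}")
    return payload["model"]


def detect_frames(model: DetectorModel, rec: ImuRecording) -> FrameLabels:
    """Per-frame strike labels from a trained detector.

    With peak decoding (default) a frame is labelled 1 only where the
    predicted strike probability exceeds the threshold *and* is a local
    maximum over the surrounding window radius, which keeps raw
    predictions close to one frame per strike.
    """
    if model.constant_label is not None:
        return FrameLabels(np.full(rec.n_frames, model.constant_label, dtype=np.int8))
    missing = [c for c in model.config.channels if getattr(rec, c) is None]
    if missing:
        raise ValidationError(
            f"recording lacks channels the detector was trained on: {missing}"
        )
    if rec.n_frames < 2 * model.config.window_radius + 1:
        raise ValidationError(
            "recording shorter than the detector window; cannot run inference"
        )
    X = model.scaler.transform(_window_matrix(rec, model.config))
    proba = model.mlp.predict_proba(X)[:, list(model.mlp.classes_).index(1)]
    if not model.config.peak_decode:
        return FrameLabels((proba >= model.threshold).astype(np.int8))
    labels = np.zeros(rec.n_frames, dtype=np.int8)
    w = model.config.window_radius
    cand, _ = sp_signal.find_peaks(proba, height=model.threshold, distance=max(1, w))
    labels[cand] = 1
    return FrameLabels(labels)
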