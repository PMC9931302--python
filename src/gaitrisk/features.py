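"""Step segmentation and the 62-feature-per-step registry.

The walk is tiled into step windows between consecutive foot strikes of
either foot.  For every included step, 62 features are computed in a fixed
registry order:

* 5 temporal — cadence, right/left step time, stride time, and the
  Robinson symmetry index |tR - tL| / (0.5 (tR + tL)) * 100;
* 27 descriptive — min/max/mean of the three linear acceleration axes,
  mean and range of the pelvis orientation angles, and SD and RMS of all
  six movement channels;
* 30 spectral — quartile, maximum, SD and peak-distinction of the
  single-sided FFT magnitude spectrum plus the ratio of even-to-odd
  harmonic power (REOH) at multiples of the step frequency, per channel.

Aggregating min, max, mean and sample SD of each feature over all included
steps gives the 248-value participant vector used for classification.

Steps overlapping hallway turns are excluded by default (mean absolute
pelvis rotation rate above 45 deg/s), since turning strides are not
representative of steady-state gait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, ParameterError, ValidationError
from .footstrike import FootStrikeEvents
from .signal_io import ImuRecording

#: short channel tag -> ImuRecording attribute
FEATURE_CHANNELS = {
    "ml": "lin_accel_ml",
    "ap": "lin_accel_ap",
    "vert": "lin_accel_vert",
    "tilt": "tilt",
    "rotation": "rotation",
    "obliquity": "obliquity",
}

_ACCEL = ("ml", "ap", "vert")
_ORIENT = ("tilt", "rotation", "obliquity")
_ALL = _ACCEL + _ORIENT

TEMPORAL_FEATURES = (
    "cadence",
    "step_time_right",
    "step_time_left",
    "stride_time",
    "symmetry_index",
)
DESCRIPTIVE_FEATURES = tuple(
    [f"min_{c}" for c in _ACCEL]
    + [f"max_{c}" for c in _ACCEL]
    + [f"mean_{c}" for c in _ACCEL]
    + [f"mean_{c}" for c in _ORIENT]
    + [f"range_{c}" for c in _ORIENT]
    + [f"sd_{c}" for c in _ALL]
    + [f"rms_{c}" for c in _ALL]
)
SPECTRAL_FEATURES = tuple(
    f"{stat}_{c}"
    for stat in ("quartile_fft", "max_fft", "sd_fft", "peak_distinction_fft", "reoh")
    for c in _ALL
)

#: the full 62-feature registry, order stable across runs
FEATURE_REGISTRY: tuple[str, ...] = TEMPORAL_FEATURES + DESCRIPTIVE_FEATURES + SPECTRAL_FEATURES
assert len(FEATURE_REGISTRY) == 62

AGGREGATE_STATS = ("min", "max", "mean", "sd")

#: 248 aggregated names, feature-major (f1_min, f1_max, f1_mean, f1_sd, f2_min, ...)
PARTICIPANT_REGISTRY: tuple[str, ...] = tuple(
    f"{f}_{s}" for f in FEATURE_REGISTRY for s in AGGREGATE_STATS
)

TURN_RATE_THRESHOLD = 45.0  # deg/s of pelvis rotation, mean |rate| over a window
SPECTRUM_NFFT = 256


@dataclass
class StepWindow:
    """Half-open frame range [start, end) between two consecutive strikes."""

    start_frame: int
    end_frame: int
    start_time: float
    end_time: float
    side_of_start: str
    in_turn: bool

    @property
    def duration(self) -> float:
        return self.end_time - self.start_time


@dataclass
class ParticipantVector:
    """248 aggregated step features plus the fall-risk label."""

    values: np.ndarray
    fall_risk: int
    participant_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(PARTICIPANT_REGISTRY):
            raise ValidationError(
                f"participant vector must have {len(PARTICIPANT_REGISTRY)} values"
            )


def segment_steps(
    events: FootStrikeEvents,
    rec: ImuRecording,
    exclude_turns: bool = True,
    turn_threshold: float = TURN_RATE_THRESHOLD,
) -> list[StepWindow]:
    """One window per consecutive event pair, turn windows flagged.

    A window is ``in_turn`` when the absolute pelvis rotation rate
    (derivative of the rotation orientation angle, deg/s) exceeds
    ``turn_threshold`` anywhere in its frames, so any step overlapping a
    turn bout is flagged; flagged windows are dropped when
    ``exclude_turns`` is set.
    """
    if len(events) < 3:
        raise InsufficientDataError(
            f"need at least 3 foot strikes to segment steps, got {len(events)}"
        )
    if rec.rotation is not None:
        rot_rate = np.abs(np.gradient(rec.rotation, rec.timestamps))
    else:
        rot_rate = np.zeros(rec.n_frames)
    windows = []
    for i in range(len(events) - 1):
        a, b = int(events.frames[i]), int(events.frames[i + 1])
        in_turn = bool(np.max(rot_rate[a:b]) > turn_threshold)
        windows.append(
            StepWindow(
                start_frame=a,
                end_frame=b,
                start_time=float(events.times[i]),
                end_time=float(events.times[i + 1]),
                side_of_start=events.sides[i],
                in_turn=in_turn,
            )
        )
    if exclude_turns:
        windows = [w for w in windows if not w.in_turn]
    return windows


def temporal_features(windows: list[StepWindow]) -> np.ndarray:
    """Per-step cadence, right/left step times, stride time, symmetry index.

    Each step contributes its own duration under its starting side; the
    opposite side's step time is taken from the previous window (the next
    one for the first step).  Stride time is the sum of the two.  Unknown
    sides fall back to alternating pseudo-sides with a warning, which
    keeps the symmetry index meaningful while leaving the right/left
    attribution arbitrary.
    """
    if len(windows) < 2:
        raise InsufficientDataError("temporal features need at least 2 step windows")
    sides = [w.side_of_start for w in windows]
    if any(s not in ("left", "right") for s in sides):
        warnings.warn(
            "step sides unknown; attributing alternating pseudo-sides",
            stacklevel=2,
        )
        sides = ["right" if i % 2 == 0 else "left" for i in range(len(windows))]
    out = np.empty((len(windows), len(TEMPORAL_FEATURES)))
    for i, w in enumerate(windows):
        d_own = w.duration
        d_other = windows[i - 1].duration if i > 0 else windows[1].duration
        if sides[i] == "right":
            t_right, t_left = d_own, d_other
        else:
            t_right, t_left = d_other, d_own
        cadence = 60.0 / d_own
        stride = d_own + d_other
        sym = abs(t_right - t_left) / (0.5 * (t_right + t_left)) * 100.0
        out[i] = (cadence, t_right, t_left, stride, sym)
    return out


def window_stats(rec: ImuRecording, w: StepWindow) -> np.ndarray:
    """The 27 descriptive statistics of one step window, registry order."""
    if w.end_frame <= w.start_frame:
        raise ValidationError("empty step window")
    rec.require(*FEATURE_CHANNELS.values())
    seg = {
        tag: getattr(rec, attr)[w.start_frame : w.end_frame]
        for tag, attr in FEATURE_CHANNELS.items()
    }
    vals: list[float] = []
    vals += [float(seg[c].min()) for c in _ACCEL]
    vals += [float(seg[c].max()) for c in _ACCEL]
    vals += [float(seg[c].mean()) for c in _ACCEL]
    vals += [float(seg[c].mean()) for c in _ORIENT]
    vals += [float(np.ptp(seg[c])) for c in _ORIENT]
    vals += [float(seg[c].std()) for c in _ALL]
    vals += [float(np.sqrt(np.mean(seg[c] ** 2))) for c in _ALL]
    return np.asarray(vals)


def _magnitude_spectrum(x: np.ndarray, nfft: int = SPECTRUM_NFFT) -> np.ndarray:
    """Single-sided FFT magnitudes of the mean-removed, zero-padded window."""
    x = x - x.mean()
    return np.abs(np.fft.rfft(x, n=max(nfft, x.size)))


def spectral_features(
    rec: ImuRecording,
    w: StepWindow,
    step_freq: float,
    nfft: int = SPECTRUM_NFFT,
) -> np.ndarray:
    """The 30 frequency-domain features of one step window, registry order.

    Per channel: 25th percentile, maximum and SD of the magnitude
    spectrum; peak distinction (max - mean)/max, 0 for a flat spectrum;
    and REOH, the even-harmonic share of total harmonic power at integer
    multiples of the step frequency up to Nyquist, each harmonic read
    from its nearest spectral bin.
    """
    if step_freq <= 0:
        raise ParameterError(f"step frequency must be positive, got {step_freq}")
    if w.end_frame - w.start_frame < 4:
        raise InsufficientDataError("spectral features need a window of >= 4 frames")
    if rec.sample_rate is None:
        raise ValidationError("recording must be uniformly sampled")
    fs = rec.sample_rate
    quart, mx, sd, pdist, reoh = [], [], [], [], []
    for tag in _ALL:
        x = getattr(rec, FEATURE_CHANNELS[tag])[w.start_frame : w.end_frame]
        mag = _magnitude_spectrum(x, nfft)
        n_used = max(nfft, x.size)
        m_max = float(mag.max())
        quart.append(float(np.percentile(mag, 25)))
        mx.append(m_max)
        sd.append(float(mag.std()))
        pdist.append(0.0 if m_max == 0 else float((m_max - mag.mean()) / m_max))
        harmonics = np.arange(1, int(np.floor((fs / 2) / step_freq)) + 1)
        if harmonics.size == 0:
            reoh.append(0.0)
            continue
        bins = np.clip(
            np.round(harmonics * step_freq * n_used / fs).astype(int), 0, mag.size - 1
        )
        power = mag[bins] ** 2
        even = power[harmonics % 2 == 0].sum()
        total = power.sum()
        reoh.append(float(even / total) if total > 0 else 0.0)
    return np.asarray(quart + mx + sd + pdist + reoh)


def step_features(
    rec: ImuRecording,
    events: FootStrikeEvents,
    exclude_turns: bool = True,
    turn_threshold: float = TURN_RATE_THRESHOLD,
) -> pd.DataFrame:
    """Full 62-feature table, one registry-ordered row per included step.

    The step frequency handed to the spectral features is the trial-level
    rate (strikes - 1) / (time of last - time of first strike).
    """
    windows = segment_steps(events, rec, exclude_turns, turn_threshold)
    if len(windows) < 2:
        raise InsufficientDataError("too few non-turn steps for feature extraction")
    step_freq = (len(events) - 1) / (events.times[-1] - events.times[0])
    temporal = temporal_features(windows)
    rows = [
        np.concatenate(
            [temporal[i], window_stats(rec, w), spectral_features(rec, w, step_freq)]
        )
        for i, w in enumerate(windows)
    ]
    return pd.DataFrame(rows, columns=list(FEATURE_REGISTRY))


def aggregate_participant(
    table: pd.DataFrame,
    fall_risk: int,
    participant_id: str = "",
) -> ParticipantVector:
    """Min/max/mean/sample-SD of each step feature over all included steps."""
    if list(table.columns) != list(FEATURE_REGISTRY):
        raise ValidationError("step table columns must match the feature registry")
    if len(table) < 2:
        raise InsufficientDataError(
            "participant aggregation needs at least 2 steps (sample SD undefined)"
        )
    x = table.to_numpy(dtype=float)
    stats = np.stack(
        [x.min(axis=0), x.max(axis=0), x.mean(axis=0), x.std(axis=0, ddof=1)], axis=1
    )
    return ParticipantVector(
        values=stats.reshape(-1), fall_risk=int(fall_risk), participant_id=participant_id
    )


def vectors_to_frame(vectors: list[ParticipantVector]) -> pd.DataFrame:
    """Stack participant vectors into a labelled DataFrame (CSV-ready)."""
    df = pd.DataFrame(
        [v.values for v in vectors], columns=list(PARTICIPANT_REGISTRY)
    )
    df.insert(0, "participant_id", [v.participant_id for v in vectors])
    df.insert(1, "fall_risk", [v.fall_risk for v in vectors])
    return df


def frame_to_vectors(df: pd.DataFrame) -> list[ParticipantVector]:
    missing = [c for c in ("fall_risk", *PARTICIPANT_REGISTRY) if c not in df.columns]
    if missing:
        raise ValidationError(f"participant table missing columns: {missing[:5]} ...")
    return [
        ParticipantVector(
            values=row[list(PARTICIPANT_REGISTRY)].to_numpy(dtype=float),
            fall_risk=int(row["fall_risk"]),
            participant_id=str(row.get("participant_id", i)),
        )
        for i, (_, row) in enumerate(df.iterrows())
    ]
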