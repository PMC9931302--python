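"""Recording I/O, resampling and zero-phase low-pass filtering.

A six-minute-walk-test (6MWT) recording from a pelvis-worn smartphone is a
set of synchronized channels sampled against a common timestamp vector:
raw accelerometer XYZ in the device frame, gravity-removed linear
acceleration in the body frame (anterior-posterior, medio-lateral,
vertical), angular velocity XYZ, and the pelvis orientation angles
(tilt, obliquity, rotation).

Recordings are exchanged as plain CSV with one fixed header row::

    time_s,ax,ay,az,lin_ap,lin_ml,lin_vert,gx,gy,gz,tilt_deg,obliquity_deg,rotation_deg

Optional channels may be absent from the file; they are stored as ``None``,
never silently zero-filled.  Preprocessing follows the usual gait-analysis
recipe: linear re-interpolation to a uniform 50 Hz grid, then a
fourth-order zero-lag (forward-backward) Butterworth low-pass at 4 Hz.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .errors import FormatError, InsufficientDataError, ParameterError, ValidationError

#: channel attribute -> CSV column, in registry order
CHANNEL_COLUMNS: dict[str, str] = {
    "raw_accel_x": "ax",
    "raw_accel_y": "ay",
    "raw_accel_z": "az",
    "lin_accel_ap": "lin_ap",
    "lin_accel_ml": "lin_ml",
    "lin_accel_vert": "lin_vert",
    "gyro_x": "gx",
    "gyro_y": "gy",
    "gyro_z": "gz",
    "tilt": "tilt_deg",
    "obliquity": "obliquity_deg",
    "rotation": "rotation_deg",
}

TIME_COLUMN = "time_s"

#: channels the low-pass filter is applied to (body-frame linear
#: acceleration, angular velocity, orientation; raw device-frame
#: acceleration is kept untouched for reference)
FILTERED_CHANNELS = (
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


@dataclass
class FilterSpec:
    """Zero-lag Butterworth low-pass specification.

    Defaults match the standard gait preprocessing choice: order 4,
    4 Hz cutoff, applied forward and backward so the net phase shift
    is zero and the effective magnitude response is |H(f)|^2.
    """

    order: int = 4
    cutoff: float = 4.0
    zero_lag: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ParameterError(f"filter order must be >= 1, got {self.order}")
        if self.cutoff <= 0:
            raise ParameterError(f"cutoff must be positive, got {self.cutoff}")


@dataclass
class ImuRecording:
    """Synchronized multi-channel IMU time series.

    ``sample_rate`` is set only once the recording has been resampled to a
    uniform grid; raw app exports carry irregular timestamps.
    """

    timestamps: np.ndarray
    raw_accel_x: np.ndarray | None = None
    raw_accel_y: np.ndarray | None = None
    raw_accel_z: np.ndarray | None = None
    lin_accel_ap: np.ndarray | None = None
    lin_accel_ml: np.ndarray | None = None
    lin_accel_vert: np.ndarray | None = None
    gyro_x: np.ndarray | None = None
    gyro_y: np.ndarray | None = None
    gyro_z: np.ndarray | None = None
    tilt: np.ndarray | None = None
    obliquity: np.ndarray | None = None
    rotation: np.ndarray | None = None
    sample_rate: float | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.timestamps.size < 2:
            raise ValidationError("recording must have at least 2 samples")
        dt = np.diff(self.timestamps)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            raise ValidationError(
                "timestamps must be strictly increasing; "
                f"first violation at data row {bad[0] + 2}"
            )
        n = self.timestamps.size
        for name in CHANNEL_COLUMNS:
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.size != n:
                raise ValidationError(
                    f"channel {name!r} has {arr.size} samples, expected {n}"
                )
            setattr(self, name, arr)

    @property
    def n_frames(self) -> int:
        return int(self.timestamps.size)

    @property
    def duration(self) -> float:
        return float(self.timestamps[-1] - self.timestamps[0])

    def channels(self) -> Iterator[tuple[str, np.ndarray]]:
        """Yield (attribute name, array) for every present channel."""
        for name in CHANNEL_COLUMNS:
            arr = getattr(self, name)
            if arr is not None:
                yield name, arr

    def channel_names(self) -> list[str]:
        return [name for name, _ in self.channels()]

    def require(self, *names: str) -> None:
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise ValidationError(f"recording is missing required channels: {missing}")

    def replace(self, **updates) -> "ImuRecording":
        return dataclasses.replace(self, **updates)

    def to_frame(self) -> pd.DataFrame:
        data = {TIME_COLUMN: self.timestamps}
        for name, arr in self.channels():
            data[CHANNEL_COLUMNS[name]] = arr
        return pd.DataFrame(data)


def read_recording(path: str | Path, dialect: str = "gaitrisk-csv") -> ImuRecording:
    """Read a recording CSV.

    The only supported dialect is the package's own (fixed column names,
    UTF-8, '.' decimal).  Missing optional channels stay absent; a missing
    time column or unknown columns are format errors, non-monotone
    timestamps a validation error naming the first offending row.
    """
    if dialect != "gaitrisk-csv":
        raise FormatError(f"unknown recording dialect {dialect!r}")
    path = Path(path)
    df = pd.read_csv(path)
    if TIME_COLUMN not in df.columns:
        raise FormatError(f"{path}: missing required column {TIME_COLUMN!r}")
    known = {TIME_COLUMN, *CHANNEL_COLUMNS.values()}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise FormatError(f"{path}: unknown columns {unknown}")
    kwargs: dict[str, np.ndarray] = {}
    for name, col in CHANNEL_COLUMNS.items():
        if col in df.columns:
            kwargs[name] = df[col].to_numpy(dtype=float)
    return ImuRecording(timestamps=df[TIME_COLUMN].to_numpy(dtype=float), **kwargs)


def write_recording(rec: ImuRecording, path: str | Path) -> None:
    rec.to_frame().to_csv(Path(path), index=False, float_format="%.9f")


def resample_to_uniform(rec: ImuRecording, rate: float = 50.0) -> ImuRecording:
    """Linearly re-interpolate every channel onto a uniform grid.

    Output timestamps are ``t0 + k/rate`` for ``k = 0..K`` with the grid
    never extending past the last input sample.
    """
    if rate <= 0:
        raise ParameterError(f"sample rate must be positive, got {rate}")
    t = rec.timestamps
    # tiny tolerance so an already-uniform grid keeps its final sample
    k_max = int(np.floor((t[-1] - t[0]) * rate + 1e-9))
    new_t = t[0] + np.arange(k_max + 1) / rate
    updates: dict[str, np.ndarray | float] = {"timestamps": new_t, "sample_rate": float(rate)}
    for name, arr in rec.channels():
        updates[name] = np.interp(new_t, t, arr)
    return ImuRecording(**updates)  # type: ignore[arg-type]


def lowpass_zero_lag(
    series: np.ndarray, spec: FilterSpec, rate: float
) -> np.ndarray:
    """Apply the zero-lag Butterworth low-pass to one series.

    Forward-backward application (``filtfilt``) cancels the phase response;
    edges are handled with reflective padding of length 3*(order+1).
    """
    x = np.asarray(series, dtype=float)
    if spec.cutoff >= rate / 2:
        raise ParameterError(
            f"cutoff {spec.cutoff} Hz must be below Nyquist ({rate / 2} Hz)"
        )
    padlen = 3 * (spec.order + 1)
    if x.size <= padlen:
        raise InsufficientDataError(
            f"series of length {x.size} too short for order-{spec.order} "
            f"zero-lag filtering (needs > {padlen} samples)"
        )
    b, a = _butter_digital(spec.order, spec.cutoff, rate)
    if not spec.zero_lag:
        return sp_signal.lfilter(b, a, x)
    return sp_signal.filtfilt(b, a, x, padtype="even", padlen=padlen)


def _butter_digital(order: int, cutoff: float, rate: float) -> tuple[np.ndarray, np.ndarray]:
    """Digital Butterworth coefficients preserving the analog magnitude.

    The analog prototype is discretized by impulse invariance rather than
    the bilinear transform, so the magnitude response keeps the defining
    Butterworth form |H(f)| = (1 + (f/fc)^(2*order))^(-1/2) instead of
    warping toward Nyquist (at 50 Hz sampling the bilinear gain at 8 Hz
    would be ~40% off the Butterworth value).  Coefficients are normalized
    to exact unit DC gain.
    """
    b_a, a_a = sp_signal.butter(order, 2 * np.pi * cutoff, btype="low", analog=True)
    b, a, _ = sp_signal.cont2discrete((b_a, a_a), 1.0 / rate, method="impulse")
    b = np.atleast_1d(np.squeeze(b))
    dc = np.abs(np.sum(b) / np.sum(a))
    return b / dc, a


def filter_recording(rec: ImuRecording, spec: FilterSpec | None = None) -> ImuRecording:
    """Low-pass every movement channel of a uniformly sampled recording."""
    if rec.sample_rate is None:
        raise ValidationError("recording must be resampled to a uniform rate first")
    spec = spec or FilterSpec()
    updates = {
        name: lowpass_zero_lag(getattr(rec, name), spec, rec.sample_rate)
        for name in FILTERED_CHANNELS
        if getattr(rec, name) is not None
    }
    return rec.replace(**updates)


def preprocess(rec: ImuRecording, rate: float = 50.0, spec: FilterSpec | None = None) -> ImuRecording:
    """Resample to a uniform grid and low-pass filter (the standard pipeline)."""
    return filter_recording(resample_to_uniform(rec, rate), spec)


# ---------------------------------------------------------------------------
# events / features / report files

def write_events_csv(events, path: str | Path) -> None:
    """Write a foot-strike event list as CSV (frame, time_s, side)."""
    df = pd.DataFrame(
        {"frame": events.frames, "time_s": events.times, "side": events.sides}
    )
    df.to_csv(Path(path), index=False, float_format="%.9f")


def read_events_csv(path: str | Path):
    from .footstrike import FootStrikeEvents

    df = pd.read_csv(Path(path))
    required = {"frame", "time_s", "side"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: event CSV needs columns {sorted(required)}")
    return FootStrikeEvents(
        frames=df["frame"].to_numpy(dtype=int),
        times=df["time_s"].to_numpy(dtype=float),
        sides=[str(s) for s in df["side"]],
    )


def write_features_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(Path(path), index=False, float_format="%.9f")


def read_features_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path))


def write_report_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
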