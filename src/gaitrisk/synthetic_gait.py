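"""Synthetic 6MWT gait-signal generator with known ground truth.

Emulates a ~6-minute walk at 50 Hz along a 20 m hallway with periodic
180-degree turns, as recorded by a pelvis-worn smartphone.  Each foot
strike is a Gaussian-windowed anterior-posterior (AP) acceleration pulse
followed 40 ms later by a vertical pulse — the peak ordering a human
labeller uses — on top of a stride-frequency medio-lateral sway, step- and
stride-frequency pelvis orientation oscillations, and additive white
sensor noise.  Left/right step-time asymmetry (a hallmark of amputee
gait) is controlled by the right/left step-time ratio.

The generator returns the exact strike schedule it used, so detection,
feature extraction and classification can be scored against ground truth
without any clinical data.  Cohorts draw per-member gait parameters from
class-conditional distributions, linking slower cadence, stronger
asymmetry and noisier signals to the fall-risk label.

The waveform is deliberately minimal and analytically controllable; it is
not a biomechanically validated amputee gait model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError, ValidationError
from .footstrike import FootStrikeEvents, FrameLabels
from .signal_io import ImuRecording

GRAVITY = 9.81  # m/s^2

#: waveform shape constants (seconds / unitless)
AP_PULSE_SIGMA = 0.05
VERT_PULSE_SIGMA = 0.05
VERT_PULSE_LAG = 0.04  # vertical peak follows the AP peak by this much
TURN_AMP_SCALE = 0.5  # step pulses are damped while turning


@dataclass
class GaitSimParams:
    """Parameters of one simulated 6MWT walk."""

    duration: float = 360.0  # s
    sample_rate: float = 50.0  # Hz
    cadence: float = 100.0  # steps/min
    step_time_asymmetry: float = 1.1  # right/left step-time ratio
    ap_peak_amp: float = 1.5  # m/s^2
    vert_peak_amp: float = 1.2  # m/s^2
    ml_amp: float = 0.8  # m/s^2
    noise_sd: float = 0.15  # m/s^2
    walk_speed: float = 1.0  # m/s
    hallway_length: float = 20.0  # m
    turn_duration: float = 2.0  # s; 0 disables turns
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cadence <= 0:
            raise ParameterError("cadence must be positive")
        if self.step_time_asymmetry <= 0:
            raise ParameterError("step-time asymmetry ratio must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise SD must be non-negative")
        if self.hallway_length <= 0:
            raise ParameterError("hallway length must be positive")
        if self.duration <= 0 or self.sample_rate <= 0:
            raise ParameterError("duration and sample rate must be positive")


@dataclass
class ClassDistribution:
    """Per-class (mean, sd) of the gait parameters that differ by class."""

    cadence: tuple[float, float] = (100.0, 8.0)
    asymmetry: tuple[float, float] = (1.1, 0.05)
    noise_sd: tuple[float, float] = (0.15, 0.03)

    def __post_init__(self) -> None:
        for name in ("cadence", "asymmetry", "noise_sd"):
            _, sd = getattr(self, name)
            if sd < 0:
                raise ParameterError(f"{name} sd must be non-negative")


@dataclass
class CohortSpec:
    """Specification of a synthetic cohort with fall-risk-linked gait.

    Defaults mirror a screening cohort in which fall-risk members walk
    slower, more asymmetrically and with noisier signals than members
    without fall risk.
    """

    n_fall_risk: int = 27
    n_no_fall_risk: int = 53
    fall_risk: ClassDistribution = field(
        default_factory=lambda: ClassDistribution(
            cadence=(85.0, 8.0), asymmetry=(1.22, 0.08), noise_sd=(0.20, 0.03)
        )
    )
    no_fall_risk: ClassDistribution = field(
        default_factory=lambda: ClassDistribution(
            cadence=(105.0, 8.0), asymmetry=(1.06, 0.04), noise_sd=(0.15, 0.03)
        )
    )
    duration: float = 360.0
    sample_rate: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fall_risk < 0 or self.n_no_fall_risk < 0:
            raise ParameterError("cohort counts must be non-negative")


@dataclass
class CohortMember:
    recording: ImuRecording
    events: FootStrikeEvents
    fall_risk: int  # 1 = fall risk, 0 = no fall risk
    params: GaitSimParams


def _strike_schedule(params: GaitSimParams) -> tuple[np.ndarray, list[str]]:
    """Alternating strike times; intervals encode cadence and asymmetry.

    The interval *ending* at a right strike is the right step time
    t_R = T * 2r/(1+r) and symmetrically for the left, so the mean step
    time stays 60/cadence regardless of the asymmetry ratio r.
    """
    mean_step = 60.0 / params.cadence
    r = params.step_time_asymmetry
    t_right = mean_step * 2.0 * r / (1.0 + r)
    t_left = mean_step * 2.0 / (1.0 + r)
    times, sides = [], []
    # start on the sampling grid so equal step times stay equal after the
    # per-strike grid snap in generate_walk
    t = np.round(0.5 * mean_step * params.sample_rate) / params.sample_rate
    side = "right"
    while t < params.duration - 0.25:
        times.append(t)
        sides.append(side)
        # the upcoming interval ends at the *other* foot's strike
        t += t_left if side == "right" else t_right
        side = "left" if side == "right" else "right"
    return np.asarray(times), sides


def _turn_bouts(params: GaitSimParams) -> list[tuple[float, float]]:
    if params.turn_duration <= 0:
        return []
    lap = params.hallway_length / params.walk_speed
    bouts = []
    t = lap
    while t < params.duration:
        bouts.append((t, min(t + params.turn_duration, params.duration)))
        t += lap + params.turn_duration
    return bouts


def _in_bout(t: np.ndarray, bouts: list[tuple[float, float]]) -> np.ndarray:
    mask = np.zeros_like(t, dtype=bool)
    for a, b in bouts:
        mask |= (t >= a) & (t < b)
    return mask


def _pulse_train(
    t: np.ndarray, centers: np.ndarray, amps: np.ndarray, sigma: float
) -> np.ndarray:
    out = np.zeros_like(t)
    # each Gaussian pulse only matters within +-4 sigma of its centre
    reach = 4.0 * sigma
    for c, a in zip(centers, amps):
        lo = np.searchsorted(t, c - reach)
        hi = np.searchsorted(t, c + reach)
        out[lo:hi] += a * np.exp(-0.5 * ((t[lo:hi] - c) / sigma) ** 2)
    return out


def generate_walk(params: GaitSimParams) -> tuple[ImuRecording, FootStrikeEvents]:
    """Simulate one walk; returns the recording and its true strike events."""
    rng = np.random.default_rng(params.seed)
    fs = params.sample_rate
    n = int(round(params.duration * fs))
    t = np.arange(n) / fs

    strike_times, sides = _strike_schedule(params)
    # snap strikes to the sampling grid: ground-truth frames are then exact,
    # and a noise-free symmetric walk is exactly symmetric step to step
    strike_times = np.round(strike_times * fs) / fs
    bouts = _turn_bouts(params)
    amp_scale = np.where(_in_bout(strike_times, bouts), TURN_AMP_SCALE, 1.0)

    ap = _pulse_train(t, strike_times, params.ap_peak_amp * amp_scale, AP_PULSE_SIGMA)
    vert = _pulse_train(
        t, strike_times + VERT_PULSE_LAG, params.vert_peak_amp * amp_scale,
        VERT_PULSE_SIGMA,
    )

    stride_period = 2.0 * 60.0 / params.cadence
    first_right = strike_times[0] if sides[0] == "right" else strike_times[1]
    ml = params.ml_amp * np.cos(2 * np.pi * (t - first_right) / stride_period)

    step_freq = params.cadence / 60.0
    tilt = 2.0 * np.sin(2 * np.pi * step_freq * t)
    obliquity = 3.0 * np.sin(2 * np.pi * (t - first_right) / stride_period)

    rotation = np.zeros(n)
    gyro_z = np.zeros(n)
    for k, (a, b) in enumerate(bouts):
        direction = 1.0 if k % 2 == 0 else -1.0
        ramp = np.clip((t - a) / max(b - a, 1e-9), 0.0, 1.0)
        rotation += direction * 180.0 * ramp
        gyro_z += direction * np.deg2rad(180.0 / max(b - a, 1e-9)) * ((t >= a) & (t < b))
    rotation += 1.0 * np.sin(2 * np.pi * step_freq * t)

    gyro_x = np.deg2rad(np.gradient(tilt, t))
    gyro_y = np.deg2rad(np.gradient(obliquity, t))

    sd = params.noise_sd
    noise = lambda scale: rng.normal(0.0, sd * scale, n) if sd > 0 else 0.0
    ap = ap + noise(1.0)
    ml = ml + noise(1.0)
    vert = vert + noise(1.0)
    rec = ImuRecording(
        timestamps=t,
        raw_accel_x=ap + noise(0.3),
        raw_accel_y=ml + noise(0.3),
        raw_accel_z=vert + GRAVITY + noise(0.3),
        lin_accel_ap=ap,
        lin_accel_ml=ml,
        lin_accel_vert=vert,
        gyro_x=gyro_x + noise(0.2),
        gyro_y=gyro_y + noise(0.2),
        gyro_z=gyro_z + noise(0.2),
        tilt=tilt + noise(2.0),
        obliquity=obliquity + noise(2.0),
        rotation=rotation + noise(2.0),
        sample_rate=fs,
    )
    frames = np.round(strike_times * fs).astype(int)
    frames = np.clip(frames, 0, n - 1)
    events = FootStrikeEvents(frames=frames, times=rec.timestamps[frames], sides=sides)
    return rec, events


def generate_cohort(spec: CohortSpec) -> list[CohortMember]:
    """Simulate a labelled cohort with class-conditional gait parameters."""
    members: list[CohortMember] = []
    seeds = np.random.SeedSequence(spec.seed).spawn(
        spec.n_fall_risk + spec.n_no_fall_risk
    )
    plan = [(1, spec.fall_risk)] * spec.n_fall_risk + [
        (0, spec.no_fall_risk)
    ] * spec.n_no_fall_risk
    for child, (label, dist) in zip(seeds, plan):
        rng = np.random.default_rng(child)
        params = GaitSimParams(
            duration=spec.duration,
            sample_rate=spec.sample_rate,
            cadence=float(np.clip(rng.normal(*dist.cadence), 40.0, 160.0)),
            step_time_asymmetry=float(np.clip(rng.normal(*dist.asymmetry), 1.0, 2.0)),
            noise_sd=float(max(rng.normal(*dist.noise_sd), 0.0)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        rec, events = generate_walk(params)
        members.append(CohortMember(rec, events, label, params))
    return members


def degrade_labels(
    truth: FrameLabels,
    drop_rate: float,
    duplicate_rate: float,
    jitter_frames: int = 0,
    seed: int = 0,
) -> FrameLabels:
    """Corrupt clean per-frame strike labels to stress post-processing.

    Each true strike is independently dropped with ``drop_rate``; retained
    strikes are jittered uniformly within ``±jitter_frames``; with
    ``duplicate_rate`` an extra positive label is appended at the adjacent
    frame, emulating the consecutive-prediction errors a per-frame
    classifier makes.
    """
    for name, r in (("drop_rate", drop_rate), ("duplicate_rate", duplicate_rate)):
        if not 0.0 <= r <= 1.0:
            raise ParameterError(f"{name} must be in [0, 1], got {r}")
    if jitter_frames < 0:
        raise ParameterError("jitter_frames must be non-negative")
    rng = np.random.default_rng(seed)
    n = len(truth)
    strikes = truth.strike_frames
    keep = strikes[rng.random(strikes.size) >= drop_rate]
    if jitter_frames > 0 and keep.size:
        keep = keep + rng.integers(-jitter_frames, jitter_frames + 1, keep.size)
    labels = np.zeros(n, dtype=np.int8)
    keep = np.clip(keep, 0, n - 1)
    labels[keep] = 1
    dup = keep[rng.random(keep.size) < duplicate_rate]
    labels[np.clip(dup + 1, 0, n - 1)] = 1
    return FrameLabels(labels)
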