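"""IMU-based gait event detection and spatiotemporal features.

The processing chain for an ankle-worn IMU is:

1. zero-phase Butterworth band-pass (0.3–5 Hz) of the mediolateral
   (Z-axis) gyroscope, which carries sagittal-plane shank rotation;
2. gait events per cycle — mid-swing as the prominent positive angular
   velocity peak, toe-off / heel strike as the flanking negative valleys;
3. heading angle θ from the attitude quaternion (yaw about vertical),
   used to project the horizontal accelerometer channels onto the
   direction of travel, a(t) = ay(t)·sin θ + az(t)·cos θ;
4. step length as the double time-integral of forward acceleration over
   each heel-strike→heel-strike interval, with a zero-velocity update at
   each step start and per-step linear velocity-drift removal;
5. cadence f = 60·N/t (steps/min) and speed v = x/t.

Pure accelerometer double integration diverges under sensor bias; the
zero-velocity reset plus linear drift removal is the minimal standard
correction and bounds per-step error instead of letting it accumulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy import integrate, signal

from .series import ImuRecord, SignalError, UniformSeries

#: Default band retaining walking-cycle frequency content, Hz.
GAIT_BAND = (0.3, 5.0)

#: Peak prominence as a fraction of the 95th percentile of |filtered gyro|.
PEAK_PROMINENCE_FRACTION = 0.30

#: Minimum separation between mid-swing peaks, seconds (caps detectable
#: cadence at 150 steps/min, the normal-walking range).
MIN_PEAK_SEPARATION = 0.4


class NoGaitDetectedError(SignalError):
    """No gait cycles found above the prominence threshold."""


@dataclass
class ImuGaitEvents:
    """Per-cycle gait event sample indices.

    Each cycle satisfies ``toe_off < mid_swing < heel_strike``; cycles are
    time-ordered and non-overlapping.
    """

    toe_off: np.ndarray
    mid_swing: np.ndarray
    heel_strike: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.toe_off = np.asarray(self.toe_off, dtype=int)
        self.mid_swing = np.asarray(self.mid_swing, dtype=int)
        self.heel_strike = np.asarray(self.heel_strike, dtype=int)
        n = len(self.mid_swing)
        if not (len(self.toe_off) == n == len(self.heel_strike)):
            raise SignalError("event arrays must have equal length")
        if n and not (
            np.all(self.toe_off < self.mid_swing)
            and np.all(self.mid_swing < self.heel_strike)
        ):
            raise SignalError("event ordering toe_off < mid_swing < heel_strike violated")
        if n > 1 and not np.all(self.heel_strike[:-1] <= self.toe_off[1:]):
            raise SignalError("gait cycles overlap or are out of order")

    @property
    def n_cycles(self) -> int:
        return len(self.mid_swing)


@dataclass
class SpatiotemporalFeatures:
    """Headline spatiotemporal gait features.

    ``step_length_m`` is the mean per-step forward displacement,
    ``cadence_spm`` steps per minute, ``speed_mps`` mean walking speed,
    ``step_count`` complete detected cycles, ``duration_s`` the analysed
    time span.
    """

    step_length_m: float
    cadence_spm: float
    speed_mps: float
    step_count: int
    duration_s: float
    per_step_length_m: np.ndarray = field(default_factory=lambda: np.array([]))

    def as_dict(self) -> dict:
        return {
            "step_length_m": self.step_length_m,
            "cadence_spm": self.cadence_spm,
            "speed_mps": self.speed_mps,
            "step_count": self.step_count,
            "duration_s": self.duration_s,
        }


def bandpass_gait(series: UniformSeries, low: float = GAIT_BAND[0],
                  high: float = GAIT_BAND[1]) -> UniformSeries:
    """Zero-phase 4th-order Butterworth band-pass of a gait signal.

    Suppresses zero drift (below ``low``) and high-frequency noise (above
    ``high``) while preserving walking-cycle content.  Output length
    equals input length; applied forward-backward so event timing is not
    lagged.
    """
    if series.fs <= 2.0 * high:
        raise SignalError(
            f"fs={series.fs} Hz too low for a {high} Hz band edge (need fs > {2*high})"
        )
    sos = signal.butter(4, [low, high], btype="bandpass", fs=series.fs, output="sos")
    y = signal.sosfiltfilt(sos, series.values)
    return UniformSeries(y, series.fs, series.t0)


def detect_imu_events(imu: ImuRecord) -> ImuGaitEvents:
    """Detect toe-off, mid-swing and heel-strike from the Z gyroscope.

    Mid-swing peaks are the prominent positive maxima of the band-passed
    mediolateral angular velocity; toe-off and heel strike are the nearest
    negative minima before and after each peak.  Only complete cycles
    (both flanking valleys present and negative) are returned.
    """
    if imu.duration < 2.0:
        raise SignalError("need at least 2 s of IMU data")
    g = bandpass_gait(imu.gyro_series(2)).values
    scale = float(np.percentile(np.abs(g), 95))
    if scale <= 0:
        raise NoGaitDetectedError("flat gyroscope signal")
    prominence = PEAK_PROMINENCE_FRACTION * scale
    distance = max(int(round(MIN_PEAK_SEPARATION * imu.fs)), 1)
    # height is required alongside prominence: a small noise bump sitting
    # between two deep valleys has large prominence but is not a mid-swing
    peaks, _ = signal.find_peaks(
        g, prominence=prominence, height=prominence, distance=distance
    )
    if len(peaks) == 0:
        raise NoGaitDetectedError("no mid-swing peaks above prominence threshold")

    # Valleys are not distance-constrained: toe-off and heel-strike minima
    # sit less than half a step period apart within one swing.
    valleys, _ = signal.find_peaks(
        -g, prominence=0.25 * prominence, height=0.25 * prominence
    )

    toe_off, mid_swing, heel_strike = [], [], []
    for p in peaks:
        before = valleys[valleys < p]
        after = valleys[valleys > p]
        if len(before) == 0 or len(after) == 0:
            continue  # incomplete cycle at a record edge
        toe_off.append(before[-1])
        mid_swing.append(p)
        heel_strike.append(after[0])
    if not mid_swing:
        raise NoGaitDetectedError("no complete gait cycles found")
    return ImuGaitEvents(
        np.array(toe_off), np.array(mid_swing), np.array(heel_strike), imu.fs
    )


def yaw_from_quaternion(q: np.ndarray) -> np.ndarray:
    """Heading angle θ (yaw about the vertical) from unit quaternions.

    ``q`` is scalar-first ``(q0, q1, q2, q3)``, a single quaternion or an
    (n, 4) array.  θ = atan2(2(q1·q2 + q0·q3), q0² + q1² − q2² − q3²),
    in (−π, π].
    """
    q = np.asarray(q, dtype=float)
    single = q.ndim == 1
    q = np.atleast_2d(q)
    if q.shape[1] != 4:
        raise SignalError("quaternions must have 4 components")
    norm = np.linalg.norm(q, axis=1)
    if np.any(norm < 1e-12):
        raise SignalError("zero quaternion has no orientation")
    q = q / norm[:, None]
    q0, q1, q2, q3 = q.T
    theta = np.arctan2(2.0 * (q1 * q2 + q0 * q3), q0**2 + q1**2 - q2**2 - q3**2)
    return float(theta[0]) if single else theta


def forward_acceleration(ay: np.ndarray, az: np.ndarray, theta) -> np.ndarray:
    """Project horizontal acceleration onto the travel direction.

    a(t) = ay(t)·sin θ(t) + az(t)·cos θ(t), applied samplewise; ``theta``
    may be scalar or per-sample.
    """
    ay = np.asarray(ay, dtype=float)
    az = np.asarray(az, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if ay.shape != az.shape:
        raise SignalError("ay and az must have equal length")
    if theta.ndim and theta.shape != ay.shape:
        raise SignalError("per-sample theta must match the channel length")
    return ay * np.sin(theta) + az * np.cos(theta)


def step_length(a: UniformSeries, events: ImuGaitEvents) -> Tuple[np.ndarray, float]:
    """Per-step forward displacement by double integration.

    For each heel-strike→heel-strike interval the forward acceleration is
    integrated to velocity (cumulative trapezoid, zero-velocity update at
    the step start), a linear velocity ramp is removed so the end-of-step
    velocity deviation (integration drift) is zeroed, and the detrended
    velocity is integrated to displacement.  Returns the per-step
    ``|displacement|`` and its mean.
    """
    hs = events.heel_strike
    if len(hs) < 2:
        raise SignalError("need at least 2 heel strikes for one complete step")
    if hs[0] < 0 or hs[-1] >= len(a.values):
        raise SignalError("events fall outside the series")
    dt = a.dt
    lengths = []
    for i, j in zip(hs[:-1], hs[1:]):
        seg = a.values[i : j + 1]
        v = integrate.cumulative_trapezoid(seg, dx=dt, initial=0.0)  # ZUPT: v[0] = 0
        ramp = np.linspace(0.0, v[-1], len(v))  # assume v = 0 at both heel strikes
        x = float(np.trapezoid(v - ramp, dx=dt))
        lengths.append(abs(x))
    lengths = np.asarray(lengths)
    return lengths, float(lengths.mean())


def cadence(n_steps: int, duration_s: float) -> float:
    """Cadence in steps per minute: f = 60·N/t."""
    if duration_s <= 0:
        raise SignalError("duration must be positive")
    return 60.0 * n_steps / duration_s


def speed(distance_m: float, duration_s: float) -> float:
    """Mean walking speed v = x/t in m/s."""
    if duration_s <= 0:
        raise SignalError("duration must be positive")
    return distance_m / duration_s


def extract_spatiotemporal(imu: ImuRecord) -> SpatiotemporalFeatures:
    """Full IMU pipeline: events → forward acceleration → features.

    Cadence and speed are evaluated over the span between the first and
    last detected heel strikes, i.e. over the N − 1 complete steps whose
    displacements are measured.
    """
    events = detect_imu_events(imu)
    theta = yaw_from_quaternion(imu.quat)
    a_fwd = forward_acceleration(imu.accel[:, 1], imu.accel[:, 2], theta)
    a = UniformSeries(a_fwd, imu.fs, imu.t0)
    per_step, mean_len = step_length(a, events)
    span = (events.heel_strike[-1] - events.heel_strike[0]) / imu.fs
    n_steps = len(per_step)
    f = cadence(n_steps, span)
    v = speed(float(per_step.sum()), span)
    return SpatiotemporalFeatures(
        step_length_m=mean_len,
        cadence_spm=f,
        speed_mps=v,
        step_count=events.n_cycles,
        duration_s=span,
        per_step_length_m=per_step,
    )
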