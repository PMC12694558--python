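"""Ground-truth signal generators for all three sensing modalities.

The waveform families are chosen for analytic ground truth, not
biomechanical realism:

* IMU — the mediolateral gyro is a train of Gaussian bumps (a positive
  mid-swing peak flanked by negative toe-off / heel-strike valleys) and
  the forward acceleration is one sine period per step, so the double
  time-integral over each heel-strike→heel-strike interval equals the
  requested step length exactly before noise.
* pressure — trapezoidal loading per channel with a heel-first,
  forefoot-later onset ordering, so all five stance events and every
  channel's impulse are known in closed form.
* sEMG — low-pass Gaussian noise heterodyned onto a drifting carrier:
  the power spectrum is symmetric about the instantaneous carrier
  frequency, so the spectral centroid (MPF) trajectory is known.

Every generator is deterministic under a fixed seed.  The default
:class:`WalkSpec` mirrors a straight-walkway validation walk: 16 steps
of 1.13 m at 100 steps/min (an ~18 m path).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Tuple

import numpy as np
from scipy import signal

from .imu import ImuGaitEvents
from .pressure import StanceEvents
from .series import (
    EMG_MUSCLES,
    PRESSURE_SITES,
    EmgRecord,
    ImuRecord,
    PressureRecord,
    SignalError,
)

#: Cycle-relative timing of the stance events generated for each channel
#: group (fractions of the gait-cycle duration).
STANCE_FRACTIONS = {"ifc": 0.0, "imc": 0.10, "iffc": 0.20, "ho": 0.42, "lfc": 0.60}

#: Per-site loading amplitude ratios (sensor units, before scaling) and
#: on/off times as fractions of the cycle.
_CHANNEL_PLAN = {
    # site: (amplitude ratio, on fraction, off fraction)
    "toe1": (0.60, 0.30, 0.60),
    "met1": (0.80, 0.10, 0.55),
    "met23": (1.00, 0.10, 0.55),
    "met45": (0.70, 0.12, 0.55),
    "midfoot_med": (0.45, 0.20, 0.50),
    "midfoot_lat": (0.50, 0.20, 0.50),
    "heel_med": (1.00, 0.0, 0.42),
    "heel_lat": (0.90, 0.0, 0.42),
}


@dataclass
class WalkSpec:
    """Parameters of one synthetic straight-line walk."""

    n_steps: int = 16
    step_length: float = 1.13  # m
    cadence: float = 100.0  # steps/min
    fs_imu: float = 100.0  # Hz
    fs_pressure: float = 50.0  # Hz
    fs_emg: float = 2000.0  # Hz
    heading: float = 0.3  # rad, fixed yaw of the travel direction
    accel_noise_sd: float = 0.1  # m/s²
    gyro_noise_sd: float = 5.0  # °/s
    pressure_noise_sd: float = 0.5  # sensor units (amplitude scale 100)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise SignalError("n_steps must be >= 1")
        for name in ("cadence", "fs_imu", "fs_pressure", "fs_emg"):
            if getattr(self, name) <= 0:
                raise SignalError(f"{name} must be positive")

    @property
    def step_period(self) -> float:
        """Step duration 60/cadence, seconds."""
        return 60.0 / self.cadence

    @property
    def cycle_period(self) -> float:
        """Gait-cycle (two-step) duration, seconds."""
        return 120.0 / self.cadence


@dataclass
class ImuWalkTruth:
    """Ground truth accompanying a synthetic IMU walk."""

    events: ImuGaitEvents
    step_length: float
    cadence: float
    heading: float


@dataclass
class PressureWalkTruth:
    """Ground truth accompanying a synthetic pressure walk."""

    events: StanceEvents
    cycle_impulse: dict  # per-site analytic trapezoid area, units·s
    amplitudes: dict  # per-site plateau amplitude, sensor units


@dataclass
class EmgTruth:
    """Ground-truth spectral centroid trajectory of a synthetic record."""

    times: np.ndarray
    centroid_hz: np.ndarray


def _gaussian_train(t: np.ndarray, centers: np.ndarray, sigma: float) -> np.ndarray:
    out = np.zeros_like(t)
    for c in centers:
        out += np.exp(-0.5 * ((t - c) / sigma) ** 2)
    return out


def generate_imu_walk(spec: WalkSpec) -> Tuple[ImuRecord, ImuWalkTruth]:
    """Synthesize an ankle IMU record for a straight walk.

    Heel strikes fall at exact multiples of the step period; each
    heel-strike→heel-strike interval carries one full sine period of
    forward acceleration with amplitude 2π·step_length/T², whose double
    integral is exactly ``spec.step_length``.  The fixed heading is
    encoded in the attitude quaternion and the forward acceleration is
    split onto the horizontal accelerometer axes accordingly.
    """
    rng = np.random.default_rng(spec.seed)
    fs, T, n = spec.fs_imu, spec.step_period, spec.n_steps
    lead = tail = 1.0
    n_samp = int(round((lead + n * T + tail) * fs))
    t = np.arange(n_samp) / fs

    to_times = lead + (np.arange(n) + 0.60) * T
    ms_times = lead + (np.arange(n) + 0.80) * T
    hs_times = lead + (np.arange(n) + 1.00) * T
    gyro_z = (
        300.0 * _gaussian_train(t, ms_times, 0.09 * T)
        - 120.0 * _gaussian_train(t, to_times, 0.05 * T)
        - 120.0 * _gaussian_train(t, hs_times, 0.05 * T)
    )

    amp = 2.0 * np.pi * spec.step_length / T**2
    phase = (t - lead) / T
    a_fwd = np.where((phase >= 0) & (phase < n), amp * np.sin(2 * np.pi * phase), 0.0)

    ay = a_fwd * np.sin(spec.heading)
    az = a_fwd * np.cos(spec.heading)
    ax = np.zeros_like(t)
    accel = np.column_stack([ax, ay, az])
    accel += rng.normal(0.0, spec.accel_noise_sd, accel.shape)
    gyro = np.column_stack([np.zeros_like(t), np.zeros_like(t), gyro_z])
    gyro += rng.normal(0.0, spec.gyro_noise_sd, gyro.shape)

    half = spec.heading / 2.0
    quat = np.tile([np.cos(half), 0.0, 0.0, np.sin(half)], (n_samp, 1))

    events = ImuGaitEvents(
        toe_off=np.round(to_times * fs).astype(int),
        mid_swing=np.round(ms_times * fs).astype(int),
        heel_strike=np.round(hs_times * fs).astype(int),
        fs=fs,
    )
    record = ImuRecord(fs=fs, accel=accel, gyro=gyro, quat=quat)
    truth = ImuWalkTruth(
        events=events,
        step_length=spec.step_length,
        cadence=spec.cadence,
        heading=spec.heading,
    )
    return record, truth


def _trapezoid(t: np.ndarray, t_on: float, t_off: float, rise: float, amp: float) -> np.ndarray:
    """Trapezoidal pulse: 0 before ``t_on``, linear rise over ``rise``,
    plateau at ``amp``, linear fall ending exactly at ``t_off``."""
    up = np.clip((t - t_on) / rise, 0.0, 1.0)
    down = np.clip((t_off - t) / rise, 0.0, 1.0)
    return amp * np.minimum(up, down)


def generate_pressure_walk(
    spec: WalkSpec, amplitude_scale: float = 100.0
) -> Tuple[PressureRecord, PressureWalkTruth]:
    """Synthesize an 8-channel plantar-pressure record.

    Each gait cycle loads the channels as trapezoids whose on/off times
    follow the heel-first, forefoot-later ordering IFC < IMC < IFFC <
    HO < LFC; all on/off times sit on the sample grid so detected events
    land within one sample of the returned ground truth.
    """
    rng = np.random.default_rng(spec.seed + 1)
    fs, Tc, n = spec.fs_pressure, spec.cycle_period, spec.n_steps
    lead = tail = 0.5
    rise = 2.0 / fs  # two-sample ramps: threshold crossings hug the corners
    n_samp = int(round((lead + n * Tc + tail) * fs))
    t = np.arange(n_samp) / fs

    def grid(x: float) -> float:
        return np.round(x * fs) / fs

    data = np.zeros((n_samp, len(PRESSURE_SITES)))
    truth_events = {k: [] for k in STANCE_FRACTIONS}
    areas = {site: 0.0 for site in PRESSURE_SITES}
    amps = {}
    for c, site in enumerate(PRESSURE_SITES):
        ratio, f_on, f_off = _CHANNEL_PLAN[site]
        amps[site] = ratio * amplitude_scale
    for k in range(n):
        start = lead + k * Tc
        for key, frac in STANCE_FRACTIONS.items():
            truth_events[key].append(grid(start + frac * Tc))
        for c, site in enumerate(PRESSURE_SITES):
            ratio, f_on, f_off = _CHANNEL_PLAN[site]
            t_on = grid(start + f_on * Tc)
            t_off = grid(start + f_off * Tc)
            data[:, c] += _trapezoid(t, t_on, t_off, rise, amps[site])
    for site in PRESSURE_SITES:
        ratio, f_on, f_off = _CHANNEL_PLAN[site]
        # analytic per-cycle trapezoid area: amp * (duration - rise)
        areas[site] = amps[site] * (grid(lead + f_off * Tc) - grid(lead + f_on * Tc) - rise)

    data += rng.normal(0.0, spec.pressure_noise_sd, data.shape)
    data = np.clip(data, 0.0, None)

    events = StanceEvents(
        t_ifc=np.array(truth_events["ifc"]),
        t_imc=np.array(truth_events["imc"]),
        t_iffc=np.array(truth_events["iffc"]),
        t_ho=np.array(truth_events["ho"]),
        t_lfc=np.array(truth_events["lfc"]),
    )
    record = PressureRecord(fs=fs, data=data)
    return record, PressureWalkTruth(events=events, cycle_impulse=areas, amplitudes=amps)


def generate_emg(
    duration: float,
    centroid_start: float,
    centroid_end: float,
    fs: float = 2000.0,
    seed: int = 0,
    cadence: float = 100.0,
    amplitude_mv: float = 1.0,
) -> Tuple[EmgRecord, EmgTruth]:
    """Synthesize a 3-muscle sEMG record with a known centroid trajectory.

    Each channel is band-limited Gaussian noise (two-sided bandwidth
    ~30 Hz) heterodyned onto a carrier whose frequency drifts linearly
    from ``centroid_start`` to ``centroid_end`` Hz — the instantaneous
    spectral centroid equals the carrier frequency.  Burst amplitude
    modulation at the step rate emulates gait-locked activation.
    """
    for c in (centroid_start, centroid_end):
        if not 20.0 <= c <= 450.0:
            raise SignalError("centroid must lie in the 20-450 Hz sEMG band")
    rng = np.random.default_rng(seed + 2)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    centroid = centroid_start + (centroid_end - centroid_start) * t / duration
    phase = 2.0 * np.pi * np.cumsum(centroid) / fs
    sos = signal.butter(4, 15.0, btype="lowpass", fs=fs, output="sos")
    burst = 0.35 + 0.65 * 0.5 * (1.0 - np.cos(2.0 * np.pi * t * cadence / 60.0))
    data = np.empty((n, len(EMG_MUSCLES)))
    for c in range(len(EMG_MUSCLES)):
        base = signal.sosfilt(sos, rng.standard_normal(n))
        base /= max(base.std(), 1e-12)
        data[:, c] = amplitude_mv * base * np.cos(phase) * burst
    record = EmgRecord(fs=fs, data=data)
    return record, EmgTruth(times=t, centroid_hz=centroid)
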