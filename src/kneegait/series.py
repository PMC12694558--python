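"""Shared in-memory containers for the three sensing modalities.

All signals are regularly sampled.  A :class:`UniformSeries` carries one
scalar channel together with its start time ``t0`` (seconds) and sampling
rate ``fs`` (Hz); multi-channel records (:class:`ImuRecord`,
:class:`PressureRecord`, :class:`EmgRecord`) share a single clock across
channels.  Indices are 0-based and intervals half-open ``[start, stop)``.

Axis convention for the ankle-worn IMU: X is the sagittal (travel)
direction, Y vertical, Z the coronal (mediolateral) axis; sagittal-plane
shank rotation therefore appears on the Z gyroscope channel.  Quaternions
are stored scalar-first ``(q0, q1, q2, q3)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Standard gravity used to convert accelerometer logs recorded in g to SI.
STANDARD_GRAVITY = 9.80665

#: Anatomical sites of the 8 insole pressure channels, in storage order:
#: first-toe distal phalanx, 1st metatarsal head, 2nd-3rd metatarsal heads,
#: 4th-5th metatarsal heads, medial/lateral midfoot, medial/lateral heel.
PRESSURE_SITES = (
    "toe1",
    "met1",
    "met23",
    "met45",
    "midfoot_med",
    "midfoot_lat",
    "heel_med",
    "heel_lat",
)

#: Quadriceps muscles recorded by the 3-channel sEMG montage.
EMG_MUSCLES = ("VM", "RF", "VL")


class SignalError(ValueError):
    """Raised when a signal container invariant is violated."""


@dataclass
class UniformSeries:
    """A regularly sampled scalar channel.

    Parameters
    ----------
    values : array-like
        Ordered real samples; must be finite and non-empty.
    fs : float
        Sampling rate in Hz; must be positive.
    t0 : float, optional
        Time of the first sample in seconds (default 0).
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise SignalError("series must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise SignalError("series contains non-finite samples")
        if not self.fs > 0:
            raise SignalError(f"fs must be positive, got {self.fs}")

    def __len__(self) -> int:
        return len(self.values)

    @property
    def dt(self) -> float:
        """Sample spacing 1/fs in seconds."""
        return 1.0 / self.fs

    @property
    def duration(self) -> float:
        """Span from the first to one past the last sample, in seconds."""
        return len(self.values) / self.fs

    def times(self) -> np.ndarray:
        """Per-sample timestamps in seconds."""
        return self.t0 + np.arange(len(self.values)) / self.fs

    def index_at(self, t: float) -> int:
        """Index of the first sample at or after time ``t``."""
        return int(np.ceil((t - self.t0) * self.fs - 1e-9))

    def slice_time(self, start: float, stop: float) -> "UniformSeries":
        """Samples with timestamps in the half-open interval [start, stop)."""
        i = max(self.index_at(start), 0)
        j = min(self.index_at(stop), len(self.values))
        if j <= i:
            raise SignalError(f"empty time slice [{start}, {stop})")
        return UniformSeries(self.values[i:j], self.fs, self.t0 + i / self.fs)


def _as_channel_matrix(x, n_channels: int, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 2 or a.shape[1] != n_channels:
        raise SignalError(f"{name} must have shape (n, {n_channels})")
    if not np.all(np.isfinite(a)):
        raise SignalError(f"{name} contains non-finite samples")
    return a


@dataclass
class ImuRecord:
    """Synchronized accelerometer/gyroscope/attitude streams.

    ``accel`` is (n, 3) in m/s² ordered (ax, ay, az); ``gyro`` is (n, 3) in
    °/s ordered (gx, gy, gz); ``quat`` is (n, 4) scalar-first unit
    quaternions, renormalized on construction.
    """

    fs: float
    accel: np.ndarray
    gyro: np.ndarray
    quat: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.accel = _as_channel_matrix(self.accel, 3, "accel")
        self.gyro = _as_channel_matrix(self.gyro, 3, "gyro")
        self.quat = _as_channel_matrix(self.quat, 4, "quat")
        if not (len(self.accel) == len(self.gyro) == len(self.quat)):
            raise SignalError("IMU channel lengths differ")
        if not self.fs > 0:
            raise SignalError(f"fs must be positive, got {self.fs}")
        norms = np.linalg.norm(self.quat, axis=1)
        if np.any(norms < 1e-12):
            raise SignalError("zero quaternion in attitude stream")
        self.quat = self.quat / norms[:, None]

    def __len__(self) -> int:
        return len(self.accel)

    @property
    def duration(self) -> float:
        return len(self) / self.fs

    def gyro_series(self, axis: int) -> UniformSeries:
        """One gyroscope axis as a :class:`UniformSeries` (0=x, 1=y, 2=z)."""
        return UniformSeries(self.gyro[:, axis], self.fs, self.t0)


@dataclass
class PressureRecord:
    """8-channel plantar-pressure record keyed by anatomical site.

    ``data`` is (n, 8) in sensor units, columns ordered as
    :data:`PRESSURE_SITES`.  Samples must be non-negative (baseline
    already subtracted).
    """

    fs: float
    data: np.ndarray
    t0: float = 0.0
    sites: tuple = field(default=PRESSURE_SITES)

    def __post_init__(self) -> None:
        self.data = _as_channel_matrix(self.data, len(PRESSURE_SITES), "pressure data")
        if not self.fs > 0:
            raise SignalError(f"fs must be positive, got {self.fs}")
        if np.any(self.data < 0):
            raise SignalError("pressure samples must be non-negative")
        if tuple(self.sites) != PRESSURE_SITES:
            raise SignalError("pressure channels must follow the standard site order")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def duration(self) -> float:
        return len(self) / self.fs

    def channel(self, site: str) -> UniformSeries:
        return UniformSeries(self.data[:, PRESSURE_SITES.index(site)], self.fs, self.t0)

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.fs


@dataclass
class EmgRecord:
    """3-channel quadriceps sEMG record (columns VM, RF, VL, in mV)."""

    fs: float
    data: np.ndarray
    t0: float = 0.0
    muscles: tuple = field(default=EMG_MUSCLES)

    def __post_init__(self) -> None:
        self.data = _as_channel_matrix(self.data, len(EMG_MUSCLES), "EMG data")
        if not self.fs > 0:
            raise SignalError(f"fs must be positive, got {self.fs}")
        if tuple(self.muscles) != EMG_MUSCLES:
            raise SignalError("EMG channels must be ordered (VM, RF, VL)")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def duration(self) -> float:
        return len(self) / self.fs

    def channel(self, muscle: str) -> UniformSeries:
        return UniformSeries(self.data[:, EMG_MUSCLES.index(muscle)], self.fs, self.t0)
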