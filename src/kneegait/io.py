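"""CSV log readers/writers for the three sensor dialects.

Each dialect is a plain CSV with a ``time`` column of float seconds first,
then the channel columns in fixed order:

``imu``
    ``time, ax, ay, az, gx, gy, gz, q0, q1, q2, q3`` — acceleration in
    m/s² (or g with ``accel_unit="g"``), angular velocity in °/s,
    scalar-first unit quaternion.
``pressure``
    ``time`` + the 8 anatomical site columns of
    :data:`kneegait.series.PRESSURE_SITES`.
``emg``
    ``time, VM, RF, VL`` in mV.

The sampling rate is inferred from the timestamps (median spacing) and the
log is rejected if any spacing deviates from the median by more than 10%.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Union

import numpy as np
import pandas as pd

from .series import (
    EMG_MUSCLES,
    PRESSURE_SITES,
    STANDARD_GRAVITY,
    EmgRecord,
    ImuRecord,
    PressureRecord,
    SignalError,
)

IMU_COLUMNS = ("time", "ax", "ay", "az", "gx", "gy", "gz", "q0", "q1", "q2", "q3")
PRESSURE_COLUMNS = ("time",) + PRESSURE_SITES
EMG_COLUMNS = ("time",) + EMG_MUSCLES

#: Maximum tolerated timestamp jitter, as a fraction of the median spacing.
JITTER_TOLERANCE = 0.10


class SchemaError(SignalError):
    """CSV header does not match the requested dialect."""


class NonUniformSamplingError(SignalError):
    """Timestamp spacing deviates from the median by more than 10%."""


def infer_rate(t: np.ndarray) -> float:
    """Sampling rate from a timestamp vector via the median spacing.

    Raises :class:`NonUniformSamplingError` if any spacing deviates from
    the median by more than :data:`JITTER_TOLERANCE`.
    """
    t = np.asarray(t, dtype=float)
    if len(t) < 2:
        raise SignalError("need at least 2 timestamps to infer a rate")
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0:
        raise NonUniformSamplingError("timestamps not strictly increasing")
    worst = int(np.argmax(np.abs(dt - med)))
    if abs(dt[worst] - med) > JITTER_TOLERANCE * med:
        raise NonUniformSamplingError(
            f"timestamp gap {dt[worst]:.6g} s at row {worst} deviates more than "
            f"{JITTER_TOLERANCE:.0%} from the median spacing {med:.6g} s"
        )
    return 1.0 / med


def _load_frame(path, columns) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")
    df = df[list(columns)]
    bad = df.index[df.isna().any(axis=1)]
    if len(bad):
        raise SignalError(f"{path.name}: NaN values at row(s) {list(bad[:5])}")
    return df


def read_series_csv(
    path,
    dialect: str,
    accel_unit: str = "m/s2",
) -> Union[ImuRecord, PressureRecord, EmgRecord]:
    """Read a sensor log CSV and return the matching record type.

    Parameters
    ----------
    path : path-like
        CSV file with the dialect's documented header.
    dialect : {"imu", "pressure", "emg"}
        Which log layout to expect.
    accel_unit : {"m/s2", "g"}
        Unit of the accelerometer columns in an IMU log; values recorded
        in g are converted with g = 9.80665 m/s².
    """
    if dialect == "imu":
        df = _load_frame(path, IMU_COLUMNS)
        fs = infer_rate(df["time"].to_numpy())
        accel = df[["ax", "ay", "az"]].to_numpy()
        if accel_unit == "g":
            accel = accel * STANDARD_GRAVITY
        elif accel_unit != "m/s2":
            raise ValueError(f"unknown accel_unit {accel_unit!r}")
        return ImuRecord(
            fs=fs,
            accel=accel,
            gyro=df[["gx", "gy", "gz"]].to_numpy(),
            quat=df[["q0", "q1", "q2", "q3"]].to_numpy(),
            t0=float(df["time"].iloc[0]),
        )
    if dialect == "pressure":
        df = _load_frame(path, PRESSURE_COLUMNS)
        fs = infer_rate(df["time"].to_numpy())
        return PressureRecord(
            fs=fs,
            data=df[list(PRESSURE_SITES)].to_numpy(),
            t0=float(df["time"].iloc[0]),
        )
    if dialect == "emg":
        df = _load_frame(path, EMG_COLUMNS)
        fs = infer_rate(df["time"].to_numpy())
        return EmgRecord(
            fs=fs,
            data=df[list(EMG_MUSCLES)].to_numpy(),
            t0=float(df["time"].iloc[0]),
        )
    raise ValueError(f"unknown dialect {dialect!r}; expected imu|pressure|emg")


def write_record_csv(record, path) -> None:
    """Write a record back out in its dialect's CSV layout."""
    t = record.t0 + np.arange(len(record)) / record.fs
    if isinstance(record, ImuRecord):
        data = np.column_stack([t, record.accel, record.gyro, record.quat])
        cols = IMU_COLUMNS
    elif isinstance(record, PressureRecord):
        data = np.column_stack([t, record.data])
        cols = PRESSURE_COLUMNS
    elif isinstance(record, EmgRecord):
        data = np.column_stack([t, record.data])
        cols = EMG_COLUMNS
    else:
        raise TypeError(f"cannot serialize {type(record).__name__}")
    pd.DataFrame(data, columns=list(cols)).to_csv(
        path, index=False, float_format="%.9g"
    )


def write_features_csv(features: Mapping[str, float], path) -> None:
    """Write a scalar-feature mapping as a one-row CSV (6 significant digits).

    Column order follows the mapping's insertion order; an empty mapping
    yields a header-only file.
    """
    names = list(features.keys())
    with open(path, "w") as fh:
        fh.write(",".join(names) + "\n")
        if names:
            fh.write(",".join(f"{float(features[k]):.6g}" for k in names) + "\n")


def read_features_csv(path) -> dict:
    """Inverse of :func:`write_features_csv`."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return {}
    if len(df) == 0:
        return {}
    return {k: float(df[k].iloc[0]) for k in df.columns}
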