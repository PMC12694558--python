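"""Bundled validation tables.

Three small measurement tables ship with the package so the validation
statistics can be recomputed without hardware:

* ``imu_validation`` — five subjects walking a straight ~18 m path with
  an ankle IMU; video-derived step count, stride length and cadence
  alongside the device-computed values.
* ``surface_calibration`` — a thin-film force sensor loaded 0–100 N in
  10 N increments, three repetitions per load, on a rigid bench and on
  a compliant insole surface; output voltages in mV.  The ``average_mV``
  column is the per-load average as recorded in the source log.
* ``positioning_errors`` — massage-head positioning error (mm) over
  five rounds of three consecutive sit-to-stand transitions.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.files("kneegait.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_imu_validation() -> pd.DataFrame:
    """Five-subject IMU-vs-video gait validation table."""
    return _load("imu_validation.csv")


def load_surface_calibration() -> pd.DataFrame:
    """Rigid/flexible surface force-sensor loading table (long format)."""
    return _load("surface_calibration.csv")


def surface_average_voltages() -> pd.DataFrame:
    """Per-load average voltages pivoted to ``flexible``/``rigid`` columns."""
    df = load_surface_calibration()
    wide = df.pivot(index="load_N", columns="surface", values="average_mV")
    return wide.reset_index()[["load_N", "flexible", "rigid"]]


def load_positioning_errors() -> pd.DataFrame:
    """Continuous positioning-accuracy table (five rounds × three transitions)."""
    return _load("positioning_errors.csv")
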