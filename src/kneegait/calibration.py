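"""Flexible-vs-rigid surface calibration of thin-film force sensors.

A force-sensing resistor mounted on a compliant insole distributes
membrane strain differently than the same sensor on a rigid bench, so
the two mounting conditions are calibrated against each other: the mean
output voltage on the flexible surface (predictor, mV) is regressed
onto the mean voltage on the rigid surface (response, mV) across a
ladder of applied loads, and the linear map is then used to translate
insole readings to the rigid-bench calibration curve.

Goodness-of-fit conventions: R² = 1 − SSE/SST, adjusted
R² = 1 − (1 − R²)(n − 1)/(n − 2), RMSE = √(SSE/n) (divisor n), and the
standard error of estimate SEE = √(SSE/(n − 2)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .series import SignalError


@dataclass
class CalibrationFit:
    """Ordinary least-squares line rigid = slope·flexible + intercept."""

    slope: float
    intercept: float
    r_square: float
    adj_r_square: float
    rmse: float
    see: float
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_square <= 1.0 + 1e-12:
            raise SignalError("r_square outside [0, 1]")
        if self.rmse < 0:
            raise SignalError("rmse must be non-negative")

    def predict(self, v):
        """Map flexible-surface voltage(s) to the rigid-surface scale."""
        return self.slope * np.asarray(v, dtype=float) + self.intercept


def fit_surface_calibration(flexible_mv, rigid_mv) -> CalibrationFit:
    """OLS fit of rigid-surface voltage on flexible-surface voltage.

    Parameters are the per-load average voltages (mV) under each
    mounting condition; needs at least 3 points and a non-constant
    predictor.
    """
    x = np.asarray(flexible_mv, dtype=float)
    y = np.asarray(rigid_mv, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise SignalError("flexible and rigid vectors must have equal length")
    n = len(x)
    if n < 3:
        raise SignalError("need at least 3 calibration points")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx <= 0:
        raise SignalError("zero variance in the flexible-surface voltages")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    sse = float(np.sum(resid**2))
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    return CalibrationFit(
        slope=slope,
        intercept=intercept,
        r_square=r2,
        adj_r_square=1.0 - (1.0 - r2) * (n - 1) / (n - 2),
        rmse=float(np.sqrt(sse / n)),
        see=float(np.sqrt(sse / (n - 2))),
        n=n,
    )


def flexible_to_rigid(fit: CalibrationFit, v):
    """Translate flexible-surface voltage(s) to the rigid-surface scale."""
    out = fit.predict(v)
    return float(out) if np.ndim(v) == 0 else out
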