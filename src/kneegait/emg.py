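"""Surface-EMG conditioning and activation/fatigue features.

Six scalar features per muscle quantify quadriceps activation intensity
and fatigue: integrated EMG (iEMG, the rectified sum Σ|xᵢ|), root mean
square (RMS), zero-crossing rate (ZCR), variance (VAR), and the two
spectral fatigue markers — mean power frequency (MPF, the spectral
centroid of the PSD) and median frequency (MF, the half-power split
point).  MF and MPF shift downward as muscle-fiber conduction velocity
drops with fatigue, which is what the windowed feature table is for.

Conditioning follows standard sEMG practice: zero-phase Butterworth
band-pass over the 20–450 Hz physiological band, a 50 Hz power-line
notch, and mean removal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

import numpy as np
import pandas as pd
from scipy import signal

from .series import EMG_MUSCLES, EmgRecord, SignalError, UniformSeries

#: Physiological sEMG band, Hz.
EMG_BAND = (20.0, 450.0)

#: Power-line frequency and notch quality factor.
NOTCH_HZ = 50.0
NOTCH_Q = 30.0


@dataclass
class PowerSpectrum:
    """One-sided power spectral density on a uniform frequency grid."""

    freqs: np.ndarray
    psd: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.freqs.shape != self.psd.shape or self.freqs.ndim != 1:
            raise SignalError("frequency grid and PSD must be equal-length vectors")
        if np.any(self.psd < 0):
            raise SignalError("PSD must be non-negative")

    @property
    def total_power(self) -> float:
        return float(np.trapezoid(self.psd, self.freqs))


def preprocess_emg(rec: EmgRecord) -> EmgRecord:
    """Condition raw sEMG: 20–450 Hz band-pass, 50 Hz notch, demean.

    Filters are zero-phase (forward-backward) so burst timing is
    preserved; requires fs > 900 Hz for the 450 Hz band edge.
    """
    if rec.fs <= 2 * EMG_BAND[1]:
        raise SignalError(
            f"fs={rec.fs} Hz too low for a {EMG_BAND[1]} Hz band edge"
        )
    sos = signal.butter(4, EMG_BAND, btype="bandpass", fs=rec.fs, output="sos")
    b_notch, a_notch = signal.iirnotch(NOTCH_HZ, NOTCH_Q, fs=rec.fs)
    out = np.empty_like(rec.data)
    for c in range(rec.data.shape[1]):
        y = signal.sosfiltfilt(sos, rec.data[:, c])
        y = signal.filtfilt(b_notch, a_notch, y)
        out[:, c] = y - y.mean()
    return EmgRecord(fs=rec.fs, data=out, t0=rec.t0)


def _check_window(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise SignalError("empty window")
    return x


def iemg(x) -> float:
    """Integrated EMG: the rectified sum Σ|xᵢ| over the window."""
    return float(np.abs(_check_window(x)).sum())


def rms(x) -> float:
    """Root mean square sqrt(Σxᵢ²/N)."""
    x = _check_window(x)
    return float(np.sqrt(np.mean(x**2)))


def zcr(x, deadband: float = 0.0) -> int:
    """Zero crossings: sign changes between consecutive samples.

    Samples with |x| ≤ ``deadband`` are ignored, so low-level noise
    around zero does not inflate the count.
    """
    x = _check_window(x)
    if deadband > 0:
        x = x[np.abs(x) > deadband]
        if x.size == 0:
            return 0
    return int(np.count_nonzero(x[1:] * x[:-1] < 0))


def variance(x) -> float:
    """Population variance Σ(xᵢ − x̄)²/N."""
    x = _check_window(x)
    return float(np.var(x))


def power_spectrum(x: UniformSeries) -> PowerSpectrum:
    """Welch PSD estimate: Hann window, 1 s segments, 50% overlap."""
    nperseg = int(round(x.fs))
    if len(x) < nperseg:
        raise SignalError("need at least 1 s of data for the Welch estimate")
    freqs, psd = signal.welch(
        x.values, fs=x.fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    return PowerSpectrum(freqs, psd)


def mpf(psd: PowerSpectrum) -> float:
    """Mean power frequency: the spectral centroid ∫f·PSD df / ∫PSD df."""
    total = psd.total_power
    if total <= 0:
        raise SignalError("zero total power: MPF undefined")
    return float(np.trapezoid(psd.freqs * psd.psd, psd.freqs) / total)


def mf(psd: PowerSpectrum) -> float:
    """Median frequency: the half-power split point of the PSD.

    The smallest f* with cumulative power ≥ half the total, with linear
    interpolation between frequency bins.
    """
    total = psd.total_power
    if total <= 0:
        raise SignalError("zero total power: MF undefined")
    cum = np.concatenate([[0.0], np.cumsum(np.diff(psd.freqs) * (psd.psd[1:] + psd.psd[:-1]) / 2.0)])
    half = total / 2.0
    j = int(np.searchsorted(cum, half))
    if j == 0:
        return float(psd.freqs[0])
    # linear interpolation of the cumulative power within bin [j-1, j]
    frac = (half - cum[j - 1]) / (cum[j] - cum[j - 1])
    return float(psd.freqs[j - 1] + frac * (psd.freqs[j] - psd.freqs[j - 1]))


def window_features(x: np.ndarray, fs: float) -> dict:
    """All six features of one window of one muscle."""
    spectrum = power_spectrum(UniformSeries(x, fs))
    return {
        "iemg": iemg(x),
        "rms": rms(x),
        "zcr": zcr(x),
        "var": variance(x),
        "mpf": mpf(spectrum),
        "mf": mf(spectrum),
    }


def emg_feature_table(rec: EmgRecord, window: float = 2.0, hop: float = 1.0) -> pd.DataFrame:
    """Windowed feature table over all three muscles.

    Windows are half-open ``[k·hop, k·hop + window)`` and must fit inside
    the record.  Returns one row per (window, muscle) with the window
    start time, muscle name and the six features.
    """
    if window > rec.duration:
        raise SignalError("window longer than the record")
    if window <= 0 or hop <= 0:
        raise SignalError("window and hop must be positive")
    n_win = int(np.floor((rec.duration - window) / hop + 1e-9)) + 1
    w = int(round(window * rec.fs))
    h = hop * rec.fs
    rows: List[dict] = []
    for k in range(n_win):
        i = int(round(k * h))
        for c, muscle in enumerate(EMG_MUSCLES):
            feats = window_features(rec.data[i : i + w, c], rec.fs)
            rows.append({"t_start": rec.t0 + i / rec.fs, "muscle": muscle, **feats})
    return pd.DataFrame(rows)
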