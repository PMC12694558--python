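"""Plantar-pressure filtering, stance-event detection and phase features.

A gait cycle runs from one initial heel contact (IFC) to the next.  The
stance phase is delimited by five events — IFC, initial metatarsal
contact (IMC), initial forefoot-flat contact (IFFC), heel off (HO) and
last foot contact (LFC) — and partitioned into four sub-phases: initial
contact (ICP = IMC−IFC), forefoot contact (FFCP = IFFC−IMC), foot flat
(FFP = HO−IFFC) and forefoot push-off (FFPOP = LFC−HO).  Swing runs from
LFC to the next IFC.

Contact is decided channel-by-channel against a relative threshold of 5%
of that channel's within-cycle peak, which makes event timing invariant
to the ±10% gain spread of thin-film force sensors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .series import PRESSURE_SITES, PressureRecord, SignalError, UniformSeries

#: Contact threshold as a fraction of the per-channel, per-cycle peak.
CONTACT_THRESHOLD_FRACTION = 0.05

#: Channel groups used by the event rules (indices into PRESSURE_SITES).
HEEL = (PRESSURE_SITES.index("heel_med"), PRESSURE_SITES.index("heel_lat"))
MIDFOOT = (PRESSURE_SITES.index("midfoot_med"), PRESSURE_SITES.index("midfoot_lat"))
METATARSAL = (
    PRESSURE_SITES.index("met1"),
    PRESSURE_SITES.index("met23"),
    PRESSURE_SITES.index("met45"),
)


class DetectionFailureError(SignalError):
    """Stance events could not be ordered IFC < IMC < IFFC < HO < LFC."""


@dataclass
class StanceEvents:
    """Per-cycle stance event times in seconds (arrays of equal length)."""

    t_ifc: np.ndarray
    t_imc: np.ndarray
    t_iffc: np.ndarray
    t_ho: np.ndarray
    t_lfc: np.ndarray

    def __post_init__(self) -> None:
        arrays = [
            np.atleast_1d(np.asarray(a, dtype=float))
            for a in (self.t_ifc, self.t_imc, self.t_iffc, self.t_ho, self.t_lfc)
        ]
        self.t_ifc, self.t_imc, self.t_iffc, self.t_ho, self.t_lfc = arrays
        n = len(self.t_ifc)
        if any(len(a) != n for a in arrays):
            raise SignalError("event arrays must have equal length")
        stacked = np.vstack(arrays)
        if n and np.any(np.diff(stacked, axis=0) <= 0):
            raise DetectionFailureError(
                "event ordering IFC < IMC < IFFC < HO < LFC violated"
            )
        if n > 1 and np.any(np.diff(self.t_ifc) <= 0):
            raise SignalError("cycles must be time-ordered")

    @property
    def n_cycles(self) -> int:
        return len(self.t_ifc)

    def cycle(self, i: int) -> Tuple[float, float, float, float, float]:
        return (
            float(self.t_ifc[i]),
            float(self.t_imc[i]),
            float(self.t_iffc[i]),
            float(self.t_ho[i]),
            float(self.t_lfc[i]),
        )


@dataclass
class PhaseDurations:
    """Stance sub-phase and swing durations of one gait cycle, seconds.

    Satisfies ICP + FFCP + FFP + FFPOP = stance and stance + swing =
    cycle duration; ``proportions`` are each duration over the full cycle
    and sum to 1.
    """

    t_icp: float
    t_ffcp: float
    t_ffp: float
    t_ffpop: float
    t_stance: float
    t_swing: float

    @property
    def cycle_duration(self) -> float:
        return self.t_stance + self.t_swing

    @property
    def proportions(self) -> dict:
        T = self.cycle_duration
        return {
            "icp": self.t_icp / T,
            "ffcp": self.t_ffcp / T,
            "ffp": self.t_ffp / T,
            "ffpop": self.t_ffpop / T,
            "stance": self.t_stance / T,
            "swing": self.t_swing / T,
        }


@dataclass
class PressureFeatures:
    """Cycle-averaged per-channel force features.

    ``peak`` — mean within-cycle maximum (sensor units); ``impulse`` —
    mean within-cycle time integral (sensor units·s); ``proportion`` —
    each channel's share of the total impulse (sums to 1).
    """

    peak: dict
    impulse: dict
    proportion: dict


def adaptive_filter(
    series: UniformSeries, window: int = 7, kappa: Optional[float] = None
) -> UniformSeries:
    """Adaptive weighted sliding filter preserving abrupt transitions.

    For each centered window the local range R = max − min sets the
    weight α = R/(R + κ); the output is α·x_center + (1−α)·mean(window).
    Quiet stretches (R ≪ κ) are smoothed toward the window mean while
    sharp edges and peaks (R ≫ κ) pass nearly unchanged — unlike a plain
    moving average, which blunts the very transitions the stance-event
    rules key on.  Edges use shrunken windows; κ defaults to 10% of the
    global signal range.
    """
    if window < 3 or window % 2 == 0:
        raise SignalError("window must be an odd integer >= 3")
    x = series.values
    if window > len(x):
        raise SignalError(f"window {window} longer than series ({len(x)} samples)")
    if kappa is None:
        rng = float(np.ptp(x))
        kappa = 0.1 * rng if rng > 0 else 1.0
    if kappa <= 0:
        raise SignalError("kappa must be positive")
    half = window // 2
    y = np.empty_like(x)
    for i in range(len(x)):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        w = x[lo:hi]
        r = float(w.max() - w.min())
        alpha = r / (r + kappa)
        y[i] = alpha * x[i] + (1.0 - alpha) * w.mean()
    return UniformSeries(y, series.fs, series.t0)


def filter_record(
    rec: PressureRecord, window: int = 7, kappa: Optional[float] = None
) -> PressureRecord:
    """Apply :func:`adaptive_filter` channel-wise; κ is shared across
    channels (10% of the record-wide range when not given)."""
    if kappa is None:
        rng = float(np.ptp(rec.data))
        kappa = 0.1 * rng if rng > 0 else 1.0
    filtered = np.column_stack(
        [
            adaptive_filter(UniformSeries(rec.data[:, c], rec.fs, rec.t0), window, kappa).values
            for c in range(rec.data.shape[1])
        ]
    )
    return PressureRecord(fs=rec.fs, data=np.clip(filtered, 0.0, None), t0=rec.t0)


def peak_pressure(series: UniformSeries, cycle: Tuple[float, float]) -> float:
    """Maximum force in the half-open time interval ``cycle``."""
    return float(series.slice_time(*cycle).values.max())


def impulse(series: UniformSeries, cycle: Tuple[float, float]) -> float:
    """Time integral of force over ``cycle`` by the trapezoidal rule,
    I = Δt·Σ(P_k + P_{k+1})/2 with Δt = 1/fs."""
    seg = series.slice_time(*cycle)
    if len(seg) < 2:
        raise SignalError("impulse needs at least 2 samples in the interval")
    return float(np.trapezoid(seg.values, dx=seg.dt))


def _segment_cycles(rec: PressureRecord) -> List[Tuple[int, int]]:
    """Split the record into IFC→IFC cycle index ranges via the total
    load: contiguous loaded regions (total force above 5% of its global
    maximum) are stance candidates; each cycle spans from one region
    start to the next (the last extends to the record end)."""
    total = rec.data.sum(axis=1)
    if total.max() <= 0:
        raise DetectionFailureError("record carries no load")
    loaded = total > CONTACT_THRESHOLD_FRACTION * total.max()
    edges = np.flatnonzero(np.diff(loaded.astype(int)) == 1) + 1
    starts = ([0] if loaded[0] else []) + edges.tolist()
    if not starts:
        raise DetectionFailureError("no loaded region found")
    bounds = starts + [len(total)]
    return [(bounds[i], bounds[i + 1]) for i in range(len(starts))]


def detect_stance_events(rec: PressureRecord) -> StanceEvents:
    """Detect the five stance events in every complete gait cycle.

    Within each IFC→IFC cycle, a channel is "in contact" while above 5%
    of its within-cycle peak (channels whose peak is under 5% of the
    cycle's strongest channel are treated as unloaded).  Then per cycle:
    IFC — first contact of either heel channel; IMC — first metatarsal
    contact after IFC; IFFC — first instant heel, midfoot and metatarsal
    groups are simultaneously in contact; HO — first instant after IFFC
    with both heel channels off; LFC — last instant any channel is in
    contact.  A cycle violating the event ordering raises
    :class:`DetectionFailureError`.
    """
    t = rec.times()
    out = {k: [] for k in ("ifc", "imc", "iffc", "ho", "lfc")}
    for lo, hi in _segment_cycles(rec):
        seg = rec.data[lo:hi]
        peaks = seg.max(axis=0)
        floor = CONTACT_THRESHOLD_FRACTION * peaks.max()
        thresh = CONTACT_THRESHOLD_FRACTION * peaks
        contact = (seg > thresh) & (peaks >= floor)  # unloaded channels never contact
        # debounce: real contact persists; an isolated single-sample
        # crossing (noise, or the filter's leak of a neighbouring cycle's
        # onset) is discarded
        prev = np.vstack([np.zeros((1, contact.shape[1]), bool), contact[:-1]])
        nxt = np.vstack([contact[1:], np.zeros((1, contact.shape[1]), bool)])
        contact &= prev | nxt
        heel = contact[:, HEEL].any(axis=1)
        mid = contact[:, MIDFOOT].any(axis=1)
        met = contact[:, METATARSAL].any(axis=1)
        any_c = contact.any(axis=1)
        try:
            i_ifc = int(np.flatnonzero(heel)[0])
            i_imc = int(np.flatnonzero(met & (np.arange(len(seg)) > i_ifc))[0])
            i_iffc = int(
                np.flatnonzero(heel & mid & met & (np.arange(len(seg)) > i_imc))[0]
            )
            heel_off = ~contact[:, HEEL].any(axis=1)
            i_ho = int(np.flatnonzero(heel_off & (np.arange(len(seg)) > i_iffc))[0])
            i_lfc = int(np.flatnonzero(any_c)[-1])
        except IndexError:
            raise DetectionFailureError(
                "could not locate all five stance events in a cycle"
            ) from None
        if not i_ifc < i_imc < i_iffc < i_ho < i_lfc:
            raise DetectionFailureError("detected events out of order (noisy signal?)")
        for key, idx in zip(out, (i_ifc, i_imc, i_iffc, i_ho, i_lfc)):
            out[key].append(t[lo + idx])
    return StanceEvents(*[np.array(out[k]) for k in ("ifc", "imc", "iffc", "ho", "lfc")])


def phase_durations(
    events: StanceEvents, cycle_index: int, next_t_ifc: float
) -> PhaseDurations:
    """Sub-phase, stance and swing durations for one cycle.

    ``next_t_ifc`` is the following cycle's initial heel contact and must
    come after this cycle's LFC.
    """
    ifc, imc, iffc, ho, lfc = events.cycle(cycle_index)
    if next_t_ifc <= lfc:
        raise SignalError("next IFC must come after this cycle's LFC")
    return PhaseDurations(
        t_icp=imc - ifc,
        t_ffcp=iffc - imc,
        t_ffp=ho - iffc,
        t_ffpop=lfc - ho,
        t_stance=lfc - ifc,
        t_swing=next_t_ifc - lfc,
    )


def all_phase_durations(events: StanceEvents) -> List[PhaseDurations]:
    """Phase durations for every cycle that has a successor."""
    return [
        phase_durations(events, i, float(events.t_ifc[i + 1]))
        for i in range(events.n_cycles - 1)
    ]


def pressure_features(rec: PressureRecord, events: StanceEvents) -> PressureFeatures:
    """Cycle-averaged peak pressure, impulse and impulse share per channel.

    Cycles span IFC→IFC (the last runs to the record end).  The impulse
    proportion divides each channel's mean impulse by the sum over
    channels.
    """
    if events.n_cycles < 1:
        raise SignalError("need at least one detected cycle")
    starts = list(events.t_ifc) + [rec.t0 + len(rec) / rec.fs]
    peaks = np.zeros((events.n_cycles, len(PRESSURE_SITES)))
    imps = np.zeros_like(peaks)
    for i in range(events.n_cycles):
        interval = (starts[i], starts[i + 1])
        for c, site in enumerate(PRESSURE_SITES):
            ch = rec.channel(site)
            peaks[i, c] = peak_pressure(ch, interval)
            imps[i, c] = impulse(ch, interval)
    mean_peak = peaks.mean(axis=0)
    mean_imp = imps.mean(axis=0)
    total = mean_imp.sum()
    if total <= 0:
        raise SignalError("all-zero record: impulse proportions undefined")
    return PressureFeatures(
        peak=dict(zip(PRESSURE_SITES, mean_peak)),
        impulse=dict(zip(PRESSURE_SITES, mean_imp)),
        proportion=dict(zip(PRESSURE_SITES, mean_imp / total)),
    )
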