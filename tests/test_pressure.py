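import numpy as np
import pytest

from kneegait import (
    PressureRecord,
    UniformSeries,
    WalkSpec,
    adaptive_filter,
    all_phase_durations,
    detect_stance_events,
    filter_record,
    generate_pressure_walk,
    impulse,
    peak_pressure,
    phase_durations,
    pressure_features,
)
from kneegait.pressure import DetectionFailureError, StanceEvents
from kneegait.series import PRESSURE_SITES, SignalError


class TestAdaptiveFilter:
    def test_constant_unchanged(self):
        s = UniformSeries(np.full(50, 3.0), fs=50.0)
        np.testing.assert_allclose(adaptive_filter(s, kappa=1.0).values, 3.0)

    def test_idempotent_on_constants(self):
        s = UniformSeries(np.full(50, 3.0), fs=50.0)
        once = adaptive_filter(s, kappa=1.0)
        twice = adaptive_filter(once, kappa=1.0)
        np.testing.assert_allclose(twice.values, once.values)

    def test_edge_preserved_versus_moving_average(self):
        """A unit step keeps >=90% of its jump, vs <=75% for a plain
        7-point moving average of the same input (brute-force oracle)."""
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = adaptive_filter(UniformSeries(x, fs=50.0), window=7, kappa=0.1).values
        jump = y[20] - y[19]
        ma = np.convolve(x, np.ones(7) / 7.0, mode="same")
        ma_jump = ma[20] - ma[19]
        assert jump >= 0.90
        assert ma_jump <= 0.75

    def test_smooths_noise_under_large_kappa(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=500)
        y = adaptive_filter(UniformSeries(x, fs=50.0), kappa=100.0).values
        assert y.var() < x.var()

    def test_length_preserved(self):
        s = UniformSeries(np.arange(11, dtype=float), fs=50.0)
        assert len(adaptive_filter(s, kappa=1.0)) == 11

    def test_window_validation(self):
        s = UniformSeries(np.zeros(5), fs=50.0)
        with pytest.raises(SignalError):
            adaptive_filter(s, window=4, kappa=1.0)
        with pytest.raises(SignalError):
            adaptive_filter(s, window=7, kappa=1.0)


class TestPeakAndImpulse:
    def test_peak_is_interval_max(self):
        s = UniformSeries(np.array([1.0, 5.0, 3.0]), fs=1.0)
        assert peak_pressure(s, (0.0, 3.0)) == 5.0

    def test_peak_of_constant(self):
        s = UniformSeries(np.full(10, 2.5), fs=10.0)
        assert peak_pressure(s, (0.0, 1.0)) == 2.5

    def test_impulse_of_constant_is_rectangle_area(self):
        fs, P, T = 50.0, 4.0, 2.0
        s = UniformSeries(np.full(int(T * fs) + 1, P), fs)
        # trapezoid over n samples spans (n-1)/fs seconds
        assert impulse(s, (0.0, T + 1 / fs)) == pytest.approx(P * T)

    def test_impulse_of_zero_signal(self):
        s = UniformSeries(np.zeros(100), fs=50.0)
        assert impulse(s, (0.0, 2.0)) == 0.0

    def test_triangular_pulse_area(self):
        fs, A, T = 200.0, 3.0, 1.0
        t = np.arange(int(T * fs) + 1) / fs
        tri = A * (1.0 - np.abs(2.0 * t / T - 1.0))
        s = UniformSeries(tri, fs)
        assert impulse(s, (0.0, T + 1 / fs)) == pytest.approx(A * T / 2, abs=A / fs)

    def test_impulse_needs_two_samples(self):
        s = UniformSeries(np.ones(100), fs=50.0)
        with pytest.raises(SignalError):
            impulse(s, (0.0, 0.02))


class TestDetectStanceEvents:
    def test_events_within_one_sample_of_truth(self, pressure_walk):
        rec, truth = pressure_walk
        ev = detect_stance_events(filter_record(rec))
        assert ev.n_cycles == truth.events.n_cycles
        for name in ("t_ifc", "t_imc", "t_iffc", "t_ho", "t_lfc"):
            err = np.abs(getattr(ev, name) - getattr(truth.events, name))
            assert np.max(err) <= 1.0 / rec.fs + 1e-9, name

    def test_heel_only_loading_fails(self):
        n = 200
        data = np.zeros((n, 8))
        heel = PRESSURE_SITES.index("heel_med")
        data[50:150, heel] = 10.0
        with pytest.raises(DetectionFailureError):
            detect_stance_events(PressureRecord(fs=50.0, data=data))

    def test_concatenated_cycles_shift_by_one_period(self):
        spec = WalkSpec(n_steps=2, pressure_noise_sd=0.0, seed=6)
        rec, _ = generate_pressure_walk(spec)
        ev = detect_stance_events(rec)
        assert ev.n_cycles == 2
        period = spec.cycle_period
        for name in ("t_ifc", "t_imc", "t_iffc", "t_ho", "t_lfc"):
            t = getattr(ev, name)
            assert t[1] - t[0] == pytest.approx(period, abs=1.0 / rec.fs)

    def test_amplitude_scaling_leaves_events_unchanged(self, pressure_walk_clean):
        rec, _ = pressure_walk_clean
        ev1 = detect_stance_events(rec)
        ev2 = detect_stance_events(PressureRecord(fs=rec.fs, data=3.5 * rec.data))
        for name in ("t_ifc", "t_imc", "t_iffc", "t_ho", "t_lfc"):
            np.testing.assert_allclose(getattr(ev2, name), getattr(ev1, name))


class TestPhaseDurations:
    def test_worked_example(self):
        ev = StanceEvents(
            t_ifc=[0.0], t_imc=[0.10], t_iffc=[0.30], t_ho=[0.50], t_lfc=[0.65]
        )
        p = phase_durations(ev, 0, 1.00)
        assert p.t_icp == pytest.approx(0.10)
        assert p.t_ffcp == pytest.approx(0.20)
        assert p.t_ffp == pytest.approx(0.20)
        assert p.t_ffpop == pytest.approx(0.15)
        assert p.t_stance == pytest.approx(0.65)
        assert p.t_swing == pytest.approx(0.35)
        assert sum(p.proportions[k] for k in ("icp", "ffcp", "ffp", "ffpop", "swing")) == pytest.approx(1.0, abs=1e-9)

    def test_additivity_invariants_on_detected_events(self, pressure_walk):
        ev = detect_stance_events(filter_record(pressure_walk[0]))
        for p in all_phase_durations(ev):
            assert p.t_icp + p.t_ffcp + p.t_ffp + p.t_ffpop == pytest.approx(
                p.t_stance, abs=1e-9
            )
            assert p.t_stance + p.t_swing == pytest.approx(p.cycle_duration, abs=1e-9)

    def test_next_ifc_must_follow_lfc(self):
        ev = StanceEvents(
            t_ifc=[0.0], t_imc=[0.1], t_iffc=[0.3], t_ho=[0.5], t_lfc=[0.65]
        )
        with pytest.raises(SignalError):
            phase_durations(ev, 0, 0.60)

    def test_ordering_violation_rejected_at_construction(self):
        with pytest.raises(DetectionFailureError):
            StanceEvents(t_ifc=[0.2], t_imc=[0.1], t_iffc=[0.3], t_ho=[0.5], t_lfc=[0.6])


class TestPressureFeatures:
    @staticmethod
    def _single_cycle_record(loaded_channels, amp=10.0):
        n = 200
        data = np.zeros((n, 8))
        for c in loaded_channels:
            data[20:100, c] = amp
        return PressureRecord(fs=50.0, data=data)

    @staticmethod
    def _one_cycle_events():
        return StanceEvents(
            t_ifc=[0.4], t_imc=[0.5], t_iffc=[0.6], t_ho=[1.5], t_lfc=[1.98]
        )

    def test_single_loaded_channel_owns_all_impulse(self):
        rec = self._single_cycle_record([0])
        feats = pressure_features(rec, self._one_cycle_events())
        assert feats.proportion["toe1"] == pytest.approx(1.0)

    def test_two_identical_channels_split_evenly(self):
        rec = self._single_cycle_record([0, 1])
        feats = pressure_features(rec, self._one_cycle_events())
        assert feats.proportion["toe1"] == pytest.approx(0.5)
        assert feats.proportion["met1"] == pytest.approx(0.5)

    def test_proportions_match_analytic_areas(self, pressure_walk_clean):
        rec, truth = pressure_walk_clean
        ev = detect_stance_events(rec)
        feats = pressure_features(rec, ev)
        analytic = np.array([truth.cycle_impulse[s] for s in PRESSURE_SITES])
        analytic /= analytic.sum()
        measured = np.array([feats.proportion[s] for s in PRESSURE_SITES])
        np.testing.assert_allclose(measured, analytic, atol=0.01)

    def test_proportions_sum_to_one(self, pressure_walk):
        rec = filter_record(pressure_walk[0])
        feats = pressure_features(rec, detect_stance_events(rec))
        assert sum(feats.proportion.values()) == pytest.approx(1.0, abs=1e-9)

    def test_peak_equals_plateau_without_noise(self, pressure_walk_clean):
        rec, truth = pressure_walk_clean
        feats = pressure_features(rec, detect_stance_events(rec))
        for site, amp in truth.amplitudes.items():
            assert feats.peak[site] == pytest.approx(amp, rel=1e-6)

    def test_amplitude_scaling_scales_features(self, pressure_walk_clean):
        rec, _ = pressure_walk_clean
        ev = detect_stance_events(rec)
        f1 = pressure_features(rec, ev)
        f2 = pressure_features(PressureRecord(fs=rec.fs, data=2.0 * rec.data), ev)
        for site in PRESSURE_SITES:
            assert f2.peak[site] == pytest.approx(2.0 * f1.peak[site])
            assert f2.impulse[site] == pytest.approx(2.0 * f1.impulse[site])
            assert f2.proportion[site] == pytest.approx(f1.proportion[site])

    def test_all_zero_record_rejected(self):
        rec = PressureRecord(fs=50.0, data=np.zeros((200, 8)))
        with pytest.raises(SignalError):
            pressure_features(rec, self._one_cycle_events())
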