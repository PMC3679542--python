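"""Optical-trap analysis: calibration, event scoring, drag, derived forces."""

import numpy as np
import pytest

from iftmotion.config import ConfigError, TrapSimConfig
from iftmotion.trap_sim import TrapTrace, simulate_recoil, simulate_trap_trace
from iftmotion.trapforce import (FitRejected, StationarityError,
                                 calibrate_stiffness, classify_events,
                                 drag_force, fit_recoil, motor_count,
                                 oscillation_drag, peak_force_stats,
                                 recoil_fits)


def _flat_trace(x, rate=2000.0, kappa=0.4):
    t = np.arange(x.size) / rate
    return TrapTrace(t, x, kappa, rate)


class TestCalibration:
    def test_equipartition_recovers_kappa_within_5pct(self):
        cfg = TrapSimConfig(event_rate=0.0, seed=5)
        trace, _ = simulate_trap_trace(cfg, 200.0)
        assert calibrate_stiffness(trace) == pytest.approx(0.4, rel=0.05)

    def test_doubled_variance_halves_kappa(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0.0, 3.0, 4000)
        k1 = calibrate_stiffness(_flat_trace(x))
        k2 = calibrate_stiffness(_flat_trace(np.sqrt(2.0) * x))
        assert k2 == pytest.approx(k1 / 2.0, rel=1e-6)

    def test_drift_ramp_raises_stationarity_error(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 2.0, 4000) + np.linspace(0.0, 30.0, 4000)
        with pytest.raises(StationarityError):
            calibrate_stiffness(_flat_trace(x))

    def test_short_segment_rejected(self):
        with pytest.raises(ConfigError):
            calibrate_stiffness(_flat_trace(np.zeros(500)))


def _constructed_excursion(plateau_s, peak_nm, rate=2000.0, kappa=0.4,
                           ramp_nm_s=250.0, pre_s=0.5, post_s=0.5):
    """Noiseless excursion: ramp up, plateau, exponential recoil."""
    dt = 1.0 / rate
    t_ramp = peak_nm / ramp_nm_s
    tau = 0.02
    t_total = pre_s + t_ramp + plateau_s + post_s
    t = np.arange(int(t_total * rate)) * dt
    x = np.zeros(t.size)
    rise = (t >= pre_s) & (t < pre_s + t_ramp)
    x[rise] = ramp_nm_s * (t[rise] - pre_s)
    plat = (t >= pre_s + t_ramp) & (t < pre_s + t_ramp + plateau_s)
    x[plat] = peak_nm
    fall = t >= pre_s + t_ramp + plateau_s
    x[fall] = peak_nm * np.exp(-(t[fall] - (pre_s + t_ramp + plateau_s))
                               / tau)
    tr = TrapTrace(t, x, kappa, rate, orientation="positive")
    return tr


class TestClassifyEvents:
    def test_long_plateau_scored_as_stall(self):
        trace = _constructed_excursion(0.15, 63.0)
        events = classify_events(trace)
        assert len(events) == 1
        ev = events[0]
        assert ev.type == "stall"
        assert ev.peak_force == pytest.approx(0.4 * 63.0, rel=0.01)
        assert ev.direction == "retrograde"

    def test_short_plateau_scored_as_release(self):
        trace = _constructed_excursion(0.05, 63.0)
        events = classify_events(trace)
        assert len(events) == 1
        assert events[0].type == "release"

    def test_beyond_detector_range_scored_as_escape(self):
        trace = _constructed_excursion(0.0, 230.0)
        events = classify_events(trace)
        assert len(events) == 1
        assert events[0].type == "escape"

    def test_agreement_with_simulator_labels_above_95pct(self):
        total, ok = 0, 0
        for seed in range(12):
            trace, labels = simulate_trap_trace(TrapSimConfig(seed=seed),
                                                60.0)
            events = classify_events(trace)
            for lab in labels:
                overlap = [e for e in events
                           if e.t_start < lab.t_end and e.t_end > lab.t_start]
                best = min(overlap,
                           key=lambda e: abs(e.peak_force - lab.peak_force)) \
                    if overlap else None
                total += 1
                if best and best.type == lab.type \
                        and best.direction == lab.direction:
                    ok += 1
        assert total > 150
        assert ok / total >= 0.95

    def test_invalid_window_rejected(self):
        trace = _constructed_excursion(0.15, 63.0)
        with pytest.raises(ConfigError):
            classify_events(trace, stall_min=0.1, v_window=0.2)


class TestPeakForceStats:
    def test_degenerate_single_value_stats(self):
        from iftmotion.trapforce import ForceEvent
        events = [ForceEvent("stall", "retrograde", 20.0, 0.2, 0.0, 1.0)
                  for _ in range(5)]
        out = peak_force_stats(events)
        assert out["retrograde/stall"]["mean"] == 20.0
        assert out["retrograde/stall"]["sem"] == 0.0
        assert out["retrograde/fractions"]["stall"] == 1.0

    def test_single_event_sem_reported_as_nan(self):
        from iftmotion.trapforce import ForceEvent
        out = peak_force_stats(
            [ForceEvent("release", "anterograde", 18.0, 0.0, 0.0, 1.0)])
        assert np.isnan(out["anterograde/release"]["sem"])

    def test_empty_event_list_rejected(self):
        with pytest.raises(ConfigError):
            peak_force_stats([])

    def test_simulated_stall_force_mean_recovered(self):
        """Recovered mean peak stall force agrees with the simulator's
        labels within 2 SEM over ~100 stalls."""
        rec, true = [], []
        for seed in range(10):
            trace, labels = simulate_trap_trace(TrapSimConfig(seed=seed),
                                                60.0)
            events = classify_events(trace)
            rec += [e.peak_force for e in events if e.type == "stall"]
            true += [l.peak_force for l in labels if l.type == "stall"]
        assert len(rec) >= 60
        sem = np.std(true) / np.sqrt(len(true))
        assert np.mean(rec) == pytest.approx(np.mean(true), abs=2 * sem)


class TestRecoilFit:
    def test_noiseless_exponential_gives_exact_gamma(self):
        cfg = TrapSimConfig(seed=0)
        trace = simulate_recoil(cfg, x0=60.0, thermal=False)
        fit = fit_recoil(trace.t, trace.x, 0.4)
        assert fit.gamma == pytest.approx(8.0, abs=1e-6)
        assert fit.tau == pytest.approx(0.02, abs=1e-8)

    def test_gamma_linear_in_tau(self):
        t = np.arange(400) / 2000.0
        for tau, expected in ((0.02, 8.0), (0.04, 16.0)):
            x = 60.0 * np.exp(-t / tau)
            fit = fit_recoil(t, x, 0.4)
            assert fit.gamma == pytest.approx(expected, rel=1e-4)

    def test_non_decaying_segment_rejected(self):
        t = np.arange(100) / 2000.0
        with pytest.raises(FitRejected):
            fit_recoil(t, np.linspace(0.0, 50.0, 100), 0.4)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ConfigError):
            fit_recoil(np.arange(5) / 2000.0, np.ones(5), 0.4)

    def test_100_thermal_recoils_recover_gamma_within_10pct(self):
        cfg = TrapSimConfig(seed=0)
        gammas = []
        for seed in range(100):
            tr = simulate_recoil(cfg, x0=63.0, duration=0.15, thermal=True,
                                 seed=1000 + seed)
            try:
                gammas.append(fit_recoil(tr.t, tr.x, 0.4).gamma)
            except FitRejected:
                continue
        assert len(gammas) >= 80
        assert np.mean(gammas) == pytest.approx(8.0, rel=0.10)

    def test_recoils_extracted_from_classified_trace(self):
        trace, _ = simulate_trap_trace(TrapSimConfig(seed=3), 60.0)
        events = classify_events(trace)
        fits = recoil_fits(trace, events)
        assert fits
        assert np.mean([f.gamma for f in fits]) == pytest.approx(8.0,
                                                                 rel=0.25)


class TestOscillationDrag:
    @staticmethod
    def _square_wave_trace(gamma_um=8.4, kappa=0.07, seed=3, noise=True):
        rate, dur = 2000.0, 20.0
        dt = 1.0 / rate
        n = int(dur * rate)
        t = np.arange(n) * dt
        centre = 250.0 * np.sign(np.sin(2 * np.pi * 0.2 * t + 1e-9))
        gamma = gamma_um * 1e-3
        rng = np.random.default_rng(seed)
        sd = np.sqrt(2 * 4.11 * dt / gamma) if noise else 0.0
        x = np.empty(n)
        x[0] = centre[0]
        w = rng.normal(0.0, sd, n) if noise else np.zeros(n)
        for i in range(1, n):
            x[i] = x[i - 1] + dt * kappa * (centre[i] - x[i - 1]) / gamma \
                + w[i]
        steps = t[np.flatnonzero(np.diff(centre) != 0) + 1]
        return TrapTrace(t, x, kappa, rate), steps

    def test_square_wave_relaxations_recover_gamma(self):
        trace, steps = self._square_wave_trace()
        fit = oscillation_drag(trace, steps, 500.0, 0.07)
        assert fit.gamma == pytest.approx(8.4, rel=0.10)
        assert fit.tau == pytest.approx(8.4e-3 / 0.07, rel=0.15)

    def test_noise_only_trace_raises(self):
        rng = np.random.default_rng(4)
        trace = _flat_trace(rng.normal(0.0, 3.0, 8000), kappa=0.07)
        with pytest.raises(ConfigError):
            oscillation_drag(trace, np.array([0.5, 1.5]), 500.0, 0.07)

    def test_recoil_and_oscillation_protocols_agree(self):
        """Both drag estimates from the same underlying gamma agree
        within 15%."""
        cfg = TrapSimConfig(seed=0)
        gammas = [fit_recoil(tr.t, tr.x, 0.4).gamma for tr in
                  (simulate_recoil(cfg, 63.0, 0.15, True, 2000 + s)
                   for s in range(40))]
        trace, steps = self._square_wave_trace(gamma_um=8.0, seed=6)
        osc = oscillation_drag(trace, steps, 500.0, 0.07)
        assert abs(np.mean(gammas) - osc.gamma) / osc.gamma < 0.15


class TestDerivedQuantities:
    @pytest.mark.parametrize("force,single,expected", [
        (25.2, 7.0, 4),     # at least four motors per train
        (6.99, 7.0, 1),
        (21.4, 6.0, 4),
    ])
    def test_motor_count(self, force, single, expected):
        assert motor_count(force, single) == expected

    def test_motor_count_monotone_in_peak_force(self):
        forces = np.linspace(0.0, 60.0, 200)
        counts = [motor_count(f, 7.0) for f in forces]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_motor_count_invalid_single_force(self):
        with pytest.raises(ConfigError):
            motor_count(25.0, 0.0)

    @pytest.mark.parametrize("gamma,v,expected", [
        (8.0, 3.0, 24.0), (8.0, 2.0, 16.0), (8.0, 0.0, 0.0),
    ])
    def test_drag_force_values(self, gamma, v, expected):
        assert drag_force(gamma, v) == pytest.approx(expected)

    def test_drag_force_linear(self):
        assert drag_force(4.0, 3.0) * 2 == drag_force(8.0, 3.0)
        assert drag_force(8.0, 1.5) * 2 == drag_force(8.0, 3.0)
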