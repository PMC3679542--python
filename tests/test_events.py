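"""Event statistics: correlation, colocalization, pauses, lags, profiles."""

import numpy as np
import pytest
from scipy import stats

from iftmotion.config import ConfigError, SimConfig
from iftmotion.events import (GlideEvent, PauseEvent, Track,
                              colocalization_test, correlate_tracks,
                              detect_gliding_onset, detect_pauses,
                              independence_test, lag_time_analysis,
                              pause_profile)
from iftmotion.kymo import Kymograph
from iftmotion.synthetic import simulate_bead, simulate_ift


def _track(t, x, tid=0, entity="bead", direction="unknown"):
    return Track(tid, entity, np.asarray(t, float), np.asarray(x, float),
                 direction=direction)


class TestCorrelateTracks:
    def test_constant_offset_gives_r_one(self):
        t = np.arange(20) * 0.2
        a = _track(t, 1.5 * t)
        b = _track(t, 1.5 * t + 0.28)
        r, n = correlate_tracks(a, b)
        assert r == pytest.approx(1.0)
        assert n == 20

    def test_time_reversed_linear_motion_gives_r_minus_one(self):
        t = np.arange(20) * 0.2
        a = _track(t, 2.0 * t)
        b = _track(t, 2.0 * t[::-1])
        r, _ = correlate_tracks(a, b)
        assert r == pytest.approx(-1.0)

    def test_insufficient_overlap_rejected(self):
        a = _track([0, 1, 2, 3], [0, 1, 2, 3])
        b = _track([10, 11, 12, 13], [0, 1, 2, 3])
        with pytest.raises(ConfigError):
            correlate_tracks(a, b)

    def test_simulated_coupled_segment_correlates_above_099(self):
        """A bead riding a train (with localization noise at SNR ~ 10)
        correlates > 0.99 with the train track."""
        rng = np.random.default_rng(8)
        t = np.arange(30) * 0.2
        train_pos = 9.0 - 2.96 * t
        loc_sd = 0.02
        a = _track(t, train_pos + rng.normal(0, loc_sd, t.size), 0, "train")
        b = _track(t, train_pos + rng.normal(0, loc_sd, t.size), 1, "bead")
        r, _ = correlate_tracks(a, b)
        assert r > 0.99


class TestColocalization:
    @staticmethod
    def _regime(seed, coupled):
        cfg = SimConfig(duration=120, seed=seed, pause_rate_max=0.0,
                        pause_rate_residual=0.0,
                        bead_attach_rate=1.0 if coupled else 0.0,
                        bead_detach_rate=0.25, bead_speed_factor=1.0)
        truth = simulate_bead(cfg, simulate_ift(cfg))
        bead = Track(0, "bead", truth.bead.t, truth.bead.s)
        trains = [Track(tr.id, "train", tr.t, tr.s, direction=tr.direction)
                  for tr in truth.trains if tr.t.size >= 2]
        return bead, trains

    def test_bead_riding_a_train_gives_zero_distances(self):
        t = np.arange(40) * 0.2
        pos = 1.0 + 2.0 * t
        bead = _track(t, pos)
        train = _track(t, pos, 1, "train", "anterograde")
        obs, null, ks, p = colocalization_test(bead, [train], n_null=10,
                                               seed=0)
        assert np.allclose(obs, 0.0)

    def test_small_n_null_rejected(self):
        t = np.arange(40) * 0.2
        bead = _track(t, t)
        train = _track(t, t, 1, "train", "anterograde")
        with pytest.raises(ConfigError):
            colocalization_test(bead, [train], n_null=5)

    def test_independent_bead_gives_nonsignificant_p(self):
        ps = [colocalization_test(*self._regime(seed, False), n_null=20,
                                  seed=seed + 500, stride=3)[3]
              for seed in range(12)]
        # under the null, p should rarely be extreme
        assert np.median(ps) > 0.05

    def test_coupled_bead_detected_with_high_power(self):
        ps = [colocalization_test(*self._regime(seed, True), n_null=20,
                                  seed=seed + 900, stride=3)[3]
              for seed in range(8)]
        assert all(p < 0.01 for p in ps)


class TestDetectPauses:
    def test_steadily_moving_track_has_no_pauses(self):
        t = np.arange(50) * 0.2
        events, st = detect_pauses([_track(t, 3.0 * t, entity="train")],
                                   acquisition_time=10.0)
        assert events == []
        assert st["frequency"] == 0.0

    def test_fully_immotile_track_excluded(self):
        t = np.arange(50) * 0.2
        events, _ = detect_pauses([_track(t, np.full(t.size, 4.0),
                                          entity="train")],
                                  acquisition_time=10.0)
        assert events == []

    def test_pause_interval_and_prior_direction_recovered(self):
        t = np.arange(60) * 0.2
        x = np.where(t < 4.0, 8.0 - 2.0 * t,
                     np.where(t < 8.0, 0.0, 2.0 * (t - 8.0)))
        x[t < 4.0] = 8.0 - 2.0 * t[t < 4.0]
        x[(t >= 4.0) & (t < 8.0)] = 0.0
        x[t >= 8.0] = 2.0 * (t[t >= 8.0] - 8.0)
        events, _ = detect_pauses([_track(t, x, entity="train")],
                                  acquisition_time=12.0)
        assert len(events) == 1
        ev = events[0]
        assert ev.prior_direction == "retrograde"
        assert ev.t_start == pytest.approx(4.0, abs=0.5)
        assert ev.t_end == pytest.approx(8.0, abs=0.5)

    def test_frequency_recovery_on_simulated_cell(self):
        """Detected (censoring-corrected) pausing frequency matches the
        configured 0.125 /s within 3 Poisson SE on a single 400 s cell."""
        cfg = SimConfig(duration=400, seed=21)
        truth = simulate_ift(cfg)
        tracks = [Track(tr.id, "train", tr.t, tr.s, direction=tr.direction)
                  for tr in truth.trains]
        _, st = detect_pauses(tracks, acquisition_time=400.0)
        se = np.sqrt(0.125 / 400.0)
        assert abs(st["frequency_corrected"] - 0.125) < 3 * se

    def test_pause_component_route(self):
        data = np.zeros((50, 40))
        data[10:30, 20] = 50.0     # 4 s vertical ridge
        k = Kymograph(data, 0.106, 0.2)
        events, st = detect_pauses(k, component_percentile=95.0)
        assert len(events) == 1
        assert events[0].position == pytest.approx(20 * 0.106, abs=0.106)


class TestGlidingOnset:
    def test_stationary_body_has_no_events(self):
        t = np.arange(60) * 0.2
        assert detect_gliding_onset(_track(t, np.zeros(t.size))) == []

    def test_constructed_run_onset_time_and_speed(self):
        t = np.arange(100) * 0.2
        x = np.clip(t - 10.0, 0.0, 4.0) * 1.5
        events = detect_gliding_onset(_track(t, x), v_thresh=0.3)
        assert len(events) == 1
        ev = events[0]
        assert ev.onset == pytest.approx(10.0, abs=0.4)
        assert ev.speed == pytest.approx(1.5, rel=0.1)
        assert ev.direction == 1


class TestLagTime:
    def test_single_lag_value(self):
        pauses = [PauseEvent(0, 5.0, 10.0, 12.0, "retrograde")]
        glides = [GlideEvent(10.5, 1, 1.0)]
        res = lag_time_analysis(pauses, glides, leading_flagellum=0)
        assert res["lags"].tolist() == [0.5]

    def test_onset_without_retrograde_pause_flagged(self):
        pauses = [PauseEvent(0, 5.0, 9.0, 12.0, "anterograde")]
        glides = [GlideEvent(10.5, 1, 1.0)]
        res = lag_time_analysis(pauses, glides, leading_flagellum=0)
        assert res["n"] == 0
        assert len(res["excluded"]) == 1

    @pytest.mark.parametrize("tau", [0.25, 0.5, 1.0, 2.0])
    def test_exponential_tau_recovery_unbiased(self, tau):
        """ML fit (sample mean) recovers tau with <10% bias at n=36."""
        rng = np.random.default_rng(17)
        estimates = []
        for _ in range(200):
            lags = rng.exponential(tau, 36)
            pauses = [PauseEvent(0, 5.0, 100.0 + i, 120.0 + i, "retrograde")
                      for i in range(1)]
            glides = [GlideEvent(100.0 + lag, 1, 1.0) for lag in lags]
            res = lag_time_analysis(pauses, glides, leading_flagellum=0)
            estimates.append(res["tau"])
        assert abs(np.mean(estimates) / tau - 1.0) < 0.1

    def test_single_seed_tau_within_2_se(self):
        rng = np.random.default_rng(3)
        lags = rng.exponential(0.48, 36)
        pauses = [PauseEvent(0, 5.0, 50.0, 60.0, "retrograde")]
        glides = [GlideEvent(50.0 + lag, 1, 1.0) for lag in lags]
        res = lag_time_analysis(pauses, glides, leading_flagellum=0)
        se = 0.48 / np.sqrt(36)
        assert abs(res["tau"] - 0.48) < 2 * se


class TestIndependenceTest:
    def test_mean_equal_to_null_gives_half(self):
        # the mean of n exponentials is right-skewed, so P(mean <= m)
        # sits slightly above 1/2 at finite n (0.525 for n = 36)
        p = independence_test(8.25, 36, 8.25, n_mc=10 ** 5, seed=1)
        assert p == pytest.approx(0.5, abs=0.05)
        assert p == pytest.approx(stats.gamma.cdf(8.25, a=36,
                                                  scale=8.25 / 36),
                                  abs=0.01)

    def test_large_observed_mean_gives_p_near_one(self):
        p = independence_test(8.25 * 3, 36, 8.25, n_mc=10 ** 4, seed=2)
        assert p > 0.99

    def test_monte_carlo_agrees_with_gamma_closed_form(self):
        """The mean of n exponential lags is Gamma(n, m/n); the MC
        p-value must match the closed-form CDF."""
        m, n = 8.25, 36
        for q in (6.0, 7.0, 8.0):
            p_mc = independence_test(q, n, m, n_mc=10 ** 5, seed=4)
            p_exact = stats.gamma.cdf(q, a=n, scale=m / n)
            assert p_mc == pytest.approx(p_exact, abs=0.01)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ConfigError):
            independence_test(0.5, 1, 8.25)
        with pytest.raises(ConfigError):
            independence_test(-0.5, 36, 8.25)


class TestPauseProfile:
    def test_uniform_coverage_gives_flat_profile(self):
        rng = np.random.default_rng(9)
        data = rng.uniform(10.0, 12.0, (100, 80))
        data[:, ::4] += 50.0     # regular bright pause columns
        k = Kymograph(data, 0.106, 0.2)
        centres, prof = pause_profile(k, 80 * 0.106, n_bins=8)
        assert prof.std() / prof.mean() < 0.3

    def test_basal_pauses_concentrate_profile_mass(self):
        """Ca2+-deprived regime: pauses only near the base."""
        data = np.full((100, 100), 5.0)
        data[:, :15] = 80.0
        k = Kymograph(data, 0.106, 0.2)
        centres, prof = pause_profile(k, 100 * 0.106, n_bins=10)
        basal = prof[centres < 0.2].sum()
        assert basal / prof.sum() > 0.9

    def test_zero_component_gives_zero_profile(self):
        k = Kymograph(np.zeros((20, 30)), 0.106, 0.2)
        _, prof = pause_profile(k, 30 * 0.106, n_bins=5)
        assert np.allclose(prof, 0.0)
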