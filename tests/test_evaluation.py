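"""Steady-state metrics, transition timing, reliability analytics."""

import numpy as np
import pytest
from scipy import integrate, stats

from bspctl import (
    TargetSchedule,
    generate_target_protocol,
    level_reliability,
    overall_reliability,
    performance_error,
    pool_reports,
    steady_state_mask,
    steady_state_metrics,
    transition_metrics,
)
from bspctl.datasets import RODENT_SESSION_METRICS


class TestMask:
    def test_single_level_true_after_initial_window(self):
        sched = TargetSchedule(breakpoints=(0.0,), levels=(0.5,))
        mask = steady_state_mask(sched, dt=1.0, n_steps=900)
        assert not mask[:300].any()
        assert mask[300:].all()

    def test_retained_count_for_mixed_transitions(self):
        # 0.7 -> 0.9 (up, 300 s masked) -> 0.4 (down, 420 s masked)
        sched = TargetSchedule(breakpoints=(0.0, 900.0, 1800.0),
                               levels=(0.7, 0.9, 0.4))
        mask = steady_state_mask(sched, dt=1.0, n_steps=2700)
        assert mask.sum() == 2700 - 300 - 300 - 420

    def test_direction_dependent_windows(self):
        up = TargetSchedule(breakpoints=(0.0, 600.0), levels=(0.4, 0.7))
        down = TargetSchedule(breakpoints=(0.0, 600.0), levels=(0.7, 0.4))
        m_up = steady_state_mask(up, dt=1.0, n_steps=1200)
        m_down = steady_state_mask(down, dt=1.0, n_steps=1200)
        assert (~m_up[600:]).sum() == 300
        assert (~m_down[600:]).sum() == 420


class TestPerformanceError:
    def test_exact_tracking_gives_zero(self):
        dev, pct = performance_error([0.5, 0.5], [0.5, 0.5])
        assert np.all(dev == 0) and np.all(pct == 0)

    def test_hand_computed_values_and_sign(self):
        dev, pct = performance_error([0.52, 0.48], [0.5, 0.5])
        assert dev[0] == pytest.approx(0.02)
        assert pct[0] == pytest.approx(4.0)
        assert pct[1] == pytest.approx(-4.0)  # below target -> negative bias

    def test_zero_target_excluded(self):
        _, pct = performance_error([0.1], [0.0])
        assert np.isnan(pct[0])


class TestSteadyStateMetrics:
    def test_hand_computed_medians(self):
        p_target = np.full(3, 0.5)
        p_hat = p_target + np.array([0.01, -0.02, 0.03])
        rep = steady_state_metrics(p_hat, p_target, np.ones(3, bool))
        assert rep.overall.mad == pytest.approx(0.02)
        assert rep.overall.mdpe == pytest.approx(2.0)
        assert rep.overall.mdape == pytest.approx(4.0)

    def test_cross_experiment_pooling_reproduces_published_table(self):
        # six per-experiment All-Levels values -> cross-experiment medians
        allv = RODENT_SESSION_METRICS["all"]
        assert pool_reports(allv["mdape"]) == pytest.approx(3.61, abs=0.01)
        assert pool_reports(allv["mdpe"]) == pytest.approx(-1.44, abs=0.01)
        assert pool_reports(allv["mad"]) == pytest.approx(0.022, abs=0.0005)
        high = RODENT_SESSION_METRICS["high"]
        assert pool_reports(high["mdape"]) == pytest.approx(2.78, abs=0.01)

    def test_per_level_banding(self):
        p_target = np.r_[np.full(100, 0.4), np.full(100, 0.7), np.full(100, 0.9)]
        p_hat = p_target + 0.01
        rep = steady_state_metrics(p_hat, p_target, np.ones(300, bool))
        assert set(rep.per_level) == {"low", "mid", "high"}
        assert rep.per_level["low"].mdpe == pytest.approx(100 * 0.01 / 0.4)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            steady_state_metrics([0.5], [0.5], [False])


class TestTransitions:
    def test_zero_time_when_already_in_band(self):
        sched = TargetSchedule(breakpoints=(0.0, 100.0), levels=(0.5, 0.52))
        p_hat = np.full(200, 0.5)
        rep = transition_metrics(p_hat, sched, dt=1.0)
        assert rep.transitions[0]["time_s"] == 0.0

    def test_linear_ramp_crossing_time_and_rate(self):
        # ramp 0.4 -> 0.9 over 100 s after the step at t = 100:
        # first |p - 0.9| <= 0.05 at p = 0.85, i.e. 90 s after the step;
        # rate = 0.5 / 1.5 min
        sched = TargetSchedule(breakpoints=(0.0, 100.0), levels=(0.4, 0.9))
        t = np.arange(300, dtype=float)
        p_hat = np.where(t < 100, 0.4, np.minimum(0.4 + (t - 100) * 0.005, 0.9))
        rep = transition_metrics(p_hat, sched, dt=1.0)
        assert rep.median_rise_s == pytest.approx(90.0)
        assert rep.median_rise_rate_per_min == pytest.approx(0.5 / 1.5)

    def test_mirrored_fall_matches_rise(self):
        sched = TargetSchedule(breakpoints=(0.0, 100.0), levels=(0.9, 0.4))
        t = np.arange(300, dtype=float)
        p_hat = np.where(t < 100, 0.9, np.maximum(0.9 - (t - 100) * 0.005, 0.4))
        rep = transition_metrics(p_hat, sched, dt=1.0)
        assert rep.median_fall_s == pytest.approx(90.0)
        assert rep.median_fall_rate_per_min == pytest.approx(0.5 / 1.5)

    def test_unreached_band_flagged_missing(self):
        sched = TargetSchedule(breakpoints=(0.0, 10.0), levels=(0.4, 0.9))
        rep = transition_metrics(np.full(100, 0.4), sched, dt=1.0)
        assert rep.transitions[0]["time_s"] is None
        assert rep.median_rise_s is None


class TestLevelReliability:
    def test_perfect_tracking_is_highly_reliable(self):
        v = level_reliability(np.zeros(100))
        assert v["reliable"] and v["highly_reliable"]

    def test_heavy_tail_fails_reliability(self):
        devs = np.r_[np.full(94, 0.01), np.full(6, 0.2)]
        v = level_reliability(devs)
        assert v["p95"] >= 0.15
        assert not v["reliable"]

    def test_uniform_errors_reliable_but_not_highly(self):
        devs = np.linspace(0.0, 0.12, 1001)  # 95th pct = 0.114
        v = level_reliability(devs)
        assert v["p95"] == pytest.approx(0.114, abs=1e-9)
        assert v["reliable"] and not v["highly_reliable"]

    def test_insufficient_samples_undetermined(self):
        v = level_reliability(np.zeros(5))
        assert v["reliable"] is None

    def test_quantile_monotone_under_larger_sample(self, rng):
        devs = rng.uniform(0, 0.1, 200)
        p95 = np.percentile(devs, 95)
        p95_after = np.percentile(np.r_[devs, 0.3], 95)
        assert p95_after >= p95


class TestOverallReliability:
    def test_all_twenty_levels_reliable(self):
        rep = overall_reliability(20, 20)
        assert rep.posterior_mode == 1.0
        assert rep.credible_lower_95 == pytest.approx(0.05 ** (1 / 21), abs=1e-12)
        assert round(rep.credible_lower_95, 2) == 0.87
        assert rep.reliable_overall

    def test_seventeen_of_twenty(self):
        rep = overall_reliability(17, 20)
        assert rep.posterior_mode == pytest.approx(0.85)
        assert round(rep.credible_lower_95, 2) == 0.67

    def test_zero_of_one_closed_form(self):
        rep = overall_reliability(0, 1)
        # posterior Beta(1,2): F(q) = 2q - q^2, so q05 = 1 - sqrt(0.95)
        assert rep.credible_lower_95 == pytest.approx(1 - np.sqrt(0.95), abs=1e-12)
        assert rep.posterior_mode == 0.0
        assert rep.reliable_overall  # lower bound still > 0

    def test_quantile_matches_quadrature_oracle(self):
        for k, n in [(20, 20), (17, 20), (3, 7), (0, 4)]:
            rep = overall_reliability(k, n)
            a, b = k + 1, n - k + 1
            cdf, _ = integrate.quad(lambda x: stats.beta.pdf(x, a, b),
                                    0, rep.credible_lower_95)
            assert cdf == pytest.approx(0.05, abs=1e-6)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            overall_reliability(5, 4)
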