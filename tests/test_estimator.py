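"""Recursive Bayesian BSP filter: prediction, Laplace update, full runs."""

import numpy as np
import pytest

from bspctl import (
    BinaryObservation,
    EstimatorConfig,
    GaussianBelief,
    filter_1d,
    filter_2d,
    predict_step,
    update_step,
)
from bspctl.simulate import simulate_closed_loop
from bspctl.transforms import get_transform


def grid_posterior_mode_2d(m, P, n, N, transform="hyperbolic_ratio", pts=401):
    """Independent dense-grid maximizer of the exact unnormalized
    log-posterior, refined once by zooming onto the coarse argmax."""
    tf = get_transform(transform)
    Pi = np.linalg.inv(P)

    def argmax_on(g1, g2):
        Z1, Z2 = np.meshgrid(g1, g2, indexing="ij")
        d1, d2 = Z1 - m[0], Z2 - m[1]
        quad = Pi[0, 0] * d1**2 + 2 * Pi[0, 1] * d1 * d2 + Pi[1, 1] * d2**2
        p = np.clip(tf.forward(np.exp(Z1)), 1e-12, 1 - 1e-12)
        lp = -0.5 * quad + n * np.log(p) + (N - n) * np.log1p(-p)
        i, j = np.unravel_index(np.argmax(lp), lp.shape)
        return np.array([g1[i], g2[j]]), (g1[1] - g1[0], g2[1] - g2[0])

    sd = np.sqrt(np.diag(P))
    mode, (h1, h2) = argmax_on(
        np.linspace(m[0] - 5 * sd[0], m[0] + 5 * sd[0], pts),
        np.linspace(m[1] - 5 * sd[1], m[1] + 5 * sd[1], pts),
    )
    mode, _ = argmax_on(
        np.linspace(mode[0] - 2 * h1, mode[0] + 2 * h1, pts),
        np.linspace(mode[1] - 2 * h2, mode[1] + 2 * h2, pts),
    )
    return mode


def grid_posterior_mode_1d(m, v, n, N, transform="hyperbolic_ratio", pts=4001):
    tf = get_transform(transform)

    def argmax_on(g):
        p = np.clip(tf.forward(np.exp(g)), 1e-12, 1 - 1e-12)
        lp = -0.5 * (g - m) ** 2 / v + n * np.log(p) + (N - n) * np.log1p(-p)
        i = np.argmax(lp)
        return g[i], g[1] - g[0]

    sd = np.sqrt(v)
    mode, h = argmax_on(np.linspace(m - 5 * sd, m + 5 * sd, pts))
    mode, _ = argmax_on(np.linspace(mode - 2 * h, mode + 2 * h, pts))
    return mode


class TestPredictStep:
    def test_noiseless_degenerate_case_reproduces_log_plant(self, dyn):
        cfg = EstimatorConfig(process_noise=np.zeros((2, 2)))
        bel = GaussianBelief(mean=np.log([2.0, 1.5]), cov=np.zeros((2, 2)))
        out = predict_step(bel, 0.7, dyn, cfg)
        x_next = dyn.A @ np.array([2.0, 1.5]) + dyn.B * 0.7
        assert np.allclose(out.mean, np.log(x_next), atol=1e-14)
        assert np.allclose(out.cov, 0.0)

    def test_jacobian_matches_finite_differences(self, dyn):
        cfg = EstimatorConfig()
        m = np.array([0.4, -0.3])
        u = 1.2
        x = np.exp(m)
        x_pred = dyn.A @ x + dyn.B * u
        F = (dyn.A * x[None, :]) / x_pred[:, None]
        h = 1e-7
        for j in range(2):
            e = np.zeros(2)
            e[j] = h
            fd = (np.log(dyn.A @ np.exp(m + e) + dyn.B * u)
                  - np.log(dyn.A @ np.exp(m - e) + dyn.B * u)) / (2 * h)
            assert np.max(np.abs(F[:, j] - fd)) < 1e-6

    def test_monte_carlo_moment_oracle(self, dyn, rng):
        # linearization bias is O(cov), so the sampling check holds only
        # for small belief covariance
        cfg = EstimatorConfig()
        bel = GaussianBelief(mean=np.array([0.3, -0.2]), cov=np.diag([0.002, 0.002]))
        pred = predict_step(bel, 1.0, dyn, cfg)
        z = rng.multivariate_normal(bel.mean, bel.cov, 100_000)
        zn = np.log(np.exp(z) @ dyn.A.T + dyn.B * 1.0)
        se_mean = zn.std(axis=0) / np.sqrt(zn.shape[0])
        assert np.all(np.abs(zn.mean(axis=0) - pred.mean) < 3 * se_mean + 3e-4)
        emp_cov = np.cov(zn.T) + cfg.process_noise
        assert np.max(np.abs(emp_cov - pred.cov)) < 1e-4

    def test_negative_infusion_rejected(self, dyn):
        bel = GaussianBelief(mean=np.zeros(2), cov=np.eye(2))
        with pytest.raises(ValueError):
            predict_step(bel, -1.0, dyn, EstimatorConfig())


class TestUpdateStep:
    def test_vacuous_observation_returns_prediction(self):
        pred = GaussianBelief(mean=np.array([0.1, 0.2]), cov=np.eye(2) * 0.3)
        post = update_step(pred, BinaryObservation(t=0, n=0, N=0))
        assert post is pred

    def test_mode_matches_dense_grid_oracle(self, rng):
        worst = 0.0
        for _ in range(100):
            m = rng.normal(0, 1.5, 2)
            L = rng.normal(0, 0.5, (2, 2))
            P = L @ L.T + np.diag([0.05, 0.05])
            n = int(rng.integers(0, 11))
            pred = GaussianBelief(mean=m, cov=P)
            post = update_step(pred, BinaryObservation(t=0, n=n, N=10))
            mode = grid_posterior_mode_2d(m, P, n, 10)
            worst = max(worst, float(np.max(np.abs(post.mean - mode))))
        assert worst < 1e-3

    def test_likelihood_pulls_estimate_in_count_direction(self):
        # prediction at BSP 0.5 (z1 = log 1 = 0)
        pred = GaussianBelief(mean=np.zeros(2), cov=np.eye(2) * 0.2)
        up = update_step(pred, BinaryObservation(t=0, n=10, N=10))
        down = update_step(pred, BinaryObservation(t=0, n=0, N=10))
        assert up.bsp() > 0.5
        assert down.bsp() < 0.5

    def test_covariance_remains_symmetric_positive_definite(self, rng):
        for _ in range(50):
            L = rng.normal(0, 0.7, (2, 2))
            P = L @ L.T + 0.01 * np.eye(2)
            pred = GaussianBelief(mean=rng.normal(0, 1, 2), cov=P)
            post = update_step(pred, BinaryObservation(t=0, n=int(rng.integers(0, 11)), N=10))
            assert np.allclose(post.cov, post.cov.T, atol=1e-12)
            assert np.all(np.linalg.eigvalsh(post.cov) > 0)

    def test_information_monotonicity_in_count_size(self, rng):
        # N=10 observations constrain z1 at least as much as N=1
        for _ in range(30):
            L = rng.normal(0, 0.5, (2, 2))
            P = L @ L.T + 0.05 * np.eye(2)
            m = rng.normal(0, 1, 2)
            p_pred = float(get_transform().forward(np.exp(m[0])))
            pred = GaussianBelief(mean=m, cov=P)
            n10 = int(round(10 * p_pred))
            n1 = int(round(p_pred))
            v10 = update_step(pred, BinaryObservation(t=0, n=n10, N=10)).cov[0, 0]
            v1 = update_step(pred, BinaryObservation(t=0, n=n1, N=1)).cov[0, 0]
            assert v10 <= v1 + 1e-12


class TestFilter2D:
    def test_tracks_true_bsp_on_model_matched_simulation(self):
        rec = simulate_closed_loop(seed=11)
        assert rec.p_hat.size == 2700  # 45 min at 1 s
        assert np.mean(np.abs(rec.p_hat - rec.p_true)) < 0.05

    def test_causality_under_truncation(self, dyn):
        rng = np.random.default_rng(0)
        obs = [BinaryObservation(t=t, n=int(rng.integers(0, 11)), N=10)
               for t in range(40)]
        u = rng.uniform(0, 2, 40)
        full = filter_2d(obs, u, dyn)
        part = filter_2d(obs[:25], u[:25], dyn)
        for (bf, pf), (bp, pp) in zip(full[:25], part):
            assert pf == pp
            assert np.array_equal(bf.mean, bp.mean)

    def test_no_suppression_and_no_drug_decays_to_zero(self, dyn):
        obs = [BinaryObservation(t=t, n=0, N=10) for t in range(400)]
        out = filter_2d(obs, np.zeros(400), dyn)
        p = [ph for _, ph in out]
        assert p[-1] < 0.02
        assert p[-1] < p[0]

    def test_length_mismatch_rejected(self, dyn):
        obs = [BinaryObservation(t=0, n=5, N=10)]
        with pytest.raises(ValueError):
            filter_2d(obs, np.zeros(2), dyn)


class TestFilter1D:
    def test_constant_probability_stream_converges(self, rng):
        obs = [BinaryObservation(t=t, n=int(rng.binomial(10, 0.7)), N=10)
               for t in range(600)]
        out = filter_1d(obs, process_noise=1e-3)
        assert abs(out[-1][1] - 0.7) < 0.05

    def test_matches_1d_grid_oracle_per_step(self, rng):
        obs = [BinaryObservation(t=t, n=int(rng.binomial(10, 0.6)), N=10)
               for t in range(50)]
        q = 1e-3
        out = filter_1d(obs, process_noise=q)
        # independently recompute each update's mode on a dense grid,
        # starting from the filter's own prediction
        belief_m, belief_v = out[0][0].mean[0], out[0][0].cov[0, 0]
        for o, (bel, _) in zip(obs[1:], out[1:]):
            pred_m, pred_v = belief_m, belief_v + q
            mode = grid_posterior_mode_1d(pred_m, pred_v, o.n, o.N)
            assert abs(bel.mean[0] - mode) < 1e-3
            belief_m, belief_v = bel.mean[0], bel.cov[0, 0]

    def test_small_process_noise_recovers_global_fraction(self, rng):
        obs = [BinaryObservation(t=t, n=int(rng.binomial(10, 0.4)), N=10)
               for t in range(300)]
        out = filter_1d(obs, process_noise=1e-9)
        frac = sum(o.n for o in obs) / (10 * len(obs))
        assert abs(out[-1][1] - frac) < 0.01

    def test_zero_process_noise_rejected(self):
        with pytest.raises(ValueError):
            filter_1d([], process_noise=0.0)
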