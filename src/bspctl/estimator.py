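"""Recursive Bayesian estimation of the burst suppression probability
from binomial suppression counts.

The filter tracks a Gaussian belief over the *logarithm* of the
two-compartment concentration state, z = log x (elementwise), which
guarantees nonnegative concentration estimates.  Each 1-s interval
contributes a binomial observation: the binarized EEG is sub-sampled at
10 Hz, giving a suppression count n out of N = 10 Bernoulli draws with
success probability equal to the BSP.

Prediction propagates the belief through the log-domain plant map

    z' = log(A exp(z) + B u) + w,     w ~ N(0, W),

linearized at the posterior mean (extended-Kalman style), and the
update replaces the exact (non-Gaussian) posterior with its Laplace
approximation: the mode is found by damped Newton iteration on the
log-posterior and the covariance is the inverse negative Hessian at the
mode.  With the default rectangular-hyperbola transform the likelihood
in z1 is exactly the logistic-binomial, so gradients and Hessians are
analytic and the update is numerically benign.

A one-dimensional random-walk special case (`filter_1d`) smooths a raw
binary trace into a BSP signal; it is the first stage of system
identification.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .pk_model import DiscreteDynamics
from .transforms import BSPTransform, get_transform

logger = logging.getLogger(__name__)

__all__ = [
    "GaussianBelief",
    "EstimatorConfig",
    "BinaryObservation",
    "predict_step",
    "update_step",
    "filter_2d",
    "filter_1d",
    "default_init_belief",
]

#: floor applied inside log() to guard against exactly-zero concentrations
LOG_EPS = 1e-12


@dataclass(frozen=True)
class BinaryObservation:
    """Suppression count for one observation interval.

    ``n`` suppressed sub-samples out of ``N`` (default 10 per 1-s
    interval at a 10 Hz sub-sampling rate).
    """

    t: int
    n: int
    N: int = 10

    def __post_init__(self):
        if not (0 <= self.n <= self.N):
            raise ValueError(f"count n={self.n} outside [0, N={self.N}]")


@dataclass
class GaussianBelief:
    """Gaussian belief over the log-concentration state.

    ``mean`` is z = log x (length 1 or 2), ``cov`` the matching
    symmetric positive-semidefinite covariance.
    """

    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self):
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=float))
        self.cov = np.atleast_2d(np.asarray(self.cov, dtype=float))
        k = self.mean.shape[0]
        if self.cov.shape != (k, k):
            raise ValueError("covariance shape does not match mean")
        if not np.all(np.isfinite(self.mean)) or not np.all(np.isfinite(self.cov)):
            raise ValueError("belief must be finite")
        if not np.allclose(self.cov, self.cov.T, atol=1e-12):
            raise ValueError("covariance must be symmetric")

    @property
    def dim(self) -> int:
        return self.mean.shape[0]

    def conc_mean(self) -> np.ndarray:
        """Point estimate of the concentration state, exp(mean)."""
        return np.exp(self.mean)

    def bsp(self, transform="hyperbolic_ratio") -> float:
        """Point BSP estimate from the effect-site component."""
        return float(get_transform(transform).forward(np.exp(self.mean[0])))


@dataclass
class EstimatorConfig:
    """Tuning knobs for the 2-D filter.

    ``process_noise`` (W) is the per-step covariance of the log-state
    innovation; the default diag(1e-4, 1e-4) per 1-s step admits slow
    drift of the concentrations relative to the deterministic model.
    """

    process_noise: np.ndarray = field(default_factory=lambda: np.diag([1e-4, 1e-4]))
    init_belief: GaussianBelief | None = None
    newton_tol: float = 1e-10
    newton_max_iter: int = 50

    def __post_init__(self):
        W = np.atleast_2d(np.asarray(self.process_noise, dtype=float))
        if not np.allclose(W, W.T) or np.any(np.linalg.eigvalsh(W) < -1e-12):
            raise ValueError("process noise must be symmetric PSD")
        self.process_noise = W
        if self.newton_tol <= 0:
            raise ValueError("newton_tol must be positive")


def default_init_belief(first_fraction: float, transform="hyperbolic_ratio") -> GaussianBelief:
    """Diffuse starting belief anchored at the first-interval suppression
    fraction (floored to 0.05 so the log is finite), with both
    compartments initialized equal and unit log-variance."""
    p0 = max(float(first_fraction), 0.05)
    z0 = float(np.log(get_transform(transform).inverse(min(p0, 0.99))))
    return GaussianBelief(mean=np.array([z0, z0]), cov=np.eye(2))


def predict_step(
    belief: GaussianBelief,
    u: float,
    dyn: DiscreteDynamics,
    cfg: EstimatorConfig,
) -> GaussianBelief:
    """Propagate the belief one step through the log-domain plant.

    mean' = log(A exp(mean) + B u); cov' = F cov F^T + W with
    F = diag(1/x_pred) A diag(exp(mean)), the Jacobian of
    z -> log(A e^z + B u) at the posterior mean.
    """
    if u < 0:
        raise ValueError("infusion rate must be nonnegative")
    x = np.exp(belief.mean)
    x_pred = dyn.A @ x + dyn.B * u
    if np.any(x_pred < LOG_EPS):
        logger.debug("predicted concentration floored at %g", LOG_EPS)
        x_pred = np.maximum(x_pred, LOG_EPS)
    F = (dyn.A * x[None, :]) / x_pred[:, None]
    cov = F @ belief.cov @ F.T + cfg.process_noise
    cov = 0.5 * (cov + cov.T)
    return GaussianBelief(mean=np.log(x_pred), cov=cov)


# ---------------------------------------------------------------------------
# Laplace update
# ---------------------------------------------------------------------------

def _loglik_terms(z1: float, n: int, N: int, tf: BSPTransform):
    """Binomial log-likelihood in z1 = log x_e and its first two
    derivatives, differentiated through p = tf(exp(z1))."""
    x = np.exp(z1)
    p = float(tf.forward(x))
    p = min(max(p, 1e-12), 1 - 1e-12)
    dp_dx = float(tf.d1(x))
    d2p_dx2 = float(tf.d2(x))
    # chain rule in z: dp/dz = p'(x) x ; d2p/dz2 = p''(x) x^2 + p'(x) x
    dp = dp_dx * x
    d2p = d2p_dx2 * x * x + dp_dx * x
    ll = n * np.log(p) + (N - n) * np.log1p(-p)
    g_p = n / p - (N - n) / (1.0 - p)
    h_p = -n / p**2 - (N - n) / (1.0 - p) ** 2
    grad = g_p * dp
    hess = h_p * dp * dp + g_p * d2p
    return ll, grad, hess


def update_step(
    pred: GaussianBelief,
    obs: BinaryObservation,
    transform="hyperbolic_ratio",
    newton_tol: float = 1e-10,
    newton_max_iter: int = 50,
) -> GaussianBelief:
    """Laplace-approximate the posterior given a binomial count.

    The posterior is proportional to N(z; pred) x Binomial(n; N,
    p(exp(z1))).  Its mode is located by damped Newton iteration with
    analytic gradient and Hessian; the returned covariance is the
    inverse of the negative log-posterior Hessian at the mode.  An
    observation with N = 0 carries no information and returns the
    prediction unchanged, as does (after a warning) a non-convergent or
    non-concave update.
    """
    if obs.N == 0:
        return pred
    tf = get_transform(transform)
    P = pred.cov
    try:
        Pinv = np.linalg.inv(P)
    except np.linalg.LinAlgError:
        Pinv = np.linalg.pinv(P)
    m = pred.mean
    k = pred.dim

    def objective(z):
        d = z - m
        ll, g1, h1 = _loglik_terms(z[0], obs.n, obs.N, tf)
        val = -0.5 * d @ Pinv @ d + ll
        grad = -Pinv @ d
        grad[0] += g1
        H = -Pinv.copy()
        H[0, 0] += h1
        return val, grad, H

    z = m.copy()
    val, grad, H = objective(z)
    converged = False
    for _ in range(newton_max_iter):
        try:
            step = np.linalg.solve(-H, grad)
        except np.linalg.LinAlgError:
            break
        if not np.all(np.isfinite(step)):
            break
        # damped: backtrack until the log-posterior does not decrease
        alpha = 1.0
        for _ in range(30):
            z_new = z + alpha * step
            val_new, grad_new, H_new = objective(z_new)
            if val_new >= val - 1e-15:
                break
            alpha *= 0.5
        moved = float(np.max(np.abs(z_new - z)))
        z, val, grad, H = z_new, val_new, grad_new, H_new
        if moved < newton_tol:
            converged = True
            break
    if not converged and float(np.max(np.abs(grad))) > 1e-6:
        warnings.warn(
            "Laplace update did not converge; falling back to the prediction "
            "with inflated covariance",
            RuntimeWarning,
        )
        return GaussianBelief(mean=m, cov=2.0 * P)
    negH = -H
    eig = np.linalg.eigvalsh(0.5 * (negH + negH.T))
    if np.any(eig <= 0):
        warnings.warn(
            "non-positive-definite Hessian at the mode; falling back to the "
            "prediction with inflated covariance",
            RuntimeWarning,
        )
        return GaussianBelief(mean=m, cov=2.0 * P)
    cov = np.linalg.inv(negH)
    cov = 0.5 * (cov + cov.T)
    return GaussianBelief(mean=z, cov=cov)


# ---------------------------------------------------------------------------
# Full filters
# ---------------------------------------------------------------------------

def filter_2d(
    observations,
    infusions,
    dyn: DiscreteDynamics,
    cfg: EstimatorConfig | None = None,
):
    """Run the 2-D predict/update recursion over aligned observation and
    infusion streams (one of each per interval).

    ``infusions[t]`` is the rate applied during the step leading into
    interval ``t``.  Returns a list of (GaussianBelief, bsp_estimate)
    pairs; the output at index t depends only on inputs up to t, so the
    filter is usable online.
    """
    observations = list(observations)
    infusions = np.asarray(infusions, dtype=float)
    if len(observations) != len(infusions):
        raise ValueError(
            f"length mismatch: {len(observations)} observations vs "
            f"{len(infusions)} infusions"
        )
    cfg = cfg or EstimatorConfig()
    tf_name = dyn.transform_name
    if cfg.init_belief is not None:
        belief = cfg.init_belief
    else:
        first_frac = observations[0].n / max(observations[0].N, 1) if observations else 0.05
        belief = default_init_belief(first_frac, tf_name)
    out = []
    for obs, u in zip(observations, infusions):
        belief = predict_step(belief, float(u), dyn, cfg)
        belief = update_step(
            belief, obs, tf_name, cfg.newton_tol, cfg.newton_max_iter
        )
        out.append((belief, belief.bsp(tf_name)))
    return out


def filter_1d(
    observations,
    process_noise: float = 1e-3,
    transform="hyperbolic_ratio",
    init_belief: GaussianBelief | None = None,
    newton_tol: float = 1e-10,
    newton_max_iter: int = 50,
):
    """Scalar random-walk special case: z_{t+1} = z_t + w, w ~ N(0, q).

    Smooths a binomial count stream into a BSP trace without a plant
    model; the smoothness is set by the scalar ``process_noise``.  Used
    as the target-trace estimator in system identification.
    """
    if process_noise <= 0:
        raise ValueError("process noise must be positive")
    observations = list(observations)
    tf = get_transform(transform)
    if init_belief is None:
        first_frac = observations[0].n / max(observations[0].N, 1) if observations else 0.05
        p0 = max(first_frac, 0.05)
        z0 = float(np.log(tf.inverse(min(p0, 0.99))))
        belief = GaussianBelief(mean=np.array([z0]), cov=np.array([[1.0]]))
    else:
        belief = init_belief
    out = []
    for obs in observations:
        belief = GaussianBelief(
            mean=belief.mean, cov=belief.cov + process_noise
        )
        belief = update_step(belief, obs, transform, newton_tol, newton_max_iter)
        out.append((belief, belief.bsp(transform)))
    return out
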