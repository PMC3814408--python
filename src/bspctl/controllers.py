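"""Infusion-rate controllers: steady-state LQR with origin shift and
clipping, and receding-horizon MPC with explicit input constraints.

Both controllers regulate the concentration state around the
equilibrium (x*, u*) that sustains the target BSP, minimizing the
quadratic cost

    sum_k (x_k - x*)' Q (x_k - x*) + R (u_k - u*)^2 .

The LQR gain comes from the discrete algebraic Riccati equation solved
by value iteration; constraints are imposed afterwards by clipping the
unconstrained solution to [u_min, u_max] (if the solution is negative,
use zero).  The MPC solves the constrained horizon-T quadratic program
at every step and applies only the first control, which respects bounds
*during* the whole predicted trajectory rather than only at the current
step.  With box constraints on u only, the condensed QP is a bounded
least-squares problem solved exactly (BVLS); optional state bounds
switch to an SLSQP solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import lsq_linear, minimize

from .pk_model import DiscreteDynamics, SetPoint

__all__ = [
    "LQRConfig",
    "LQRGain",
    "MPCConfig",
    "solve_dare",
    "lqr_infusion",
    "mpc_infusion",
    "finite_horizon_gains",
]


@dataclass
class LQRConfig:
    """Quadratic cost weights and input bounds.

    Q defaults to diag(1, 0): only the effect-site concentration (the
    EEG-observable state) is penalized.  R trades infusion effort
    against speed of response — smaller R gives a faster controller.
    The default R = 1 is calibrated so the reference-rat closed loop
    makes upward target transitions in under a minute with no
    overshoot; R only has meaning relative to the identified input gain
    b_in, so re-tune it when using fitted parameters.
    """

    Q: np.ndarray = field(default_factory=lambda: np.diag([1.0, 0.0]))
    R: float = 1.0
    u_min: float = 0.0
    u_max: float = np.inf

    def __post_init__(self):
        Q = np.atleast_2d(np.asarray(self.Q, dtype=float))
        if not np.allclose(Q, Q.T) or np.any(np.linalg.eigvalsh(Q) < -1e-12):
            raise ValueError("Q must be symmetric PSD")
        self.Q = Q
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.u_min > self.u_max:
            raise ValueError("u_min exceeds u_max")


@dataclass(frozen=True)
class LQRGain:
    """Steady-state Riccati solution S and feedback row L (u = -L x)."""

    S: np.ndarray
    L: np.ndarray


@dataclass
class MPCConfig:
    """Receding-horizon settings.

    ``horizon_T`` is the number of lookahead steps (seconds at the
    default 1-s cadence); ``terminal_cost`` adds x_T' S x_T with the
    Riccati S, making short horizons behave like the infinite-horizon
    controller.  ``state_bounds`` is an optional (lower, upper) pair of
    length-2 arrays constraining every predicted state.
    """

    horizon_T: int = 30
    u_min: float = 0.0
    u_max: float = np.inf
    state_bounds: tuple | None = None
    terminal_cost: bool = False

    def __post_init__(self):
        if self.horizon_T < 1:
            raise ValueError("horizon must be at least 1 step")
        if self.u_min > self.u_max:
            raise ValueError("u_min exceeds u_max")


def solve_dare(dyn: DiscreteDynamics, cfg: LQRConfig, tol: float = 1e-12,
               max_iter: int = 1_000_000) -> LQRGain:
    """Solve the discrete algebraic Riccati equation by value iteration.

    Iterates S <- Q + A'SA - A'SB (R + B'SB)^{-1} B'SA from S = Q until
    the update is below ``tol``; the steady-state feedback row is
    L = (R + B'SB)^{-1} B'SA.  Requires (A, B) controllable.  Accepts a
    DiscreteDynamics or a raw ``(A, B)`` pair.
    """
    from .pk_model import DiscreteDynamics as _DD
    from .pk_model import controllability_check

    ok, rank = controllability_check(dyn)
    if not ok:
        raise ValueError(
            f"(A, B) not controllable: the controllability matrix has "
            f"rank {rank}"
        )
    if isinstance(dyn, _DD):
        A, B = dyn.A, dyn.B
    else:
        A, B = dyn
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.asarray(B, dtype=float).reshape(A.shape[0], 1)
    Q, R = np.atleast_2d(np.asarray(cfg.Q, dtype=float)), float(cfg.R)
    if Q.shape != A.shape:
        Q = np.eye(A.shape[0]) * Q.ravel()[0] if Q.size == 1 else Q
    Q = Q[: A.shape[0], : A.shape[0]]
    S = Q.copy()
    for _ in range(max_iter):
        BtSA = B.T @ S @ A
        S_new = Q + A.T @ S @ A - A.T @ S @ B @ BtSA / (R + (B.T @ S @ B).item())
        S_new = 0.5 * (S_new + S_new.T)
        if np.max(np.abs(S_new - S)) < tol:
            S = S_new
            break
        S = S_new
    else:
        raise RuntimeError("Riccati value iteration did not converge")
    L = (B.T @ S @ A) / (R + (B.T @ S @ B).item())
    return LQRGain(S=S, L=L.reshape(-1))


def finite_horizon_gains(dyn: DiscreteDynamics, cfg: LQRConfig, T: int,
                         terminal: np.ndarray | None = None):
    """Backward Riccati recursion over T steps; returns the list of
    feedback rows [L_0, ..., L_{T-1}] and the value matrices.  Terminal
    cost defaults to Q (the cost on the final predicted state)."""
    A, B = dyn.A, dyn.B.reshape(2, 1)
    Q, R = cfg.Q, float(cfg.R)
    S = Q.copy() if terminal is None else np.asarray(terminal, dtype=float)
    gains, values = [], [S]
    for _ in range(T):
        denom = R + (B.T @ S @ B).item()
        L = (B.T @ S @ A) / denom
        S = Q + A.T @ S @ (A - B @ L)
        S = 0.5 * (S + S.T)
        gains.append(L.reshape(2))
        values.append(S)
    gains.reverse()
    values.reverse()
    return gains, values


def lqr_infusion(x_hat, setpoint: SetPoint, gain: LQRGain, cfg: LQRConfig) -> float:
    """Bounded certainty-equivalence LQR law.

    u = clip(u* - L (x_hat - x*), [u_min, u_max]) with ``x_hat`` the
    concentration estimate (exp of the filter's log-state mean).
    """
    x_hat = np.asarray(x_hat, dtype=float).reshape(2)
    u = setpoint.u_star - (gain.L @ (x_hat - setpoint.x_star)).item()
    return float(np.clip(u, cfg.u_min, cfg.u_max))


from functools import lru_cache


@lru_cache(maxsize=32)
def _condensed_cached(A_bytes: bytes, B_bytes: bytes, T: int):
    A = np.frombuffer(A_bytes).reshape(2, 2)
    B = np.frombuffer(B_bytes)
    Phi = np.zeros((2 * T, 2))
    Gamma = np.zeros((2 * T, T))
    Ak = np.eye(2)
    powers = [Ak]
    for _ in range(T):
        Ak = A @ Ak
        powers.append(Ak)
    for k in range(1, T + 1):
        Phi[2 * (k - 1): 2 * k, :] = powers[k]
        for j in range(k):
            Gamma[2 * (k - 1): 2 * k, j] = powers[k - 1 - j] @ B
    return Phi, Gamma


@lru_cache(maxsize=32)
def _pinv_cached(A_ls_bytes: bytes, shape: tuple):
    A_ls = np.frombuffer(A_ls_bytes).reshape(shape)
    return np.linalg.pinv(A_ls)


def mpc_infusion(
    x_hat,
    setpoints,
    dyn: DiscreteDynamics,
    mpc_cfg: MPCConfig,
    lqr_cfg: LQRConfig,
    return_plan: bool = False,
):
    """Receding-horizon constrained control: solve the horizon-T QP and
    return the first infusion rate.

    ``setpoints`` is either a single SetPoint (held over the horizon) or
    a sequence of T SetPoints giving the target trajectory.  Stage cost
    is (x_k - x*_k)' Q (x_k - x*_k) + R (u_k - u*_k)^2 over k = 1..T
    (controls k = 0..T-1), with an optional Riccati terminal cost.  Box
    constraints on u are always honored; optional per-component state
    bounds raise on infeasibility.
    """
    T = mpc_cfg.horizon_T
    if mpc_cfg.u_min == mpc_cfg.u_max:  # degenerate constraint set
        return (float(mpc_cfg.u_min), np.full(T, float(mpc_cfg.u_min))) \
            if return_plan else float(mpc_cfg.u_min)
    x0 = np.asarray(x_hat, dtype=float).reshape(2)
    if isinstance(setpoints, SetPoint):
        sp_list = [setpoints] * T
    else:
        sp_list = list(setpoints)
        if len(sp_list) < T:
            sp_list = sp_list + [sp_list[-1]] * (T - len(sp_list))
        sp_list = sp_list[:T]

    Q, R = lqr_cfg.Q, float(lqr_cfg.R)
    Phi, Gamma = _condensed_cached(dyn.A.tobytes(), dyn.B.tobytes(), T)
    x_ref = np.concatenate([sp.x_star for sp in sp_list])
    u_ref = np.array([sp.u_star for sp in sp_list])

    # Weighted least-squares form: rows sqrt(Q)-weighted state residuals
    # for k=1..T, then sqrt(R)-weighted control residuals.
    Qw = np.linalg.cholesky(Q + 1e-15 * np.eye(2))  # Q is PSD; jitter for rank
    Wstack = np.kron(np.eye(T), Qw.T)  # (2T x 2T), rows weight each state
    if mpc_cfg.terminal_cost:
        from numpy.linalg import cholesky

        S = solve_dare(dyn, lqr_cfg).S
        # replace the final stage weight Q with Q + S (terminal value)
        Sw = cholesky(Q + S + 1e-15 * np.eye(2))
        Wstack[-2:, -2:] = Sw.T
    A_ls_top = Wstack @ Gamma
    b_ls_top = Wstack @ (x_ref - Phi @ x0)
    A_ls_bot = np.sqrt(R) * np.eye(T)
    b_ls_bot = np.sqrt(R) * u_ref
    A_ls = np.vstack([A_ls_top, A_ls_bot])
    b_ls = np.concatenate([b_ls_top, b_ls_bot])

    lo = np.full(T, mpc_cfg.u_min)
    hi = np.full(T, mpc_cfg.u_max)

    if mpc_cfg.state_bounds is None:
        # Try the unconstrained minimizer first; if it already satisfies the
        # box it is the constrained optimum too.
        pinv = _pinv_cached(A_ls.tobytes(), A_ls.shape)
        u_unc = pinv @ b_ls
        if np.all(u_unc >= lo - 1e-12) and np.all(u_unc <= hi + 1e-12):
            u_opt = np.clip(u_unc, lo, hi)
        else:
            res = lsq_linear(A_ls, b_ls, bounds=(lo, hi), method="bvls")
            if not res.success and res.status <= 0:
                raise RuntimeError(f"MPC solver failed: {res.message}")
            u_opt = res.x
    else:
        s_lo, s_hi = mpc_cfg.state_bounds
        s_lo = np.tile(np.asarray(s_lo, dtype=float), T)
        s_hi = np.tile(np.asarray(s_hi, dtype=float), T)

        def cost(u):
            r = A_ls @ u - b_ls
            return float(r @ r)

        def jac(u):
            return 2.0 * A_ls.T @ (A_ls @ u - b_ls)

        cons = [
            {"type": "ineq", "fun": lambda u: Phi @ x0 + Gamma @ u - s_lo},
            {"type": "ineq", "fun": lambda u: s_hi - (Phi @ x0 + Gamma @ u)},
        ]
        u0 = np.clip(u_ref, lo, hi)
        res = minimize(
            cost, u0, jac=jac, bounds=list(zip(lo, hi)), constraints=cons,
            method="SLSQP", options={"maxiter": 500, "ftol": 1e-12},
        )
        if not res.success:
            states = (Phi @ x0 + Gamma @ np.clip(res.x, lo, hi))
            viol_lo = np.where(states < s_lo - 1e-8)[0]
            viol_hi = np.where(states > s_hi + 1e-8)[0]
            binding = "lower state bound" if viol_lo.size else (
                "upper state bound" if viol_hi.size else "input bound")
            raise RuntimeError(
                f"MPC QP infeasible or solver failed ({res.message}); "
                f"binding constraint: {binding}"
            )
        u_opt = res.x
    if return_plan:
        return float(u_opt[0]), u_opt
    return float(u_opt[0])
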