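"""In-silico plant and closed-loop experiment runner.

Simulates the full loop at a 1-s cadence: the two-compartment plant is
stepped with the previous infusion rate, a binomial suppression count
n ~ Binomial(N=10, p_true) emulates the segmented EEG, the Bayesian
estimator updates its belief, and the controller (bounded LQR or MPC)
emits the next infusion rate.  All randomness derives from a single
seed fanned out to named child streams, so records are bit-reproducible.

Also provides the simulation protocol generator (permutations of the
0.4 / 0.7 / 0.9 target levels, 15 minutes each) and a surrogate raw-EEG
generator for exercising the segmentation stage end to end.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import controllers as ctrl
from . import estimator as est
from .pk_model import (
    DiscreteDynamics,
    PKParams,
    SetPoint,
    discretize,
    plant_step,
    steady_state_setpoint,
)
from .segmentation import EEGRecord

__all__ = [
    "TargetSchedule",
    "SimulationRecord",
    "generate_target_protocol",
    "simulate_closed_loop",
    "generate_surrogate_eeg",
    "REFERENCE_RAT",
]

#: Documented "reference rat" two-compartment parameters used by the
#: simulator by default.  Chosen to reproduce the observable dynamics of
#: rodent propofol burst suppression: a bolus drives the BSP to its peak
#: in about a minute and it decays back over several minutes (continuous
#: eigenvalues ~0.5/min and ~2.5/min), an uncontrolled drop from BSP 0.9
#: reaches the 0.4 band in ~5 minutes, and the equilibrium infusion at
#: BSP 0.9 is ~2 mg/min (just under a 2.4 mg/min pump cap).
REFERENCE_RAT = PKParams(k10=0.90, k12=0.70, k21=1.40, b_in=8.0, dt=1.0)


@dataclass(frozen=True)
class TargetSchedule:
    """Piecewise-constant BSP target: level ``levels[i]`` holds from
    ``breakpoints[i]`` (seconds) until the next breakpoint."""

    breakpoints: tuple
    levels: tuple

    def __post_init__(self):
        bp = tuple(float(b) for b in self.breakpoints)
        lv = tuple(float(p) for p in self.levels)
        if len(bp) != len(lv) or not bp:
            raise ValueError("breakpoints and levels must align and be nonempty")
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ValueError("breakpoints must be strictly increasing")
        if any(not (0 < p < 1) for p in lv):
            raise ValueError("target levels must lie in (0, 1)")
        object.__setattr__(self, "breakpoints", bp)
        object.__setattr__(self, "levels", lv)

    def target_at(self, t: float) -> float:
        """Target BSP in force at time t (seconds)."""
        idx = int(np.searchsorted(self.breakpoints, t, side="right")) - 1
        return self.levels[max(idx, 0)]

    def duration_hint(self, minutes_per_level: float | None = None) -> float:
        if len(self.breakpoints) >= 2:
            seg = self.breakpoints[-1] - self.breakpoints[-2]
        else:
            seg = 900.0
        return self.breakpoints[-1] + seg

    def to_dict(self) -> dict:
        return {"breakpoints": list(self.breakpoints), "levels": list(self.levels)}

    @classmethod
    def from_dict(cls, d: dict) -> "TargetSchedule":
        return cls(tuple(d["breakpoints"]), tuple(d["levels"]))


def generate_target_protocol(
    levels=(0.4, 0.7, 0.9),
    minutes_per_level: float = 15.0,
    permutation: int = 0,
) -> TargetSchedule:
    """The k-level step protocol, one of the k! orderings.

    Default is the 45-minute three-level protocol (0.4, 0.7, 0.9 for 15
    minutes each); ``permutation`` indexes the lexicographic enumeration
    of orderings, 0 .. k!-1.
    """
    levels = tuple(levels)
    perms = list(itertools.permutations(levels))
    if not (0 <= permutation < len(perms)):
        raise IndexError(
            f"permutation index {permutation} outside [0, {len(perms) - 1}]"
        )
    ordered = perms[permutation]
    seg = minutes_per_level * 60.0
    return TargetSchedule(
        breakpoints=tuple(i * seg for i in range(len(ordered))),
        levels=ordered,
    )


@dataclass
class SimulationRecord:
    """Complete per-step log of one closed-loop run (1-s cadence)."""

    time: np.ndarray
    x_true: np.ndarray          # (T, 2) true concentration states
    p_true: np.ndarray          # true BSP
    counts: np.ndarray          # (T,) binomial suppression counts
    N: int
    p_hat: np.ndarray           # estimated BSP
    z_mean: np.ndarray          # (T, 2) posterior log-state means
    z_var: np.ndarray           # (T, 3) var11, var22, cov12
    p_target: np.ndarray
    infusion: np.ndarray        # rate applied during [t, t+1)
    controller: str
    seed: int | None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_s": self.time,
                "x_e_true": self.x_true[:, 0],
                "x_c_true": self.x_true[:, 1],
                "p_true": self.p_true,
                "N": self.N,
                "n": self.counts,
                "p_hat": self.p_hat,
                "z1_mean": self.z_mean[:, 0],
                "z2_mean": self.z_mean[:, 1],
                "var11": self.z_var[:, 0],
                "var22": self.z_var[:, 1],
                "cov12": self.z_var[:, 2],
                "p_target": self.p_target,
                "infusion_mg_min": self.infusion,
            }
        )


def _initial_state(params: PKParams, dyn: DiscreteDynamics, p0: float) -> np.ndarray:
    """State at BSP p0 with the compartments in their equilibrium ratio
    (x_c = (k21/k12) x_e) — the condition at which control starts after
    the induction bolus has partially washed out."""
    tf = dyn.get_transform()
    xe = float(tf.inverse(p0))
    return np.array([xe, xe * params.k21 / params.k12])


def initial_belief(params: PKParams, init_bsp: float = 0.2) -> est.GaussianBelief:
    """Filter starting belief used by the closed-loop runner: mean at the
    log of the init-BSP state (compartments in equilibrium ratio), unit
    log-covariance.  Exposed so offline replay can reproduce a run's
    estimates exactly."""
    dyn = discretize(params)
    x0 = _initial_state(params, dyn, init_bsp)
    return est.GaussianBelief(mean=np.log(np.maximum(x0, est.LOG_EPS)), cov=np.eye(2))


def simulate_closed_loop(
    params: PKParams = REFERENCE_RAT,
    schedule: TargetSchedule | None = None,
    controller: str = "lqr",
    lqr_cfg: ctrl.LQRConfig | None = None,
    mpc_cfg: ctrl.MPCConfig | None = None,
    est_cfg: est.EstimatorConfig | None = None,
    seed: int | None = 0,
    duration_s: float | None = None,
    N: int = 10,
    init_bsp: float = 0.2,
    feedback: str = "estimator",
) -> SimulationRecord:
    """Run one closed-loop trial.

    Per 1-s step: advance the plant with the previous infusion rate,
    draw the suppression count n ~ Binomial(N, p_true) (BSP taken at
    the interval start), run the filter's predict/update, and let the
    controller pick the next rate from the concentration estimate and
    the current target's equilibrium.

    ``feedback='true_state'`` bypasses the estimator and feeds the
    controller the exact plant state (the configuration used to compare
    controllers in isolation); ``seed=None`` with true-state feedback
    gives the fully noiseless loop.
    """
    if schedule is None:
        schedule = generate_target_protocol()
    dyn = discretize(params)
    lqr_cfg = lqr_cfg or ctrl.LQRConfig()
    est_cfg = est_cfg or est.EstimatorConfig()
    if controller not in ("lqr", "mpc", "none"):
        raise ValueError(f"unknown controller {controller!r}")
    if controller == "mpc":
        mpc_cfg = mpc_cfg or ctrl.MPCConfig(u_min=lqr_cfg.u_min, u_max=lqr_cfg.u_max)
    gain = ctrl.solve_dare(dyn, lqr_cfg)
    tf = dyn.get_transform()

    if duration_s is None:
        duration_s = schedule.duration_hint()
    steps = int(round(duration_s / params.dt))
    dt = params.dt

    rng = np.random.default_rng(seed) if seed is not None else None
    obs_rng = rng.spawn(1)[0] if rng is not None else None

    # cache one setpoint per distinct target level
    sp_cache: dict[float, SetPoint] = {}

    def setpoint_for(p: float) -> SetPoint:
        if p not in sp_cache:
            sp_cache[p] = steady_state_setpoint(dyn, p)
        return sp_cache[p]

    x = _initial_state(params, dyn, init_bsp)
    belief = initial_belief(params, init_bsp)

    T = steps
    rec = SimulationRecord(
        time=np.arange(T) * dt,
        x_true=np.zeros((T, 2)),
        p_true=np.zeros(T),
        counts=np.zeros(T, dtype=int),
        N=N,
        p_hat=np.zeros(T),
        z_mean=np.zeros((T, 2)),
        z_var=np.zeros((T, 3)),
        p_target=np.zeros(T),
        infusion=np.zeros(T),
        controller=controller,
        seed=seed,
    )

    u_prev = 0.0
    for t in range(T):
        if t > 0:
            try:
                x = plant_step(x, u_prev, dyn)
            except ValueError as e:  # pragma: no cover - defensive
                raise RuntimeError(f"plant failure at step {t}: {e}") from e
        p_true = float(tf.forward(x[0]))
        if obs_rng is not None:
            n = int(obs_rng.binomial(N, p_true))
        else:
            n = int(round(N * p_true))
        obs = est.BinaryObservation(t=t, n=n, N=N)

        try:
            belief = est.predict_step(belief, u_prev, dyn, est_cfg)
            belief = est.update_step(
                belief, obs, dyn.transform_name,
                est_cfg.newton_tol, est_cfg.newton_max_iter,
            )
        except Exception as e:
            raise RuntimeError(f"estimator failure at step {t}: {e}") from e

        p_target = schedule.target_at(t * dt)
        sp = setpoint_for(p_target)
        x_fb = x if feedback == "true_state" else belief.conc_mean()
        try:
            if controller == "none":
                u = 0.0
            elif controller == "lqr":
                u = ctrl.lqr_infusion(x_fb, sp, gain, lqr_cfg)
            else:
                # current target held over the horizon: the controller does
                # not anticipate future target changes, mirroring the LQR
                u = ctrl.mpc_infusion(x_fb, sp, dyn, mpc_cfg, lqr_cfg)
                u = float(np.clip(u, mpc_cfg.u_min, mpc_cfg.u_max))
        except Exception as e:
            raise RuntimeError(f"controller failure at step {t}: {e}") from e

        rec.x_true[t] = x
        rec.p_true[t] = p_true
        rec.counts[t] = n
        rec.p_hat[t] = belief.bsp(dyn.transform_name)
        rec.z_mean[t] = belief.mean
        rec.z_var[t] = (belief.cov[0, 0], belief.cov[1, 1], belief.cov[0, 1])
        rec.p_target[t] = p_target
        rec.infusion[t] = u
        u_prev = u
    return rec


def generate_surrogate_eeg(
    bsp_trace,
    fs: float = 500.0,
    seed: int = 0,
    burst_amp_uv: float = 50.0,
    suppression_amp_uv: float = 2.0,
    subrate_hz: float = 10.0,
    persistence: float = 0.8,
):
    """Synthetic raw-EEG fixture with exact burst/suppression labels.

    For each sub-interval (1/subrate_hz seconds) the suppressed state is
    drawn Bernoulli(p_t) from the supplied BSP trace (one value per
    second).  ``persistence`` is the probability of carrying the
    previous sub-interval's state forward instead of redrawing — for a
    constant trace the marginal stays exactly Bernoulli(p) but dwell
    times stretch by
    1/(1 - persistence), emulating the seconds-long bursts and
    suppressions of real burst-suppression EEG (0 gives independent
    draws).  Bursts are band-limited Gaussian noise at ``burst_amp_uv``
    RMS; suppressions are low-amplitude noise at ``suppression_amp_uv``
    RMS.  Returns (EEGRecord, labels) where labels mark each raw sample
    1 = suppressed.  This is a stand-in signal for exercising the
    segmentation stage, not a biophysical EEG model.
    """
    from scipy.signal import butter, filtfilt

    bsp_trace = np.asarray(bsp_trace, dtype=float)
    if np.any(bsp_trace < 0) or np.any(bsp_trace > 1):
        raise ValueError("BSP trace must lie in [0, 1]")
    if not (0 <= persistence < 1):
        raise ValueError("persistence must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    sub_len = int(round(fs / subrate_hz))
    n_sub_per_s = int(round(subrate_hz))
    states = []
    prev = None
    for p in bsp_trace:
        for _ in range(n_sub_per_s):
            if prev is not None and rng.random() < persistence:
                s = prev
            else:
                s = bool(rng.random() < p)
            states.append(s)
            prev = s
    states = np.asarray(states, dtype=bool)
    labels = np.repeat(states.astype(np.int8), sub_len)
    total = labels.size
    # band-limited (1-30 Hz) noise carrier, scaled per-state
    white = rng.standard_normal(total)
    b, a = butter(2, [1.0, min(30.0, 0.45 * fs)], btype="band", fs=fs)
    carrier = filtfilt(b, a, white)
    carrier /= np.std(carrier)
    amp = np.where(labels == 1, suppression_amp_uv, burst_amp_uv)
    samples = carrier * amp
    return EEGRecord(samples=samples, fs=fs), labels
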