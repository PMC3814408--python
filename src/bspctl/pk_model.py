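"""Two-compartment pharmacokinetic model of anesthetic-induced burst
suppression.

The drug (e.g. propofol) enters and is eliminated through the central
(plasma) compartment and exchanges with the effect-site (brain)
compartment, whose concentration drives the EEG burst suppression
probability through a monotone hyperbolic transform.

State ordering is ``x = (x_e, x_c)`` — effect site first — throughout
the package.  With rates in 1/min the continuous-time dynamics are::

    dx_e/dt = -k21 * x_e + k12 * x_c
    dx_c/dt =  k21 * x_e - (k10 + k12) * x_c + b_in * u(t)

where ``u`` is the infusion rate in mg/min and ``b_in`` maps infusion to
central-concentration rate.  Concentration units are dimensionless
(absorbed into ``b_in``): only the transform-mapped BSP is observable,
so ``b_in`` is an identified parameter rather than a physical constant.

Discretization is the exact zero-order-hold (matrix-exponential) map
over the control interval ``dt`` (seconds; default 1 s, the cadence at
which the closed-loop system updates its BSP estimate and infusion
rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

from .transforms import BSPTransform, get_transform

__all__ = [
    "PKParams",
    "DiscreteDynamics",
    "SetPoint",
    "discretize",
    "bsp_from_conc",
    "conc_from_bsp",
    "steady_state_setpoint",
    "controllability_check",
    "plant_step",
]


@dataclass(frozen=True)
class PKParams:
    """Continuous-time two-compartment model parameters.

    Parameters
    ----------
    k10 : float
        Elimination rate from the central compartment (1/min).
    k12 : float
        Central -> effect-site transfer rate (1/min).  Must be positive
        for the discretized pair (A, B) to be controllable.
    k21 : float
        Effect-site -> central transfer rate (1/min).
    b_in : float
        Input gain: central-concentration rate per unit infusion rate
        (concentration-units/min per mg/min).
    dt : float
        Discretization step in seconds (default 1.0).
    transform : str
        BSP transform family, 'hyperbolic_ratio' (default) or 'tanh'.
    """

    k10: float
    k12: float
    k21: float
    b_in: float
    dt: float = 1.0
    transform: str = "hyperbolic_ratio"

    def __post_init__(self):
        for name in ("k10", "k12", "k21", "b_in", "dt"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"PKParams.{name} must be strictly positive, got {v!r}")
        get_transform(self.transform)  # validate name early

    @property
    def dt_min(self) -> float:
        """Discretization step in minutes (rates are per minute)."""
        return self.dt / 60.0

    def rate_matrix(self) -> np.ndarray:
        """Continuous-time rate matrix acting on (x_e, x_c), 1/min."""
        return np.array(
            [
                [-self.k21, self.k12],
                [self.k21, -(self.k10 + self.k12)],
            ]
        )

    def input_vector(self) -> np.ndarray:
        """Continuous-time input vector (drug enters the central compartment)."""
        return np.array([0.0, self.b_in])

    def get_transform(self) -> BSPTransform:
        return get_transform(self.transform)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "k10": self.k10,
            "k12": self.k12,
            "k21": self.k21,
            "b_in": self.b_in,
            "dt": self.dt,
            "transform": self.transform,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PKParams":
        return cls(**{k: d[k] for k in ("k10", "k12", "k21", "b_in") },
                   dt=d.get("dt", 1.0),
                   transform=d.get("transform", "hyperbolic_ratio"))

    def with_rates(self, k10=None, k12=None, k21=None, b_in=None) -> "PKParams":
        """Copy with some rates replaced (used by the fitter)."""
        return replace(
            self,
            k10=self.k10 if k10 is None else k10,
            k12=self.k12 if k12 is None else k12,
            k21=self.k21 if k21 is None else k21,
            b_in=self.b_in if b_in is None else b_in,
        )


@dataclass(frozen=True)
class DiscreteDynamics:
    """Zero-order-hold discretization (A, B) of a two-compartment model.

    ``x_{t+1} = A x_t + B u_t`` with x = (x_e, x_c) and u in mg/min.
    A is substochastic-like (nonnegative, spectral radius < 1: the drug
    washes out) and B is nonnegative with drug entering centrally.
    """

    A: np.ndarray
    B: np.ndarray
    transform_name: str = "hyperbolic_ratio"

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        B = np.asarray(self.B, dtype=float).reshape(2)
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)
        if A.shape != (2, 2):
            raise ValueError("A must be 2x2")
        if np.any(A < -1e-12):
            raise ValueError("A must be entrywise nonnegative")
        if max(abs(np.linalg.eigvals(A))) >= 1.0:
            raise ValueError("A must be stable (spectral radius < 1)")
        if np.any(B < -1e-15) or B[1] <= 0:
            raise ValueError("B must be nonnegative with positive central entry")

    def get_transform(self) -> BSPTransform:
        return get_transform(self.transform_name)


@dataclass(frozen=True)
class SetPoint:
    """Equilibrium (x*, u*) sustaining a constant target BSP p*."""

    p_star: float
    x_star: np.ndarray
    u_star: float

    def __post_init__(self):
        object.__setattr__(self, "x_star", np.asarray(self.x_star, dtype=float).reshape(2))


def discretize(params: PKParams) -> DiscreteDynamics:
    """Exact zero-order-hold discretization of the two-compartment model.

    Uses the augmented matrix exponential ``expm([[M, b], [0, 0]] * dt)``
    whose top blocks are A = e^{M dt} and B = (integral of e^{M s} ds) b.
    """
    M = params.rate_matrix() * params.dt_min
    b = params.input_vector() * params.dt_min
    aug = np.zeros((3, 3))
    aug[:2, :2] = M
    aug[:2, 2] = b
    E = expm(aug)
    A = E[:2, :2]
    B = E[:2, 2]
    return DiscreteDynamics(A=A, B=B, transform_name=params.transform)


def bsp_from_conc(x_e, transform="hyperbolic_ratio"):
    """Burst suppression probability at effect-site concentration ``x_e``."""
    return get_transform(transform).forward(x_e)


def conc_from_bsp(p, transform="hyperbolic_ratio"):
    """Effect-site concentration required to sustain BSP ``p`` in [0, 1)."""
    return get_transform(transform).inverse(p)


def steady_state_setpoint(dyn: DiscreteDynamics, p_star: float) -> SetPoint:
    """Equilibrium state and infusion rate for a constant BSP target.

    Fixes ``x_e* = conc_from_bsp(p_star)`` and solves the two linear
    equilibrium equations ``(I - A) x* = B u*`` for the remaining
    unknowns (x_c*, u*).  This is the origin shift turning BSP tracking
    into a regulator problem around (x*, u*).
    """
    if not (0 < p_star < 1):
        raise ValueError(f"target BSP must be in (0, 1), got {p_star}")
    tf = dyn.get_transform()
    xe_star = float(tf.inverse(p_star))
    IA = np.eye(2) - dyn.A
    # Unknowns (x_c*, u*): IA @ (xe*, xc*) = B u*
    # row i: IA[i,0]*xe + IA[i,1]*xc - B[i]*u = 0
    Msys = np.array([[IA[0, 1], -dyn.B[0]], [IA[1, 1], -dyn.B[1]]])
    rhs = -IA[:, 0] * xe_star
    if abs(np.linalg.det(Msys)) < 1e-14:
        raise np.linalg.LinAlgError("degenerate model: equilibrium system is singular")
    xc_star, u_star = np.linalg.solve(Msys, rhs)
    if u_star < -1e-12:
        raise ValueError(
            f"target BSP {p_star} requires negative infusion {u_star:.3g} mg/min"
        )
    return SetPoint(p_star=p_star, x_star=np.array([xe_star, xc_star]), u_star=float(max(u_star, 0.0)))


def controllability_check(dyn) -> tuple[bool, int]:
    """Rank of the controllability matrix [B, AB, ..., A^{n-1}B];
    controllable iff the rank equals the state dimension.

    Accepts a DiscreteDynamics or a raw ``(A, B)`` pair (any dimension).
    """
    if isinstance(dyn, DiscreteDynamics):
        A, B = dyn.A, dyn.B
    else:
        A, B = dyn
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.asarray(B, dtype=float).reshape(A.shape[0], -1)
    blocks, Akb = [B], B
    for _ in range(A.shape[0] - 1):
        Akb = A @ Akb
        blocks.append(Akb)
    rank = int(np.linalg.matrix_rank(np.column_stack(blocks)))
    return rank == A.shape[0], rank


def plant_step(x, u: float, dyn: DiscreteDynamics) -> np.ndarray:
    """One noiseless step of the discrete plant: ``A x + B u``."""
    if u < 0:
        raise ValueError(f"infusion rate must be nonnegative, got {u}")
    x = np.asarray(x, dtype=float).reshape(2)
    return dyn.A @ x + dyn.B * u
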