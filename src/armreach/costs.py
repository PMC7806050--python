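"""The five basic movement cost functionals and their balanced composite.

Costs are evaluated on sampled trajectories over a uniform time grid:

- ``HJ``  hand jerk:       integral of the squared Cartesian jerk of the wrist
- ``JJ``  joint jerk:      integral of the squared joint-angle jerk
- ``TC``  torque change:   integral of the squared torque rates
- ``Geo`` geodesic:        kinetic-metric path length, integral of sqrt(qd' M qd)
- ``Enr`` absolute work:   integral of sum_i |qd_i tau_i|

All integrals use trapezoidal quadrature; derivatives not supplied by the
caller are taken by central differences (one-sided at the ends).  Each cost
is a nonnegative integral of a norm-like integrand and is zero exactly for
a stationary trajectory.

Because the basic costs live in wildly different units, a per-task scalar
factor vector ``S`` rescales them into a common range before weighting; the
joint-jerk factor is anchored at 1 and the composite cost is
``J = sum_i S_i alpha_i J_i``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arm import ArmParameters, CartesianTrajectory, JointTrajectory, mass_matrix

COST_NAMES = ("HJ", "JJ", "TC", "Geo", "Enr")

__all__ = ["COST_NAMES", "WeightVector", "ScalarFactors", "CostBreakdown",
           "evaluate_basic_costs", "composite_cost"]


@dataclass(frozen=True)
class WeightVector:
    """Nonnegative weights over (HJ, JJ, TC, Geo, Enr)."""

    alpha: tuple
    normalized: bool = False

    def __post_init__(self):
        a = np.asarray(self.alpha, float)
        if a.shape != (5,):
            raise ValueError("alpha must have 5 components")
        if np.any(a < -1e-12):
            raise ValueError("alpha components must be nonnegative")
        a = np.clip(a, 0.0, None)
        if self.normalized:
            s = a.sum()
            if s <= 0:
                raise ValueError("cannot normalize a zero weight vector")
            a = a / s
        object.__setattr__(self, "alpha", tuple(a))

    def normalize(self) -> "WeightVector":
        return WeightVector(self.alpha, normalized=True)

    @classmethod
    def one_hot(cls, name: str) -> "WeightVector":
        a = np.zeros(5)
        a[COST_NAMES.index(name)] = 1.0
        return cls(tuple(a), normalized=True)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.alpha, float)


@dataclass(frozen=True)
class ScalarFactors:
    """Per-task range-balancing factors; the JJ factor is 1 by convention."""

    S: tuple
    task_id: str = ""

    def __post_init__(self):
        s = np.asarray(self.S, float)
        if s.shape != (5,):
            raise ValueError("S must have 5 components")
        if np.any(s <= 0):
            raise ValueError("scalar factors must be positive")
        if abs(s[COST_NAMES.index("JJ")] - 1.0) > 1e-12:
            raise ValueError("the joint-jerk scalar factor must be exactly 1")
        object.__setattr__(self, "S", tuple(s))

    @classmethod
    def ones(cls) -> "ScalarFactors":
        return cls((1.0,) * 5)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.S, float)


@dataclass(frozen=True)
class CostBreakdown:
    J_HJ: float
    J_JJ: float
    J_TC: float
    J_Geo: float
    J_Enr: float
    J_composite: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.J_HJ, self.J_JJ, self.J_TC, self.J_Geo, self.J_Enr])

    def to_dict(self) -> dict:
        d = dict(zip(COST_NAMES, self.as_array().tolist()))
        d["composite"] = float(self.J_composite)
        return d


def _deriv(y: np.ndarray, dt: float, order: int = 1) -> np.ndarray:
    """Grid derivatives by local quintic (Savitzky-Golay) fits.

    A 7-point moving quintic fit is exact for polynomials up to degree 5
    and, unlike repeated central differencing, keeps full accuracy at the
    interval ends, where the jerk of a reach peaks.
    """
    from scipy.signal import savgol_filter

    window = min(7, y.shape[0] if y.shape[0] % 2 == 1 else y.shape[0] - 1)
    poly = min(5, window - 1)
    if poly < order:
        raise ValueError("too few samples for the requested derivative")
    return savgol_filter(y, window_length=window, polyorder=poly,
                         deriv=order, delta=dt, axis=0, mode="interp")


def evaluate_basic_costs(joint_traj: JointTrajectory,
                         torque_traj: np.ndarray,
                         endeff_traj: CartesianTrajectory,
                         params: ArmParameters,
                         smooth_abs_eps: float = 0.0) -> CostBreakdown:
    """Evaluate the five basic costs on one trajectory.

    ``torque_traj`` is the (N, 3) torque sequence on the same grid; the
    torque rate is taken by central differences.  ``smooth_abs_eps`` > 0
    replaces |x| in the energy integrand by sqrt(x^2 + eps^2) (used inside
    gradient-based trajectory optimization; evaluation keeps the exact
    absolute value by default).
    """
    t = joint_traj.t
    if t.size < 4:
        raise ValueError("at least 4 samples required (third derivatives)")
    if endeff_traj.t.size != t.size or not np.allclose(endeff_traj.t, t):
        raise ValueError("joint and end-effector grids must match")
    tau = np.asarray(torque_traj, float)
    if tau.shape != (t.size, 3):
        raise ValueError("torque sequence must match the trajectory grid")
    dt = joint_traj.dt

    dq = _deriv(joint_traj.q, dt, 1)
    jerk_q = _deriv(joint_traj.q, dt, 3)
    jerk_x = _deriv(endeff_traj.pos, dt, 3)
    dtau = _deriv(tau, dt, 1)

    J_HJ = np.trapezoid(np.sum(jerk_x**2, axis=1), dx=dt)
    J_JJ = np.trapezoid(np.sum(jerk_q**2, axis=1), dx=dt)
    J_TC = np.trapezoid(np.sum(dtau**2, axis=1), dx=dt)
    M = mass_matrix(joint_traj.q, params)
    quad = np.einsum("ni,nij,nj->n", dq, M, dq)
    J_Geo = np.trapezoid(np.sqrt(np.clip(quad, 0.0, None)), dx=dt)
    prod = dq * tau
    if smooth_abs_eps > 0:
        absw = np.sqrt(prod**2 + smooth_abs_eps**2) - smooth_abs_eps
    else:
        absw = np.abs(prod)
    J_Enr = np.trapezoid(np.sum(absw, axis=1), dx=dt)
    return CostBreakdown(float(J_HJ), float(J_JJ), float(J_TC),
                         float(J_Geo), float(J_Enr))


def composite_cost(breakdown: CostBreakdown, alpha: WeightVector,
                   S: ScalarFactors) -> float:
    """Scalar-balanced weighted sum  J = sum_i S_i alpha_i J_i."""
    return float(np.dot(S.as_array() * alpha.as_array(), breakdown.as_array()))
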