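"""Direct optimal control of point-to-point reaches for a weighted cost.

The reach is posed as: find joint trajectories q(t) from a start to an end
configuration in time T that minimize the scalar-balanced composite cost
``J = sum_i S_i alpha_i J_i`` subject to the arm dynamics and joint-angle
box limits.  The arm is fully actuated, so every sufficiently smooth joint
path is dynamically feasible and the torques (and their rates, needed by
the torque-change and energy costs) follow from inverse dynamics.  The
dynamics therefore never appear as constraints: they are satisfied exactly
by construction, and the transcription reduces to smooth unconstrained
optimization over a compact trajectory parametrization.

Each joint trajectory is a quintic rest-to-rest interpolant plus a
correction expanded in bump polynomials ``s^3 (1-s)^3 P_k(2s-1)`` (P_k
shifted Legendre), which vanish together with their first and second
derivatives at both ends, so boundary conditions hold for every candidate.
Joint limits enter as a smooth quadratic hinge penalty.  The optimizer is
deterministic (L-BFGS-B from the quintic interpolant), so re-solving a
task always returns the same trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from numpy.polynomial import legendre, polynomial as P
from scipy.optimize import minimize

from .arm import (ArmParameters, CartesianTrajectory, JointTrajectory,
                  forward_kinematics, inverse_dynamics, mass_matrix,
                  wrist_jerk)
from .costs import (COST_NAMES, CostBreakdown, ScalarFactors, WeightVector,
                    composite_cost, evaluate_basic_costs)

__all__ = ["OCPTask", "OCPSettings", "OCPSolution", "solve_ocp",
           "single_cost_solutions"]


@dataclass(frozen=True)
class OCPTask:
    """Boundary conditions and discretization of one reaching task."""

    q_start: tuple
    q_end: tuple
    duration: float = 1.0
    boundary: str = "rest"          # "rest" (qd = qdd = 0 at ends) or "free_rates"
    n_nodes: int = 50

    def __post_init__(self):
        qs = np.asarray(self.q_start, float).reshape(3)
        qe = np.asarray(self.q_end, float).reshape(3)
        object.__setattr__(self, "q_start", tuple(qs))
        object.__setattr__(self, "q_end", tuple(qe))
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if self.n_nodes < 20:
            raise ValueError("n_nodes must be at least 20")
        if self.boundary not in ("rest", "free_rates"):
            raise ValueError("boundary must be 'rest' or 'free_rates'")

    @property
    def key(self) -> tuple:
        return (self.q_start, self.q_end, self.duration, self.boundary,
                self.n_nodes)


@dataclass(frozen=True)
class OCPSettings:
    n_basis: int = 6                # correction polynomials per joint
    max_iter: int = 300
    ftol: float = 1e-12
    gtol: float = 1e-9
    smooth_abs_eps: float = 1e-6    # |x| smoothing inside the optimizer
    geo_eps: float = 1e-8           # sqrt smoothing for the geodesic integrand
    limit_penalty: float = 1e7


@dataclass
class OCPSolution:
    task: OCPTask
    t: np.ndarray
    q: np.ndarray
    dq: np.ndarray
    ddq: np.ndarray
    tau: np.ndarray
    dtau: np.ndarray
    endeffector: CartesianTrajectory
    breakdown: CostBreakdown
    status: str
    n_iter: int
    coefficients: np.ndarray

    @property
    def joint_trajectory(self) -> JointTrajectory:
        return JointTrajectory(t=self.t, q=self.q)

    @property
    def converged(self) -> bool:
        return self.status == "converged"


# --------------------------------------------------------------------------
# trajectory parametrization

@lru_cache(maxsize=64)
def _basis_matrices(T: float, n_nodes: int, n_basis: int, boundary: str):
    """Design matrices of the correction basis and its time derivatives.

    Returns (s_grid, [B0, B1, B2, B3]) with Bd of shape (n_nodes, n_basis)
    holding the d-th time derivative of each basis polynomial on the grid.
    """
    s = np.linspace(0.0, 1.0, n_nodes)
    if boundary == "rest":
        # s^3 (1-s)^3 in power basis
        env = P.polypow(np.array([0.0, 1.0]), 3)
        env = P.polymul(env, P.polypow(np.array([1.0, -1.0]), 3))
    else:  # free end rates: only position pinned at the ends
        env = P.polymul(np.array([0.0, 1.0]), np.array([1.0, -1.0]))
    mats = []
    polys = []
    for k in range(n_basis):
        leg = legendre.leg2poly(np.eye(n_basis)[k])        # P_k in power basis on [-1,1]
        # shift to [0,1]: P_k(2s-1)
        shifted = np.zeros(1)
        arg = np.array([-1.0, 2.0])
        term = np.array([1.0])
        for c in leg:
            shifted = P.polyadd(shifted, c * term)
            term = P.polymul(term, arg)
        polys.append(P.polymul(env, shifted))
    for d in range(4):
        B = np.empty((n_nodes, n_basis))
        for k, p in enumerate(polys):
            B[:, k] = P.polyval(s, P.polyder(p, d)) / T**d
        mats.append(B)
    # precondition: scale each column to unit jerk RMS so the Hessian of
    # smoothness costs is well conditioned in the coefficients
    scale = 1.0 / np.sqrt(np.mean(mats[3] ** 2, axis=0))
    for B in mats:
        B *= scale
    return s, mats


def _quintic_base(task: OCPTask):
    """Rest-to-rest quintic joint interpolant and its time derivatives."""
    s = np.linspace(0.0, 1.0, task.n_nodes)
    T = task.duration
    sig = 10 * s**3 - 15 * s**4 + 6 * s**5
    dsig = (30 * s**2 - 60 * s**3 + 30 * s**4) / T
    d2sig = (60 * s - 180 * s**2 + 120 * s**3) / T**2
    d3sig = (60 - 360 * s + 360 * s**2) / T**3
    dq_vec = np.asarray(task.q_end) - np.asarray(task.q_start)
    base = np.asarray(task.q_start) + np.outer(sig, dq_vec)
    return base, np.outer(dsig, dq_vec), np.outer(d2sig, dq_vec), np.outer(d3sig, dq_vec)


def _trajectories(task: OCPTask, settings: OCPSettings, coeffs: np.ndarray):
    """q and its first three time derivatives for a coefficient vector."""
    K = settings.n_basis
    c = coeffs.reshape(3, K)
    _, (B0, B1, B2, B3) = _basis_matrices(task.duration, task.n_nodes, K,
                                          task.boundary)
    base = _quintic_base(task)
    out = []
    for d, B in enumerate((B0, B1, B2, B3)):
        out.append(base[d] + B @ c.T)
    return out  # q, dq, ddq, dddq each (N, 3)


def _numeric_deriv(y: np.ndarray, dt: float, order: int = 1) -> np.ndarray:
    for _ in range(order):
        y = np.gradient(y, dt, axis=0, edge_order=2)
    return y


def _objective(task: OCPTask, settings: OCPSettings, w: np.ndarray,
               params: ArmParameters, coeffs: np.ndarray) -> float:
    q, dq, ddq, dddq = _trajectories(task, settings, coeffs)
    dt = task.duration / (task.n_nodes - 1)
    J = 0.0
    iHJ, iJJ, iTC, iGeo, iEnr = range(5)
    if w[iJJ] > 0:
        J += w[iJJ] * np.trapezoid(np.sum(dddq**2, axis=1), dx=dt)
    if w[iHJ] > 0:
        jx = wrist_jerk(q, dq, ddq, dddq, params)
        J += w[iHJ] * np.trapezoid(np.sum(jx**2, axis=1), dx=dt)
    if w[iTC] > 0 or w[iEnr] > 0 or w[iGeo] > 0:
        from .arm import _coriolis_from_dM, dynamics_bundle

        M, G, dM = dynamics_bundle(q, params)
        if w[iTC] > 0 or w[iEnr] > 0:
            C = _coriolis_from_dM(dM, dq)
            tau = (np.einsum("nij,nj->ni", M, ddq)
                   + np.einsum("nij,nj->ni", C, dq) + G)
            if w[iTC] > 0:
                dtau = _numeric_deriv(tau, dt, 1)
                J += w[iTC] * np.trapezoid(np.sum(dtau**2, axis=1), dx=dt)
            if w[iEnr] > 0:
                prod = dq * tau
                eps = settings.smooth_abs_eps
                absw = np.sqrt(prod**2 + eps**2) - eps
                J += w[iEnr] * np.trapezoid(np.sum(absw, axis=1), dx=dt)
        if w[iGeo] > 0:
            quad = np.einsum("ni,nij,nj->n", dq, M, dq)
            J += w[iGeo] * np.trapezoid(np.sqrt(quad + settings.geo_eps**2),
                                        dx=dt)
    # joint-limit quadratic hinge penalty
    lo = np.asarray(params.q_min)
    hi = np.asarray(params.q_max)
    viol = np.clip(lo - q, 0.0, None) + np.clip(q - hi, 0.0, None)
    if np.any(viol > 0):
        J += settings.limit_penalty * np.trapezoid(np.sum(viol**2, axis=1), dx=dt)
    return float(J)


def solve_ocp(task: OCPTask, alpha: WeightVector, S: ScalarFactors,
              params: ArmParameters,
              settings: OCPSettings | None = None,
              initial_coefficients: np.ndarray | None = None) -> OCPSolution:
    """Solve the reaching OCP for one weight vector.

    Returns a solution with status ``"converged"``, ``"not converged"``
    (iteration budget hit; best iterate returned so an outer search can
    still penalize it) or ``"infeasible"`` (boundary states outside the
    joint limits).  ``initial_coefficients`` warm-starts the optimizer
    (used by the inverse-optimal-control loop, whose successive weight
    candidates have nearby optima); the default start is the quintic
    joint interpolant (zero coefficients).
    """
    settings = settings or OCPSettings()
    w = S.as_array() * alpha.as_array()
    qs, qe = np.asarray(task.q_start), np.asarray(task.q_end)
    if not (params.admissible(qs) and params.admissible(qe)):
        return _empty_solution(task, params, settings, status="infeasible")

    if initial_coefficients is not None and \
            initial_coefficients.shape == (3 * settings.n_basis,):
        x0 = np.asarray(initial_coefficients, float)
    else:
        x0 = np.zeros(3 * settings.n_basis)
    res = minimize(
        lambda c: _objective(task, settings, w, params, c), x0,
        method="L-BFGS-B",
        options=dict(maxiter=settings.max_iter, ftol=settings.ftol,
                     gtol=settings.gtol))
    status = "converged" if res.success or res.status == 0 else "not converged"
    return _assemble(task, params, settings, alpha, S, res.x, status,
                     int(res.nit))


def _empty_solution(task, params, settings, status):
    return _assemble(task, params, settings,
                     WeightVector((0.2,) * 5), ScalarFactors.ones(),
                     np.zeros(3 * settings.n_basis), status, 0)


def _assemble(task, params, settings, alpha, S, coeffs, status, n_iter):
    q, dq, ddq, _ = _trajectories(task, settings, coeffs)
    t = np.linspace(0.0, task.duration, task.n_nodes)
    tau = inverse_dynamics((q, dq, ddq), params)
    dt = task.duration / (task.n_nodes - 1)
    dtau = _numeric_deriv(tau, dt, 1)
    _, wrist = forward_kinematics(q, params)
    endeff = CartesianTrajectory(t=t, pos=wrist)
    jt = JointTrajectory(t=t, q=q)
    bd = evaluate_basic_costs(jt, tau, endeff, params)
    bd = CostBreakdown(*bd.as_array(), composite_cost(bd, alpha, S))
    return OCPSolution(task=task, t=t, q=q, dq=dq, ddq=ddq, tau=tau,
                       dtau=dtau, endeffector=endeff, breakdown=bd,
                       status=status, n_iter=n_iter, coefficients=coeffs)


def single_cost_solutions(task: OCPTask, params: ArmParameters,
                          settings: OCPSettings | None = None) -> dict:
    """One-hot OCP solutions for each basic cost (unit scalar factors)."""
    return {name: solve_ocp(task, WeightVector.one_hot(name),
                            ScalarFactors.ones(), params, settings)
            for name in COST_NAMES}
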