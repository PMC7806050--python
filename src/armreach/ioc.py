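"""Bi-level inverse optimal control over the five-cost composite.

Given an observed relative end-effector trajectory, the engine searches
for the normalized weight vector alpha whose optimal-control rollout is
closest (in DTW distance) to the observation:

    upper level:  min_alpha  D(t*_alpha, t_obs),  sum_i alpha_i = 1
    lower level:  t*_alpha = argmin of the scalar-balanced composite OCP

Protocol: the joint-jerk weight is fixed at 1 and the remaining four
components are searched inside [0, 1] by a deterministic derivative-free
trust-region method (COBYLA), started from (0.5, 1, 0.5, 0.5, 0.5) and run
three times with initial trust radii 0.15, 0.3 and 0.45.  If a returned
component exceeds one, the run is restarted with that component fixed to
one and the joint-jerk weight freed.  The best of all runs is normalized
to the simplex.  The search is local — the bi-level landscape has no
tractable global certificate — so recovery is judged by tolerance, not
exactness.

Scalar factors are recalibrated per task (they change whenever either
boundary configuration changes) from the five single-cost optima:
S_i = J_i,max / J_JJ,max with J_i,max the largest value of cost i across
those five trajectories, anchored at S_JJ = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .arm import ArmParameters, CartesianTrajectory
from .costs import (COST_NAMES, CostBreakdown, ScalarFactors, WeightVector,
                    evaluate_basic_costs)
from .metrics import dtw_distance
from .ocp import OCPSettings, OCPTask, single_cost_solutions, solve_ocp

__all__ = ["IOCSettings", "IOCResult", "calibrate_scalar_factors", "ioc_fit",
           "compare_single_vs_composite"]

_JJ = COST_NAMES.index("JJ")
_INIT_ALPHA = np.array([0.5, 1.0, 0.5, 0.5, 0.5])
_RADII = (0.15, 0.3, 0.45)


@dataclass(frozen=True)
class IOCSettings:
    max_upper_iter: int = 100       # DFO iterations per radius run
    radii: tuple = _RADII
    cache_decimals: int = 4         # alpha rounding for OCP memoization
    ocp: OCPSettings = field(default_factory=OCPSettings)


@dataclass
class IOCResult:
    alpha_star: WeightVector
    scalar_factors: ScalarFactors
    dtw_value: float
    traces: list
    status: str

    def to_dict(self) -> dict:
        return {
            "alpha": dict(zip(COST_NAMES, self.alpha_star.as_array().tolist())),
            "scalar_factors": dict(zip(COST_NAMES,
                                       self.scalar_factors.as_array().tolist())),
            "dtw": self.dtw_value,
            "status": self.status,
            "traces": self.traces,
        }


def calibrate_scalar_factors(task: OCPTask, params: ArmParameters,
                             settings: OCPSettings | None = None,
                             _solutions: dict | None = None) -> ScalarFactors:
    """Range-balancing factors S_i = J_i,max / J_JJ,max for one task.

    Must be re-run whenever the start or end configuration changes.
    Raises for a degenerate task (start equals end: every basic cost is
    zero and no balancing exists) and for any failed single-cost solve.
    """
    if np.allclose(task.q_start, task.q_end):
        raise ValueError("degenerate task: start equals end, all costs vanish")
    sols = _solutions or single_cost_solutions(task, params, settings)
    for name, sol in sols.items():
        if sol.status == "infeasible":
            raise RuntimeError(f"single-cost OCP for {name} failed: {sol.status}")
    # J_i evaluated on every single-cost optimum; J_i,max over those
    table = np.array([[evaluate_basic_costs(s.joint_trajectory, s.tau,
                                            s.endeffector, params).as_array()
                       for s in sols.values()]])[0]
    j_max = table.max(axis=0)
    if j_max[_JJ] <= 0:
        raise ValueError("degenerate task: joint-jerk range is zero")
    # balance every cost's range [0, J_i,max] onto the joint-jerk range:
    # S_i J_i spans [0, J_JJ,max] for each i, with S_JJ = 1
    with np.errstate(divide="ignore"):
        S = np.where(j_max > 0, j_max[_JJ] / j_max, 1.0)
    S[_JJ] = 1.0
    return ScalarFactors(tuple(S), task_id=str(task.key))


class _CachedRollout:
    """Memoize OCP solves on the rounded weight vector for one task."""

    def __init__(self, task, S, params, settings: IOCSettings):
        self.task, self.S, self.params, self.settings = task, S, params, settings
        self.cache: dict = {}
        self.n_solves = 0
        self._warm = None   # coefficients of the first solve (fixed start)

    def __call__(self, alpha_full: np.ndarray):
        key = tuple(np.round(alpha_full, self.settings.cache_decimals))
        if key not in self.cache:
            wv = WeightVector(tuple(np.clip(alpha_full, 0.0, None)))
            # every candidate is warm-started from the SAME point (the
            # first evaluation's optimum): faster than the quintic start,
            # yet the rollout stays a well-defined function of alpha —
            # warm-starting from the previous candidate would make the
            # search objective path-dependent and mislead the DFO
            sol = solve_ocp(self.task, wv, self.S, self.params,
                            self.settings.ocp,
                            initial_coefficients=self._warm)
            self.n_solves += 1
            if self._warm is None:
                self._warm = sol.coefficients
            self.cache[key] = sol
        return self.cache[key]


def _run_dfo(rollout, observation, fixed: int, radius: float,
             max_iter: int, x0: np.ndarray):
    """One trust-region DFO run over the four free components.

    The method is COBYQA (Powell-family quadratic-model trust region,
    deterministic) started at ``x0`` with initial radius ``radius``.  The
    search objective is DTW with squared local distances — smooth near a
    perfect match, which the interpolation models exploit; reported
    distances elsewhere stay plain Euclidean.  ``max_iter`` counts trust-
    region steps; the 2n+1 evaluations that build the first model are on
    top of it.  The free components are bounded in [0, 1.2]: the slack
    above 1 lets the restart rule observe a component crossing one.
    """
    free = [i for i in range(5) if i != fixed]

    def objective(x):
        alpha = np.empty(5)
        alpha[fixed] = 1.0
        alpha[free] = np.clip(x, 0.0, None)
        sol = rollout(alpha)
        if sol.status == "infeasible":
            return 1e6
        return dtw_distance(sol.endeffector, observation,
                            local="sqeuclidean").dtw_value

    n_free = len(free)
    maxfev = (2 * n_free + 1) + int(np.ceil(1.3 * max_iter))
    res = minimize(objective, x0, method="COBYQA",
                   bounds=[(0.0, 1.2)] * n_free,
                   options=dict(initial_tr_radius=radius, maxfev=maxfev,
                                final_tr_radius=1e-5))
    alpha = np.empty(5)
    alpha[fixed] = 1.0
    alpha[free] = np.clip(res.x, 0.0, None)
    return alpha, float(res.fun), int(res.nfev)


def ioc_fit(observation: CartesianTrajectory, task: OCPTask,
            params: ArmParameters,
            settings: IOCSettings | None = None,
            scalar_factors: ScalarFactors | None = None) -> IOCResult:
    """Recover the normalized cost-weight vector explaining an observation.

    ``observation`` must already be a relative end-effector trajectory
    (marker data goes through ``markers_to_joint_angles`` and
    ``relative_endeffector_trajectory`` first).
    """
    settings = settings or IOCSettings()
    S = scalar_factors or calibrate_scalar_factors(task, params, settings.ocp)
    rollout = _CachedRollout(task, S, params, settings)

    traces = []
    best = None
    for radius in settings.radii:
        fixed = _JJ
        x0 = _INIT_ALPHA[[i for i in range(5) if i != fixed]].copy()
        alpha, fval, nfev = _run_dfo(rollout, observation, fixed, radius,
                                     settings.max_upper_iter, x0)
        restarted = False
        over = [i for i in range(5) if i != fixed and alpha[i] > 1.0 + 1e-9]
        if over:
            # fix the largest offending component to one, free the former
            new_fixed = int(np.argmax(alpha))
            x0 = np.minimum(alpha[[i for i in range(5) if i != new_fixed]], 1.0)
            alpha, fval, nfev2 = _run_dfo(rollout, observation, new_fixed,
                                          radius, settings.max_upper_iter, x0)
            nfev += nfev2
            restarted = True
        traces.append({"radius": radius, "evaluations": nfev,
                       "restarted": restarted, "best_sq_dtw": fval,
                       "alpha": alpha.tolist()})
        if best is None or fval < best[1]:
            best = (alpha, fval)

    if best is None or not np.isfinite(best[1]):
        raise RuntimeError("all OCP evaluations failed during the IOC search")
    alpha_star = WeightVector(tuple(best[0])).normalize()
    # the stored distance is the Euclidean DTW of a fresh alpha_star rollout
    final = solve_ocp(task, alpha_star, S, params, settings.ocp)
    final_dtw = dtw_distance(final.endeffector, observation).dtw_value
    return IOCResult(alpha_star=alpha_star, scalar_factors=S,
                     dtw_value=float(final_dtw),
                     traces=traces, status="converged")


def compare_single_vs_composite(observation: CartesianTrajectory,
                                task: OCPTask, params: ArmParameters,
                                settings: IOCSettings | None = None,
                                result: IOCResult | None = None) -> dict:
    """DTW errors of the five single-cost models and the fitted composite.

    Returns a 6-row mapping model-name -> DTW distance to the observation,
    reproducing the single-versus-composite comparison on any observation.
    """
    settings = settings or IOCSettings()
    sols = single_cost_solutions(task, params, settings.ocp)
    table = {name: dtw_distance(sol.endeffector, observation).dtw_value
             for name, sol in sols.items()}
    if result is None:
        result = ioc_fit(observation, task, params, settings)
    table["Composite"] = result.dtw_value
    return table
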