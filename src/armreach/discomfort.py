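"""Discomfort metric linking reach geometry to the kinematics/dynamics trade-off.

Fitted cost weights across a task grid show that dynamics-related costs
(torque change + energy) contribute more for uncomfortable reaches.  The
discomfort of a task is scored from three factors, in degrees: the
starting shoulder pitch ``q1_S`` (90 deg = fully stretched down, the most
comfortable posture), the starting shoulder yaw ``q2_S``, and the pitch
change ``q1_Change = q1_E - q1_S``:

    Dis = (90 - q1_S)/180 + beta1 * q2_S/180 + beta2 * q1_Change/180

The two free weights (beta1, beta2) are chosen to maximize the R^2 of a
simple linear regression of the dynamics contribution C on Dis, by
exhaustive grid search over [-1, 1]^2.  Because R^2 of a one-variable
least-squares line equals the squared Pearson correlation, the grid is
evaluated in closed form from second moments of the three factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["TaskFactors", "DiscomfortFit", "discomfort", "fit_linear",
           "optimize_betas"]


@dataclass(frozen=True)
class TaskFactors:
    """Per-task reach factors (degrees) and cost contributions (fractions)."""

    q1_S: float
    q2_S: float
    q1_Change: float
    dynamics_contribution: float      # alpha_TC + alpha_Enr
    kinematics_contribution: float = float("nan")   # alpha_HJ + alpha_JJ

    def __post_init__(self):
        c = self.dynamics_contribution
        if not 0.0 <= c <= 1.0:
            raise ValueError("contributions must lie in [0, 1]")


def discomfort(q1_S, q2_S, q1_Change, beta1: float, beta2: float):
    """The linear discomfort score; all angles in degrees."""
    q1_S = np.asarray(q1_S, float)
    return ((90.0 - q1_S) / 180.0
            + beta1 * np.asarray(q2_S, float) / 180.0
            + beta2 * np.asarray(q1_Change, float) / 180.0)


def fit_linear(dis_values, contributions):
    """Least-squares line C ~ theta1 + theta2 * Dis and its R^2."""
    x = np.asarray(dis_values, float)
    c = np.asarray(contributions, float)
    if x.size < 3:
        raise ValueError("at least 3 points required")
    if np.var(c) <= 1e-15:
        raise ValueError("contributions have zero variance; R^2 undefined")
    if np.var(x) <= 1e-15:
        raise ValueError("discomfort values have zero variance")
    theta2, theta1 = np.polyfit(x, c, 1)
    pred = theta1 + theta2 * x
    r2 = 1.0 - np.sum((c - pred) ** 2) / np.sum((c - c.mean()) ** 2)
    return float(theta1), float(theta2), float(r2)


@dataclass(frozen=True)
class DiscomfortFit:
    beta1: float
    beta2: float
    theta1: float
    theta2: float
    r_squared: float

    def __post_init__(self):
        if self.r_squared > 1.0 + 1e-12:
            raise ValueError("R^2 cannot exceed 1")

    def to_dict(self) -> dict:
        return {"beta1": self.beta1, "beta2": self.beta2,
                "theta1": self.theta1, "theta2": self.theta2,
                "r_squared": self.r_squared}


def optimize_betas(task_factors: list, resolution: float = 0.005,
                   bound: float = 1.0) -> DiscomfortFit:
    """Exhaustive (beta1, beta2) grid search maximizing regression R^2.

    The grid covers [-bound, bound]^2 at the given resolution.  For a
    one-regressor least-squares line R^2 = corr(Dis, C)^2, and Dis is
    affine in (beta1, beta2), so every grid value is evaluated exactly
    from the covariance structure of the three factors — this *is* the
    exhaustive evaluation, with no per-cell regression.  Ties are broken
    toward the smallest ||beta||, then lexicographically.
    """
    if len(task_factors) < 10:
        raise ValueError("at least 10 tasks required")
    base = np.array([(90.0 - tf.q1_S) / 180.0 for tf in task_factors])
    a = np.array([tf.q2_S / 180.0 for tf in task_factors])
    b = np.array([tf.q1_Change / 180.0 for tf in task_factors])
    c = np.array([tf.dynamics_contribution for tf in task_factors])
    if np.var(c) <= 1e-15:
        raise ValueError("contributions have zero variance")
    if np.var(base) + np.var(a) + np.var(b) <= 1e-15:
        raise ValueError("task factors are degenerate (no variation)")

    def ctr(v):
        return v - v.mean()

    base_c, a_c, b_c, c_c = ctr(base), ctr(a), ctr(b), ctr(c)
    n_grid = int(round(2 * bound / resolution)) + 1
    betas = np.linspace(-bound, bound, n_grid)
    B1, B2 = np.meshgrid(betas, betas, indexing="ij")

    # cov(Dis, C) and var(Dis) are quadratic/affine in (beta1, beta2)
    cov_dc = (base_c @ c_c) + B1 * (a_c @ c_c) + B2 * (b_c @ c_c)
    var_d = ((base_c @ base_c)
             + B1**2 * (a_c @ a_c) + B2**2 * (b_c @ b_c)
             + 2 * B1 * (base_c @ a_c) + 2 * B2 * (base_c @ b_c)
             + 2 * B1 * B2 * (a_c @ b_c))
    var_c = c_c @ c_c
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(var_d > 1e-15, cov_dc**2 / (var_d * var_c), -np.inf)

    best = r2.max()
    cand = np.argwhere(r2 >= best - 1e-12)
    norms = B1[cand[:, 0], cand[:, 1]]**2 + B2[cand[:, 0], cand[:, 1]]**2
    order = np.lexsort((cand[:, 1], cand[:, 0], np.round(norms, 12)))
    i, j = cand[order[0]]
    beta1, beta2 = float(B1[i, j]), float(B2[i, j])
    dis = discomfort(np.array([tf.q1_S for tf in task_factors]),
                     np.array([tf.q2_S for tf in task_factors]),
                     np.array([tf.q1_Change for tf in task_factors]),
                     beta1, beta2)
    theta1, theta2, r_squared = fit_linear(dis, c)
    return DiscomfortFit(beta1=beta1, beta2=beta2, theta1=theta1,
                         theta2=theta2, r_squared=r_squared)
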