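"""Probabilistic movement primitives over wrist trajectories.

A trajectory axis is represented as y(t) = Phi_t' w + eps, with Gaussian
radial basis functions on a normalized phase axis in [0, 1] and a Gaussian
distribution N(mu_w, Sigma_w) over the basis weights capturing trial-to-
trial motor variability.  The x, y, z axes are modelled as independent
blocks sharing one basis system.  Supported operations:

- maximum-likelihood fitting from demonstrations (per-trajectory ridge
  regression, then sample mean/covariance of the weights);
- the marginal state distribution at any phase (mean and variance of
  position and velocity);
- Gaussian conditioning on a partial (prefix) observation and rollout of
  the full predicted trajectory with pointwise variance;
- online updating by appending an observation to the storage and refitting;
- closed-form KL divergence between the weight distributions of two
  models, used as the convergence monitor of the online pipeline.

With a single demonstration (the optimal-control initialization of the
hybrid pipeline) the weight covariance cannot be estimated and is set to a
configured large prior, so early predictions carry honest, wide bands that
contract as real observations arrive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .arm import CartesianTrajectory

__all__ = ["BasisSystem", "ProMPModel", "fit", "marginal", "condition",
           "condition_and_rollout", "prefix", "update", "kl_divergence"]


@dataclass(frozen=True)
class BasisSystem:
    """Gaussian radial bases on the phase axis z in [0, 1].

    ``n`` centers are spread uniformly over [0, 1]; the common width is
    ``overlap / (n - 1)`` so neighbouring bases overlap smoothly.  The
    basis matrix at a phase stacks values and phase-derivatives,
    Phi_z = [phi_z, dphi_z], giving position and velocity rows.
    """

    n: int = 15
    overlap: float = 2.0

    def __post_init__(self):
        if self.n < 5:
            raise ValueError("at least 5 basis functions required")

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(0.0, 1.0, self.n)

    @property
    def width(self) -> float:
        return self.overlap / (self.n - 1)

    def phi(self, z) -> np.ndarray:
        """Normalized basis values, shape (len(z), n)."""
        z = np.atleast_1d(np.asarray(z, float))
        raw = np.exp(-0.5 * ((z[:, None] - self.centers[None, :])
                             / self.width) ** 2)
        return raw / raw.sum(axis=1, keepdims=True)

    def dphi(self, z, h: float = 1e-6) -> np.ndarray:
        """Phase derivative of the normalized basis (central difference)."""
        return (self.phi(np.asarray(z) + h) - self.phi(np.asarray(z) - h)) / (2 * h)

    def design(self, z) -> np.ndarray:
        """Stacked [phi; dphi], shape (len(z), 2, n)."""
        return np.stack([self.phi(z), self.dphi(z)], axis=1)


@dataclass
class ProMPModel:
    basis: BasisSystem
    mu_w: np.ndarray          # (3, n) per-axis weight means
    Sigma_w: np.ndarray       # (3, n, n) per-axis weight covariances
    sigma_y: np.ndarray       # (3,) per-axis observation noise std
    storage: list = field(default_factory=list)   # past trajectories (resampled)
    n_phase: int = 50
    large_prior: float = 100.0
    ridge: float = 1e-3
    cov_shrink: float = 0.1

    @property
    def n_observations(self) -> int:
        return len(self.storage)

    def mean_trajectory(self, n_points: int | None = None) -> CartesianTrajectory:
        z = np.linspace(0.0, 1.0, n_points or self.n_phase)
        phi = self.basis.phi(z)
        pos = np.stack([phi @ self.mu_w[a] for a in range(3)], axis=1)
        return CartesianTrajectory(t=z, pos=pos)


def _resample(traj: CartesianTrajectory, n_phase: int) -> np.ndarray:
    """Linear time-to-phase mapping and resampling to the phase grid."""
    z = np.linspace(0.0, 1.0, n_phase)
    src = (traj.t - traj.t[0]) / (traj.t[-1] - traj.t[0])
    return np.stack([np.interp(z, src, traj.pos[:, a]) for a in range(3)], axis=1)


def _ridge_weights(basis: BasisSystem, y_grid: np.ndarray, ridge: float):
    z = np.linspace(0.0, 1.0, y_grid.shape[0])
    phi = basis.phi(z)                       # (T, n)
    A = phi.T @ phi + ridge * np.eye(basis.n)
    return np.linalg.solve(A, phi.T @ y_grid)   # (n, 3)


def fit(trajectories: list, basis: BasisSystem | None = None,
        n_phase: int = 50, large_prior: float = 100.0,
        ridge: float = 1e-3, cov_shrink: float = 0.1,
        noise_floor: float = 1e-6) -> ProMPModel:
    """Maximum-likelihood ProMP fit from demonstration trajectories.

    Each trajectory is mapped linearly onto the phase grid and projected
    onto the basis by ridge least squares; the weight distribution is the
    sample mean and covariance over demonstrations.  The covariance gets a
    diagonal shrinkage of ``cov_shrink`` times its mean eigenvalue: with
    few demonstrations the raw sample covariance is rank-deficient, which
    would make conditioning overconfident and divergences between refits
    blow up.  With one demonstration the covariance is set to
    ``large_prior**2 * I``.  Observation noise is estimated per axis from
    the fit residuals, floored at ``noise_floor``.
    """
    basis = basis or BasisSystem()
    if len(trajectories) < 1:
        raise ValueError("at least one trajectory required")
    for tr in trajectories:
        if tr.t.size < basis.n:
            raise ValueError("trajectory shorter than the number of bases")
    grids = [_resample(tr, n_phase) for tr in trajectories]
    W = np.stack([_ridge_weights(basis, g, ridge) for g in grids])  # (R, n, 3)

    mu = W.mean(axis=0).T                                           # (3, n)
    if len(grids) == 1:
        Sigma = np.stack([large_prior**2 * np.eye(basis.n)] * 3)
    else:
        Sigma = np.empty((3, basis.n, basis.n))
        eye = np.eye(basis.n)
        for a in range(3):
            d = W[:, :, a] - mu[a]
            S = d.T @ d / (len(grids) - 1)
            Sigma[a] = S + (cov_shrink * np.trace(S) / basis.n + ridge) * eye

    z = np.linspace(0.0, 1.0, n_phase)
    phi = basis.phi(z)
    resid = np.stack([g - phi @ W[i] for i, g in enumerate(grids)])
    sigma_y = np.maximum(np.sqrt(np.mean(resid**2, axis=(0, 1))), noise_floor)
    return ProMPModel(basis=basis, mu_w=mu, Sigma_w=Sigma, sigma_y=sigma_y,
                      storage=list(grids), n_phase=n_phase,
                      large_prior=large_prior, ridge=ridge,
                      cov_shrink=cov_shrink)


def marginal(model: ProMPModel, z) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis Gaussian state distribution at phase(s) z.

    Returns ``(mean, var)`` of shape (len(z), 2, 3): position and phase-
    velocity rows for each axis, with variance
    Phi' Sigma_w Phi + sigma_y^2 (the noise enters the position row).
    """
    z = np.atleast_1d(np.asarray(z, float))
    if np.any(z < -1e-9) or np.any(z > 1 + 1e-9):
        raise ValueError("phase must lie in [0, 1]")
    Phi = model.basis.design(z)              # (T, 2, n)
    mean = np.einsum("tdn,an->tda", Phi, model.mu_w)
    var = np.einsum("tdn,anm,tdm->tda", Phi, model.Sigma_w, Phi)
    var[:, 0, :] += model.sigma_y**2
    return mean, var


def condition(model: ProMPModel, obs: CartesianTrajectory) -> ProMPModel:
    """Posterior model after conditioning the weights on observed points.

    ``obs.t`` holds the *phases* of the observed samples (see
    :func:`prefix`).  Standard linear-Gaussian conditioning per axis:
    the posterior precision is Sigma_w^-1 + Phi' Phi / sigma_y^2.  The
    observation noise and storage are carried over unchanged.
    """
    z_obs = np.asarray(obs.t, float)
    phi = model.basis.phi(z_obs)               # (K, n)
    n = model.basis.n
    mu_post = np.empty_like(model.mu_w)
    Sigma_post = np.empty_like(model.Sigma_w)
    for a in range(3):
        Sw = model.Sigma_w[a]
        noise = model.sigma_y[a] ** 2
        prec = np.linalg.inv(Sw) + phi.T @ phi / noise
        Sigma_post[a] = np.linalg.inv(prec)
        Sigma_post[a] = 0.5 * (Sigma_post[a] + Sigma_post[a].T)
        mu_post[a] = Sigma_post[a] @ (np.linalg.solve(Sw, model.mu_w[a])
                                      + phi.T @ obs.pos[:, a] / noise)
    return replace(model, mu_w=mu_post, Sigma_w=Sigma_post,
                   storage=list(model.storage))


def condition_and_rollout(model: ProMPModel, partial_obs: CartesianTrajectory,
                          n_points: int | None = None):
    """Condition on a trajectory prefix and roll out the full prediction.

    ``partial_obs`` carries phases in its time column (see :func:`prefix`);
    an empty prefix returns the prior rollout.  Returns ``(mean, std)``
    arrays of shape (n_points, 3) over the full phase axis; the variance
    is never negative.
    """
    n_points = n_points or model.n_phase
    z_full = np.linspace(0.0, 1.0, n_points)
    post = model if partial_obs is None or partial_obs.t.size == 0 \
        else condition(model, partial_obs)
    mean, var = marginal(post, z_full)
    return mean[:, 0, :], np.sqrt(np.clip(var[:, 0, :], 0.0, None))


def prefix(traj: CartesianTrajectory, fraction: float = 0.3) -> CartesianTrajectory:
    """First ``fraction`` of a trajectory, re-indexed by phase in [0, fraction]."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    k = max(2, int(np.ceil(fraction * traj.t.size)))
    z = np.linspace(0.0, fraction, k)
    src = (traj.t - traj.t[0]) / (traj.t[-1] - traj.t[0])
    pos = np.stack([np.interp(z, src, traj.pos[:, a]) for a in range(3)], axis=1)
    return CartesianTrajectory(t=z, pos=pos)


def update(model: ProMPModel, new_obs: CartesianTrajectory) -> ProMPModel:
    """Append an observation to the storage and refit the distribution."""
    grids = list(model.storage) + [_resample(new_obs, model.n_phase)]
    z = np.linspace(0.0, 1.0, model.n_phase)
    trajs = [CartesianTrajectory(t=z, pos=g) for g in grids]
    return fit(trajs, basis=model.basis, n_phase=model.n_phase,
               large_prior=model.large_prior, ridge=model.ridge,
               cov_shrink=model.cov_shrink)


def kl_divergence(model_a: ProMPModel, model_b: ProMPModel) -> float:
    """KL(a || b) between the stacked per-axis weight distributions."""
    if model_a.basis.n != model_b.basis.n:
        raise ValueError("models must share the basis dimension")
    total = 0.0
    n = model_a.basis.n
    for a in range(3):
        S0, S1 = model_a.Sigma_w[a], model_b.Sigma_w[a]
        m0, m1 = model_a.mu_w[a], model_b.mu_w[a]
        L1 = np.linalg.cholesky(S1 + 1e-12 * np.eye(n))
        sol = np.linalg.solve(S1, S0)
        d = m1 - m0
        mahal = d @ np.linalg.solve(S1, d)
        _, logdet0 = np.linalg.slogdet(S0 + 1e-12 * np.eye(n))
        _, logdet1 = np.linalg.slogdet(S1 + 1e-12 * np.eye(n))
        total += 0.5 * (np.trace(sol) + mahal - n + logdet1 - logdet0)
    return float(max(total, 0.0))
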