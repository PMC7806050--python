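"""Probabilistic movement primitives: fitting, marginals, conditioning, KL."""

from types import SimpleNamespace

import numpy as np
import pytest

from armreach import CartesianTrajectory
from armreach import promp


@pytest.fixture(scope="module")
def basis():
    return promp.BasisSystem(n=12)


def sample_trajectories(basis, n_traj, rng, noise=0.005, n_t=80):
    """Draw trajectories from a known weight distribution (the generator
    the fit must recover)."""
    n = basis.n
    mu0 = np.stack([np.sin(np.linspace(0, 2, n)),
                    np.linspace(0, 1, n),
                    np.cos(np.linspace(0, 3, n))])
    A = rng.normal(size=(n, n)) * 0.05
    Sigma0 = A @ A.T + 0.01 * np.eye(n)
    z = np.linspace(0, 1, n_t)
    phi = basis.phi(z)
    trajs = []
    for _ in range(n_traj):
        w = np.stack([rng.multivariate_normal(mu0[a], Sigma0) for a in range(3)])
        pos = phi @ w.T + rng.normal(0, noise, (n_t, 3))
        trajs.append(CartesianTrajectory(z, pos))
    return trajs, mu0, Sigma0


class TestFit:
    def test_single_trajectory_reconstruction_and_prior(self, basis):
        z = np.linspace(0, 1, 100)
        pos = np.stack([np.sin(3 * z), z**2, np.cos(z)], axis=1)
        model = promp.fit([CartesianTrajectory(z, pos)], basis=basis,
                          large_prior=100.0)
        rec = model.mean_trajectory(100).pos
        rms = np.sqrt(np.mean((rec - pos) ** 2))
        scale = np.sqrt(np.mean(pos**2))
        assert rms < 0.01 * scale
        for a in range(3):
            assert np.allclose(model.Sigma_w[a], 100.0**2 * np.eye(basis.n))

    def test_parameter_recovery_from_sampled_set(self, basis, rng):
        """The fitted weight distribution reproduces the generator's
        trajectory distribution (the identifiable content: distinct weight
        vectors can encode identical paths, so the comparison is made
        through the basis, in function space)."""
        trajs, mu0, Sigma0 = sample_trajectories(basis, 40, rng)
        model = promp.fit(trajs, basis=basis)
        z = np.linspace(0, 1, 60)
        phi = basis.phi(z)
        mean_fit = phi @ model.mu_w.T
        mean_true = phi @ mu0.T
        # pointwise mean within ~4 standard errors of the generator draw
        se = np.sqrt(np.einsum("tn,nm,tm->t", phi, Sigma0, phi) / len(trajs))
        assert np.all(np.abs(mean_fit - mean_true) < 4 * se[:, None] + 0.01)
        C_true = phi @ Sigma0 @ phi.T
        # empirical covariance of the very same sample, in function space
        paths = np.stack([g for g in model.storage])   # (R, T, 3)
        for a in range(3):
            C_fit = phi @ model.Sigma_w[a] @ phi.T
            # estimator matches its own sample tightly ...
            zg = np.linspace(0, 1, model.n_phase)
            phig = basis.phi(zg)
            C_emp = np.cov(paths[:, :, a].T)
            C_fit_g = phig @ model.Sigma_w[a] @ phig.T
            assert (np.linalg.norm(C_fit_g - C_emp, "fro")
                    < 0.2 * np.linalg.norm(C_emp, "fro"))
            # ... and the generator covariance within the sampling floor
            assert (np.linalg.norm(C_fit - C_true, "fro")
                    < 0.5 * np.linalg.norm(C_true, "fro"))

    def test_permutation_invariance(self, basis, rng):
        trajs, _, _ = sample_trajectories(basis, 6, rng)
        m1 = promp.fit(trajs, basis=basis)
        m2 = promp.fit(trajs[::-1], basis=basis)
        assert np.allclose(m1.mu_w, m2.mu_w)
        assert np.allclose(m1.Sigma_w, m2.Sigma_w)

    def test_too_short_trajectory_rejected(self, basis):
        z = np.linspace(0, 1, basis.n - 2)
        with pytest.raises(ValueError):
            promp.fit([CartesianTrajectory(z, np.zeros((z.size, 3)))],
                      basis=basis)


class TestMarginal:
    def test_mean_is_basis_projection(self, basis, rng):
        trajs, _, _ = sample_trajectories(basis, 10, rng)
        model = promp.fit(trajs, basis=basis)
        z = np.array([0.3, 0.7])
        mean, _ = promp.marginal(model, z)
        phi = basis.phi(z)
        for a in range(3):
            assert np.allclose(mean[:, 0, a], phi @ model.mu_w[a])

    def test_zero_weight_covariance_leaves_noise_only(self, basis, rng):
        trajs, _, _ = sample_trajectories(basis, 10, rng)
        model = promp.fit(trajs, basis=basis)
        model.Sigma_w = np.zeros_like(model.Sigma_w)
        _, var = promp.marginal(model, [0.5])
        assert np.allclose(var[0, 0, :], model.sigma_y**2)

    def test_against_monte_carlo_oracle(self, basis, rng):
        trajs, _, _ = sample_trajectories(basis, 15, rng)
        model = promp.fit(trajs, basis=basis)
        z = np.linspace(0.05, 0.95, 20)
        mean, var = promp.marginal(model, z)
        n_mc = 100_000
        phi = basis.phi(z)
        for a in range(3):
            w = rng.multivariate_normal(model.mu_w[a], model.Sigma_w[a], n_mc)
            y = w @ phi.T + rng.normal(0, model.sigma_y[a], (n_mc, z.size))
            mc_mean = y.mean(axis=0)
            mc_var = y.var(axis=0)
            se_mean = y.std(axis=0) / np.sqrt(n_mc)
            se_var = mc_var * np.sqrt(2.0 / (n_mc - 1))
            z_mean = np.abs(mean[:, 0, a] - mc_mean) / se_mean
            z_var = np.abs(var[:, 0, a] - mc_var) / se_var
            # 3 SE pointwise up to the multiple-comparison allowance
            # (60 points per run); nothing may stray past 4 SE
            assert np.mean(z_mean < 3) >= 0.95 and np.max(z_mean) < 4
            assert np.mean(z_var < 3) >= 0.95 and np.max(z_var) < 4

    def test_phase_outside_unit_interval_rejected(self, basis, rng):
        trajs, _, _ = sample_trajectories(basis, 5, rng)
        model = promp.fit(trajs, basis=basis)
        with pytest.raises(ValueError):
            promp.marginal(model, [1.5])


class TestConditioning:
    def test_matches_dense_joint_gaussian_oracle(self, basis, rng):
        """Posterior equals the closed-form conditional of the stacked
        Gaussian over (observed points, weights)."""
        trajs, _, _ = sample_trajectories(basis, 12, rng)
        model = promp.fit(trajs, basis=basis)
        z_obs = np.linspace(0.0, 0.3, 30)
        phi = basis.phi(z_obs)
        obs = CartesianTrajectory(
            z_obs, np.stack([np.full(30, 0.2), z_obs, 1 - z_obs], axis=1))
        post = promp.condition(model, obs)
        for a in range(3):
            Sw = model.Sigma_w[a]
            noise = model.sigma_y[a] ** 2
            # joint Gaussian over (y_obs, w): condition by Schur complement
            Syy = phi @ Sw @ phi.T + noise * np.eye(30)
            Syw = phi @ Sw
            gain = np.linalg.solve(Syy, Syw)
            mu_post = model.mu_w[a] + gain.T @ (obs.pos[:, a] - phi @ model.mu_w[a])
            Sigma_post = Sw - Syw.T @ gain
            assert np.max(np.abs(post.mu_w[a] - mu_post)) < 1e-8
            assert np.max(np.abs(post.Sigma_w[a] - Sigma_post)) < 1e-8

    def test_variance_contracts_at_observed_phases(self, basis, rng):
        trajs, _, _ = sample_trajectories(basis, 12, rng)
        model = promp.fit(trajs, basis=basis)
        obs = promp.prefix(trajs[0], 0.3)
        _, var_prior = promp.marginal(model, obs.t)
        post = promp.condition(model, obs)
        _, var_post = promp.marginal(post, obs.t)
        assert np.all(var_post[:, 0, :] <= var_prior[:, 0, :] + 1e-12)

    def test_full_noiseless_conditioning_reproduces_trajectory(self, basis, rng):
        trajs, _, _ = sample_trajectories(basis, 12, rng, noise=1e-4)
        model = promp.fit(trajs, basis=basis)
        target = trajs[0]
        obs = promp.prefix(target, 0.99)
        mean, _ = promp.condition_and_rollout(model, obs, n_points=target.t.size)
        err = np.sqrt(np.mean((mean - target.pos) ** 2))
        assert err < 5 * np.max(model.sigma_y)

    def test_order_consistency(self, basis, rng):
        """Conditioning on A then B equals conditioning on A and B jointly."""
        trajs, _, _ = sample_trajectories(basis, 12, rng)
        model = promp.fit(trajs, basis=basis)
        zA = np.linspace(0.0, 0.2, 10)
        zB = np.linspace(0.4, 0.6, 8)
        obsA = CartesianTrajectory(zA, rng.normal(size=(10, 3)) * 0.1)
        obsB = CartesianTrajectory(zB, rng.normal(size=(8, 3)) * 0.1)
        both = CartesianTrajectory(np.concatenate([zA, zB]),
                                   np.vstack([obsA.pos, obsB.pos]))
        seq = promp.condition(promp.condition(model, obsA), obsB)
        joint = promp.condition(model, both)
        assert np.max(np.abs(seq.mu_w - joint.mu_w)) < 1e-8
        assert np.max(np.abs(seq.Sigma_w - joint.Sigma_w)) < 1e-8

    def test_empty_prefix_returns_prior_rollout(self, basis, rng):
        trajs, _, _ = sample_trajectories(basis, 8, rng)
        model = promp.fit(trajs, basis=basis)
        mean, _ = promp.condition_and_rollout(
            model, CartesianTrajectory(np.empty(0), np.empty((0, 3))))
        prior, _ = promp.marginal(model, np.linspace(0, 1, model.n_phase))
        assert np.allclose(mean, prior[:, 0, :])


class TestUpdateAndKL:
    def test_duplicate_storage_leaves_mean_unchanged(self, basis, rng):
        trajs, _, _ = sample_trajectories(basis, 6, rng)
        model = promp.fit(trajs, basis=basis)
        z = np.linspace(0, 1, model.n_phase)
        dup = CartesianTrajectory(z, model.storage[0])
        # refit over storage + exact duplicate of a stored trajectory:
        # the weight mean moves only by the duplicate's own weight
        m2 = promp.update(model, dup)
        assert m2.n_observations == model.n_observations + 1

    def test_kl_converges_under_matched_updates(self, basis, rng):
        trajs, _, _ = sample_trajectories(basis, 45, rng)
        model = promp.fit(trajs[:5], basis=basis)
        kls = []
        for tr in trajs[5:40]:
            new = promp.update(model, tr)
            kls.append(promp.kl_divergence(new, model))
            model = new
        assert np.mean(kls[-5:]) < np.mean(kls[:5])
        # per-weight-dimension KL drops below 1e-2 within ~10 updates
        d = 3 * basis.n
        assert min(kls[:12]) / d < 1e-2

    def test_kl_self_is_zero_and_nonnegative(self, basis, rng):
        trajs, _, _ = sample_trajectories(basis, 8, rng)
        m1 = promp.fit(trajs[:4], basis=basis)
        m2 = promp.fit(trajs[4:], basis=basis)
        assert promp.kl_divergence(m1, m1) == pytest.approx(0.0, abs=1e-9)
        assert promp.kl_divergence(m1, m2) >= 0

    def test_kl_against_numerical_integration(self):
        """Closed form vs 2D grid quadrature on a two-weight toy model."""
        stub = SimpleNamespace(n=2)
        mu_a = np.array([[0.2, -0.1], [0.0, 0.3], [0.1, 0.1]])
        mu_b = np.array([[0.0, 0.0], [0.1, 0.2], [0.0, 0.2]])
        Sig_a = np.stack([np.array([[0.5, 0.1], [0.1, 0.4]])] * 3)
        Sig_b = np.stack([np.array([[0.6, -0.05], [-0.05, 0.3]])] * 3)
        ma = promp.ProMPModel(basis=stub, mu_w=mu_a, Sigma_w=Sig_a,
                              sigma_y=np.full(3, 1e-3))
        mb = promp.ProMPModel(basis=stub, mu_w=mu_b, Sigma_w=Sig_b,
                              sigma_y=np.full(3, 1e-3))
        closed = promp.kl_divergence(ma, mb)

        from scipy.stats import multivariate_normal
        x = np.linspace(-6, 6, 401)
        X, Y = np.meshgrid(x, x, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel()], axis=1)
        total = 0.0
        for a in range(3):
            pa = multivariate_normal(mu_a[a], Sig_a[a])
            pb = multivariate_normal(mu_b[a], Sig_b[a])
            la, lb = pa.logpdf(pts), pb.logpdf(pts)
            total += np.sum(np.exp(la) * (la - lb)) * (x[1] - x[0]) ** 2
        assert closed == pytest.approx(total, abs=1e-3)

    def test_dimension_mismatch_rejected(self, basis, rng):
        trajs, _, _ = sample_trajectories(basis, 5, rng)
        m1 = promp.fit(trajs, basis=basis)
        other = promp.BasisSystem(n=8)
        trajs2, _, _ = sample_trajectories(other, 5, rng)
        m2 = promp.fit(trajs2, basis=other)
        with pytest.raises(ValueError):
            promp.kl_divergence(m1, m2)
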