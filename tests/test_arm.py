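"""Arm kinematics, Lagrangian dynamics and marker geometry."""

import numpy as np
import pytest

from armreach import (ArmParameters, JointState, JointTrajectory, MarkerFrame,
                      forward_dynamics, forward_kinematics, inverse_dynamics,
                      markers_to_joint_angles, relative_endeffector_trajectory)
from armreach.arm import coriolis_matrix, gravity_vector, mass_matrix

from conftest import random_admissible_q


class TestForwardKinematics:
    def test_fully_extended(self, params):
        elbow, wrist = forward_kinematics(np.zeros(3), params)
        # stretched arm lies along the frame's +x axis
        assert np.allclose(elbow, [params.upper_arm_length, 0, 0])
        assert np.allclose(wrist, [params.total_length, 0, 0])
        # elbow collinear between shoulder and wrist
        assert np.linalg.norm(np.cross(elbow, wrist)) < 1e-12

    def test_pure_elbow_flexion(self, params):
        e0, _ = forward_kinematics(np.zeros(3), params)
        elbow, wrist = forward_kinematics([0.0, 0.0, np.pi / 2], params)
        assert np.allclose(elbow, e0)
        fore = wrist - elbow
        assert np.isclose(np.linalg.norm(fore), params.forearm_length)
        assert abs(np.dot(fore, elbow)) < 1e-12

    def test_segment_lengths_conserved(self, params, rng):
        q = random_admissible_q(params, rng, n=200)
        elbow, wrist = forward_kinematics(q, params)
        assert np.allclose(np.linalg.norm(elbow, axis=1),
                           params.upper_arm_length)
        assert np.allclose(np.linalg.norm(wrist - elbow, axis=1),
                           params.forearm_length)

    def test_rejects_nonfinite(self, params):
        with pytest.raises(ValueError):
            forward_kinematics([np.nan, 0, 0], params)


class TestDynamics:
    def test_static_torque_is_gravity(self, params, rng):
        q = random_admissible_q(params, rng)
        tau = inverse_dynamics(JointState(q, np.zeros(3), np.zeros(3)), params)
        assert np.allclose(tau, gravity_vector(q, params))

    def test_inertial_limit_without_gravity(self, rng):
        p0 = ArmParameters(gravity=0.0)
        q = random_admissible_q(p0, rng)
        ddq = rng.normal(size=3)
        tau = inverse_dynamics(JointState(q, np.zeros(3), ddq), p0)
        assert np.allclose(tau, mass_matrix(q, p0) @ ddq)

    def test_matches_euler_lagrange_oracle(self, params, rng):
        """tau agrees with numeric differentiation of the Lagrangian."""
        def lagrangian(q, dq):
            ke = 0.5 * dq @ mass_matrix(q, params) @ dq
            elbow, wrist = forward_kinematics(q, params)
            com_u = elbow / np.linalg.norm(elbow) * params.com_upper
            fore = (wrist - elbow) / np.linalg.norm(wrist - elbow)
            com_f = elbow + fore * params.com_fore
            v = params.gravity * (params.mass_upper * com_u[2]
                                  + params.mass_fore * com_f[2])
            return ke - v

        # inner/outer steps balance truncation against roundoff in the
        # nested second difference
        h, ht = 1e-5, 1e-4
        eye = np.eye(3)
        for _ in range(5):
            q = random_admissible_q(params, rng)
            dq, ddq = rng.normal(size=3), rng.normal(size=3)
            tau = inverse_dynamics(JointState(q, dq, ddq), params)

            def dl_ddq(qq, dd):
                return np.array([
                    (lagrangian(qq, dd + h * eye[i])
                     - lagrangian(qq, dd - h * eye[i])) / (2 * h)
                    for i in range(3)])

            dl_dq = np.array([
                (lagrangian(q + h * eye[i], dq)
                 - lagrangian(q - h * eye[i], dq)) / (2 * h)
                for i in range(3)])
            ddt = (dl_ddq(q + ht * dq, dq + ht * ddq)
                   - dl_ddq(q - ht * dq, dq - ht * ddq)) / (2 * ht)
            oracle = ddt - dl_dq
            assert np.max(np.abs(tau - oracle)) < 1e-6 * max(1.0, np.max(np.abs(tau)))

    def test_forward_inverse_roundtrip(self, params, rng):
        for _ in range(10):
            q = random_admissible_q(params, rng)
            dq = rng.normal(size=3)
            tau = rng.normal(size=3) * 5
            ddq = forward_dynamics(q, dq, tau, params)
            assert np.allclose(inverse_dynamics(JointState(q, dq, ddq), params),
                               tau, atol=1e-9)

    def test_gravity_compensation_gives_zero_acceleration(self, params, rng):
        q = random_admissible_q(params, rng)
        ddq = forward_dynamics(q, np.zeros(3), gravity_vector(q, params), params)
        assert np.allclose(ddq, 0.0, atol=1e-10)

    def test_prescribed_acceleration_without_gravity(self, rng):
        p0 = ArmParameters(gravity=0.0)
        q = random_admissible_q(p0, rng)
        a = rng.normal(size=3)
        ddq = forward_dynamics(q, np.zeros(3), mass_matrix(q, p0) @ a, p0)
        assert np.allclose(ddq, a, atol=1e-10)

    def test_mass_matrix_spd_over_workspace(self, params, rng):
        q = random_admissible_q(params, rng, n=10_000, margin=0.0)
        M = mass_matrix(q, params)
        assert np.allclose(M, np.swapaxes(M, -1, -2))
        assert np.min(np.linalg.eigvalsh(M)) > 0

    def test_coriolis_skew_symmetry(self, params, rng):
        """dM/dt - 2C is skew-symmetric when C uses Christoffel symbols."""
        for _ in range(20):
            q = random_admissible_q(params, rng)
            dq = rng.normal(size=3)
            h = 1e-6
            mdot = (mass_matrix(q + h * dq, params)
                    - mass_matrix(q - h * dq, params)) / (2 * h)
            s = mdot - 2 * coriolis_matrix(q, dq, params)
            assert np.max(np.abs(s + s.T)) < 1e-7

    def test_energy_conserved_without_torque_or_gravity(self, rng):
        from scipy.integrate import solve_ivp

        p0 = ArmParameters(gravity=0.0)
        q0 = random_admissible_q(p0, rng)
        dq0 = rng.normal(size=3) * 0.5

        def rhs(_, y):
            q, dq = y[:3], y[3:]
            return np.concatenate([dq, forward_dynamics(q, dq, np.zeros(3), p0)])

        sol = solve_ivp(rhs, (0, 1.0), np.concatenate([q0, dq0]),
                        rtol=1e-10, atol=1e-12, dense_output=False)
        ke = [0.5 * sol.y[3:, k] @ mass_matrix(sol.y[:3, k], p0) @ sol.y[3:, k]
              for k in (0, -1)]
        assert abs(ke[1] - ke[0]) < 1e-8 * max(ke[0], 1e-12)


class TestMarkerGeometry:
    def test_roundtrip_with_translation(self, params, rng):
        for _ in range(50):
            q = random_admissible_q(params, rng)
            elbow, wrist = forward_kinematics(q, params)
            offset = rng.normal(size=3)
            q_back = markers_to_joint_angles(
                MarkerFrame(offset, elbow + offset, wrist + offset))
            assert np.max(np.abs(q_back - q)) < 1e-9

    def test_collinear_extended_frame_is_zero(self, params):
        frame = MarkerFrame([0, 0, 0], [params.upper_arm_length, 0, 0],
                            [params.total_length, 0, 0])
        assert np.allclose(markers_to_joint_angles(frame), 0.0)

    def test_downward_elbow_gives_positive_pitch(self, params):
        """30 deg below horizontal maps to q1 = +30 deg (positive = down)."""
        u = np.array([np.cos(np.deg2rad(30)), 0.0, -np.sin(np.deg2rad(30))])
        frame = MarkerFrame(np.zeros(3), u * params.upper_arm_length,
                            u * params.total_length)
        q = markers_to_joint_angles(frame)
        assert np.isclose(np.rad2deg(q[0]), 30.0)
        assert np.allclose(q[1:], 0.0, atol=1e-12)

    def test_degenerate_frames_rejected(self):
        with pytest.raises(ValueError):
            markers_to_joint_angles(MarkerFrame(np.zeros(3), np.zeros(3),
                                                [0.3, 0, 0]))
        with pytest.raises(ValueError):
            # upper arm aligned with the yaw axis: gimbal configuration
            markers_to_joint_angles(MarkerFrame([0, 0, 0], [0, 0.3, 0],
                                                [0.2, 0.3, 0]))

    def test_frame_length_validation(self, params):
        frame = MarkerFrame([0, 0, 0], [0.5, 0, 0], [0.9, 0, 0])
        with pytest.raises(ValueError):
            frame.validate_lengths(params)


class TestRelativeEndeffector:
    def test_constant_angles_give_constant_point(self, params):
        t = np.linspace(0, 1, 30)
        q = np.tile(np.deg2rad([10.0, 20.0, 30.0]), (30, 1))
        out = relative_endeffector_trajectory(JointTrajectory(t, q), params)
        assert np.allclose(out.pos, out.pos[0])

    def test_matches_model_wrist_for_model_markers(self, params, rng):
        t = np.linspace(0, 1, 40)
        q0, q1 = (random_admissible_q(params, rng) for _ in range(2))
        s = (3 * t**2 - 2 * t**3)[:, None]
        q = q0 + s * (q1 - q0)
        _, wrist = forward_kinematics(q, params)
        obs_q = markers_to_joint_angles((np.zeros((40, 3)),
                                         forward_kinematics(q, params)[0], wrist))
        out = relative_endeffector_trajectory(JointTrajectory(t, obs_q), params)
        assert np.max(np.abs(out.pos - wrist)) < 1e-9

    def test_independent_of_subject_arm_length(self, params):
        """A 10% longer actual arm yields identical relative output."""
        t = np.linspace(0, 1, 20)
        q = np.tile(np.deg2rad([5.0, 30.0, 40.0]), (20, 1))
        q[:, 2] += np.linspace(0, 0.4, 20)
        traj = JointTrajectory(t, q)
        long_arm = params.scaled(1.1)
        _, wrist_long = forward_kinematics(q, long_arm)
        obs_q = markers_to_joint_angles(
            (np.zeros((20, 3)), forward_kinematics(q, long_arm)[0], wrist_long))
        out_long = relative_endeffector_trajectory(JointTrajectory(t, obs_q), params)
        out_model = relative_endeffector_trajectory(traj, params)
        assert np.max(np.abs(out_long.pos - out_model.pos)) < 1e-9


class TestArmParameters:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ArmParameters(upper_arm_length=-0.1)
        with pytest.raises(ValueError):
            ArmParameters(com_upper=0.5)   # beyond the segment
        with pytest.raises(ValueError):
            ArmParameters(q_min=(0.0, 0.0, 0.0), q_max=(-1.0, 1.0, 1.0))

    def test_table_postures_are_interior(self, params):
        from armreach import STARTING_POSTURES_DEG
        lo, hi = np.asarray(params.q_min), np.asarray(params.q_max)
        for post in STARTING_POSTURES_DEG:
            q = np.deg2rad(post)
            assert np.all(q > lo) and np.all(q < hi)
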