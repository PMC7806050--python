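"""3-DoF rigid-body arm model: kinematics, Lagrangian dynamics, marker geometry.

The arm is two rigid segments (upper arm, forearm) driven by three joint
angles: shoulder pitch ``q1`` (positive = downward rotation), shoulder yaw
``q2`` (positive = toward the body midline) and elbow flexion ``q3``
(zero = fully extended).  The shoulder roll degree of freedom is neglected.

Frame convention (shoulder-centered, right-handed): ``+x`` points from the
shoulder toward the reaching board, ``+y`` toward the body midline, ``+z``
up.  At ``q = 0`` the arm is fully stretched along ``+x``.

Dynamics follow the Euler-Lagrange equations

    tau = M(q) qdd + C(q, qd) qd + G(q)

with ``M`` the inertia matrix, ``C`` built from Christoffel symbols (so that
``dM/dt - 2C`` is skew-symmetric) and ``G`` the gravity torque vector.  The
closed-form expressions are derived symbolically once per process (sympy)
and evaluated through vectorized compiled callables.  Viscous friction and
tissue elasticity are neglected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

__all__ = [
    "ArmParameters",
    "JointState",
    "TorqueState",
    "DynamicsTerms",
    "MarkerFrame",
    "JointTrajectory",
    "CartesianTrajectory",
    "forward_kinematics",
    "inverse_dynamics",
    "forward_dynamics",
    "dynamics_terms",
    "markers_to_joint_angles",
    "relative_endeffector_trajectory",
]


@dataclass(frozen=True)
class ArmParameters:
    """Anthropometric and inertial parameters of the two-segment arm.

    Lengths and center-of-mass offsets are in meters (offset measured from
    the proximal joint), masses in kg, inertias in kg m^2 about the segment
    center of mass (transverse principal value; the small axial value is
    derived from ``segment_radius``), joint limits in radians.

    Defaults are documented mid-range adult values (upper arm 0.30 m /
    2.1 kg, forearm 0.33 m / 1.65 kg, center of mass at 45% of segment
    length, thin-cylinder inertias); every field is overridable per subject.
    """

    upper_arm_length: float = 0.30
    forearm_length: float = 0.33
    mass_upper: float = 2.1
    mass_fore: float = 1.65
    com_upper: float = 0.45 * 0.30
    com_fore: float = 0.45 * 0.33
    inertia_upper: float = 2.1 * 0.30**2 / 12.0
    inertia_fore: float = 1.65 * 0.33**2 / 12.0
    segment_radius: float = 0.04
    q_min: tuple = (-np.pi / 2, -np.deg2rad(10.0), 0.0)
    q_max: tuple = (np.pi / 2, np.deg2rad(120.0), np.deg2rad(150.0))
    gravity: float = 9.81

    def __post_init__(self):
        for name in ("upper_arm_length", "forearm_length", "mass_upper",
                     "mass_fore", "inertia_upper", "inertia_fore",
                     "segment_radius"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 <= self.com_upper <= self.upper_arm_length:
            raise ValueError("com_upper must lie within the upper arm")
        if not 0 <= self.com_fore <= self.forearm_length:
            raise ValueError("com_fore must lie within the forearm")
        qmin, qmax = np.asarray(self.q_min, float), np.asarray(self.q_max, float)
        if qmin.shape != (3,) or qmax.shape != (3,):
            raise ValueError("q_min/q_max must have 3 entries")
        if not np.all(qmin < qmax):
            raise ValueError("q_min must be elementwise below q_max")
        object.__setattr__(self, "q_min", tuple(qmin))
        object.__setattr__(self, "q_max", tuple(qmax))

    @property
    def total_length(self) -> float:
        return self.upper_arm_length + self.forearm_length

    def admissible(self, q) -> bool:
        q = np.asarray(q, float)
        return bool(np.all(q >= np.asarray(self.q_min) - 1e-12)
                    and np.all(q <= np.asarray(self.q_max) + 1e-12))

    def scaled(self, factor: float) -> "ArmParameters":
        """Arm with segment lengths (and com offsets) scaled by ``factor``."""
        return ArmParameters(
            upper_arm_length=self.upper_arm_length * factor,
            forearm_length=self.forearm_length * factor,
            mass_upper=self.mass_upper, mass_fore=self.mass_fore,
            com_upper=self.com_upper * factor, com_fore=self.com_fore * factor,
            inertia_upper=self.inertia_upper, inertia_fore=self.inertia_fore,
            segment_radius=self.segment_radius,
            q_min=self.q_min, q_max=self.q_max, gravity=self.gravity)

    def _numeric(self) -> tuple:
        # axial inertia of a thin solid cylinder about its long axis
        iau = 0.5 * self.mass_upper * self.segment_radius**2
        iaf = 0.5 * self.mass_fore * self.segment_radius**2
        return (self.upper_arm_length, self.forearm_length,
                self.mass_upper, self.mass_fore,
                self.com_upper, self.com_fore,
                self.inertia_upper, self.inertia_fore,
                iau, iaf, self.gravity)


@dataclass
class JointState:
    q: np.ndarray
    dq: np.ndarray
    ddq: np.ndarray

    def __post_init__(self):
        self.q = np.asarray(self.q, float).reshape(3)
        self.dq = np.asarray(self.dq, float).reshape(3)
        self.ddq = np.asarray(self.ddq, float).reshape(3)
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.dq))
                and np.all(np.isfinite(self.ddq))):
            raise ValueError("joint state must be finite")


@dataclass
class TorqueState:
    tau: np.ndarray
    dtau: np.ndarray | None = None


@dataclass
class DynamicsTerms:
    M: np.ndarray
    C: np.ndarray
    Gvec: np.ndarray


@dataclass
class MarkerFrame:
    """Shoulder, elbow and wrist 3D positions at one time stamp (meters)."""

    t_s: np.ndarray
    t_e: np.ndarray
    t_w: np.ndarray

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, float).reshape(3)
        self.t_e = np.asarray(self.t_e, float).reshape(3)
        self.t_w = np.asarray(self.t_w, float).reshape(3)

    def validate_lengths(self, params: ArmParameters, tol: float = 0.05):
        du = np.linalg.norm(self.t_e - self.t_s)
        df = np.linalg.norm(self.t_w - self.t_e)
        if abs(du - params.upper_arm_length) > tol * params.upper_arm_length:
            raise ValueError("upper-arm marker distance inconsistent with model")
        if abs(df - params.forearm_length) > tol * params.forearm_length:
            raise ValueError("forearm marker distance inconsistent with model")


@dataclass
class JointTrajectory:
    """Uniformly sampled joint-angle trajectory q(t), angles in radians."""

    t: np.ndarray
    q: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, float).reshape(-1)
        self.q = np.asarray(self.q, float)
        if self.q.shape != (self.t.size, 3):
            raise ValueError("q must have shape (len(t), 3)")
        if self.t.size >= 2:
            dt = np.diff(self.t)
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise ValueError("time base must be uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def derivative(self, order: int = 1) -> np.ndarray:
        out = self.q
        for _ in range(order):
            out = np.gradient(out, self.dt, axis=0, edge_order=2)
        return out


@dataclass
class CartesianTrajectory:
    """Uniformly sampled 3D point trajectory (meters)."""

    t: np.ndarray
    pos: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, float).reshape(-1)
        self.pos = np.asarray(self.pos, float)
        if self.pos.shape != (self.t.size, 3):
            raise ValueError("pos must have shape (len(t), 3)")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])


# --------------------------------------------------------------------------
# symbolic derivation (done once per process)

@lru_cache(maxsize=1)
def _compiled_dynamics():
    import sympy as sp

    q1, q2, q3 = sp.symbols("q1 q2 q3", real=True)
    d1, d2, d3 = sp.symbols("d1 d2 d3", real=True)
    lu, lf, mu, mf, cu, cf, Iu, If_, Iau, Iaf, g = sp.symbols(
        "lu lf mu mf cu cf Iu If Iau Iaf g", positive=True)

    qv = sp.Matrix([q1, q2, q3])
    dv = sp.Matrix([d1, d2, d3])

    def Ry(a):
        return sp.Matrix([[sp.cos(a), 0, -sp.sin(a)],
                          [0, 1, 0],
                          [sp.sin(a), 0, sp.cos(a)]])

    def Rz(a):
        return sp.Matrix([[sp.cos(a), -sp.sin(a), 0],
                          [sp.sin(a), sp.cos(a), 0],
                          [0, 0, 1]])

    # positive q1 rotates +x downward (toward -z): inverse of standard Ry
    Ru = Ry(-q1) * Rz(q2)
    Rf = Ru * Rz(q3)
    ex = sp.Matrix([1, 0, 0])
    ey = sp.Matrix([0, 1, 0])
    ez = sp.Matrix([0, 0, 1])

    # world-frame angular velocities (rotation axes expressed in world)
    w_u = (-ey) * d1 + (Ry(-q1) * ez) * d2
    w_f = w_u + (Ru * ez) * d3

    p_cu = cu * (Ru * ex)
    elbow = lu * (Ru * ex)
    p_cf = elbow + cf * (Rf * ex)

    def vel(p):
        J = p.jacobian(qv)
        return J * dv

    v_cu = vel(p_cu)
    v_cf = vel(p_cf)

    Ibu = sp.diag(Iau, Iu, Iu)   # body frame, x longitudinal
    Ibf = sp.diag(Iaf, If_, If_)
    KE = (mu * (v_cu.T * v_cu)[0] + mf * (v_cf.T * v_cf)[0]
          + (w_u.T * Ru * Ibu * Ru.T * w_u)[0]
          + (w_f.T * Rf * Ibf * Rf.T * w_f)[0]) / 2
    V = g * (mu * p_cu[2] + mf * p_cf[2])

    M = sp.hessian(KE, dv)
    Gv = sp.Matrix([sp.diff(V, s) for s in qv])
    dMdq = [M.diff(s) for s in qv]  # list of 3x3

    args = (q1, q2, q3, lu, lf, mu, mf, cu, cf, Iu, If_, Iau, Iaf, g)
    M_exprs = [sp.expand_trig(e) for e in M]
    G_exprs = list(Gv)
    dM_exprs = [e for Mk in dMdq for e in Mk]

    fM = sp.lambdify(args, M_exprs, modules="numpy", cse=True)
    fG = sp.lambdify(args, G_exprs, modules="numpy", cse=True)
    fdM = sp.lambdify(args, dM_exprs, modules="numpy", cse=True)
    # fused evaluation: M, G and dM/dq share most trigonometric
    # subexpressions, so one cse pass over all of them is ~3x cheaper
    # than three separate calls (this dominates the OCP runtime)
    fAll = sp.lambdify(args, M_exprs + G_exprs + dM_exprs,
                       modules="numpy", cse=True)
    return fM, fG, fdM, fAll


@lru_cache(maxsize=1)
def _compiled_wrist_jerk():
    """Exact third time derivative of the wrist position via the chain rule."""
    import sympy as sp

    t = sp.Symbol("t")
    qf = [sp.Function(f"qf{i}")(t) for i in range(3)]
    lu, lf = sp.symbols("lu lf", positive=True)

    def Ry(a):
        return sp.Matrix([[sp.cos(a), 0, sp.sin(a)],
                          [0, 1, 0],
                          [-sp.sin(a), 0, sp.cos(a)]])

    def Rz(a):
        return sp.Matrix([[sp.cos(a), -sp.sin(a), 0],
                          [sp.sin(a), sp.cos(a), 0],
                          [0, 0, 1]])

    ex = sp.Matrix([1, 0, 0])
    Ru = Ry(qf[0]) * Rz(qf[1])
    wrist = lu * (Ru * ex) + lf * (Ru * Rz(qf[2]) * ex)
    jerk = wrist.diff(t, 3)

    syms = []
    subs = []
    for i in range(3):
        qi, di, ai, ji = sp.symbols(f"q{i} d{i} a{i} j{i}", real=True)
        syms += [qi, di, ai, ji]
        subs += [(qf[i].diff(t, 3), ji), (qf[i].diff(t, 2), ai),
                 (qf[i].diff(t), di), (qf[i], qi)]
    jerk = jerk.subs(subs)
    args = tuple(syms) + (lu, lf)
    return sp.lambdify(args, list(jerk), modules="numpy", cse=True)


def wrist_jerk(q, dq, ddq, dddq, params: ArmParameters) -> np.ndarray:
    """Cartesian jerk of the wrist for batched joint states, shape (..., 3)."""
    fn = _compiled_wrist_jerk()
    q, dq, ddq, dddq = (np.asarray(a, float) for a in (q, dq, ddq, dddq))
    args = []
    for i in range(3):
        args += [q[..., i], dq[..., i], ddq[..., i], dddq[..., i]]
    vals = fn(*args, params.upper_arm_length, params.forearm_length)
    out = np.empty(q.shape)
    for i, v in enumerate(vals):
        out[..., i] = v
    return out


def _eval_stack(fn, q, par, shape):
    q = np.asarray(q, float)
    q1, q2, q3 = q[..., 0], q[..., 1], q[..., 2]
    vals = fn(q1, q2, q3, *par)
    out = np.empty(q.shape[:-1] + (len(vals),))
    for i, v in enumerate(vals):
        out[..., i] = v
    return out.reshape(q.shape[:-1] + shape)


def mass_matrix(q, params: ArmParameters) -> np.ndarray:
    """Inertia matrix M(q); batched over leading axes of ``q``."""
    fM, _, _, _ = _compiled_dynamics()
    return _eval_stack(fM, q, params._numeric(), (3, 3))


def gravity_vector(q, params: ArmParameters) -> np.ndarray:
    _, fG, _, _ = _compiled_dynamics()
    return _eval_stack(fG, q, params._numeric(), (3,))


def _dMdq(q, params: ArmParameters) -> np.ndarray:
    # shape (..., 3, 3, 3): axis -3 indexes the differentiation variable k
    _, _, fdM, _ = _compiled_dynamics()
    return _eval_stack(fdM, q, params._numeric(), (3, 3, 3))


def dynamics_bundle(q, params: ArmParameters):
    """Fused evaluation of (M, Gvec, dM/dq) for batched q."""
    _, _, _, fAll = _compiled_dynamics()
    flat = _eval_stack(fAll, q, params._numeric(), (39,))
    q = np.asarray(q, float)
    lead = q.shape[:-1]
    M = flat[..., :9].reshape(lead + (3, 3))
    G = flat[..., 9:12]
    dM = flat[..., 12:].reshape(lead + (3, 3, 3))
    return M, G, dM


def _coriolis_from_dM(dM: np.ndarray, dq) -> np.ndarray:
    dq = np.asarray(dq, float)
    term1 = np.moveaxis(dM, -3, -1)
    term2 = np.swapaxes(term1, -1, -2)
    term3 = np.swapaxes(term1, -3, -1)
    c = 0.5 * (term1 + term2 - term3)
    return np.einsum("...ijk,...k->...ij", c, dq)


def coriolis_matrix(q, dq, params: ArmParameters) -> np.ndarray:
    """C(q, qd) from Christoffel symbols of the first kind:
    c_ijk = (dM_ij/dq_k + dM_ik/dq_j - dM_jk/dq_i) / 2."""
    return _coriolis_from_dM(_dMdq(q, params), dq)


def dynamics_terms(q, dq, params: ArmParameters) -> DynamicsTerms:
    return DynamicsTerms(M=mass_matrix(q, params),
                         C=coriolis_matrix(q, dq, params),
                         Gvec=gravity_vector(q, params))


def inverse_dynamics(state: JointState | tuple, params: ArmParameters) -> np.ndarray:
    """Joint torques tau = M qdd + C qd + G for one state or a batch."""
    if isinstance(state, JointState):
        q, dq, ddq = state.q, state.dq, state.ddq
    else:
        q, dq, ddq = (np.asarray(a, float) for a in state)
    if not (np.all(np.isfinite(q)) and np.all(np.isfinite(dq))
            and np.all(np.isfinite(ddq))):
        raise ValueError("state must be finite")
    M, G, dM = dynamics_bundle(q, params)
    C = _coriolis_from_dM(dM, dq)
    return (np.einsum("...ij,...j->...i", M, ddq)
            + np.einsum("...ij,...j->...i", C, dq) + G)


def forward_dynamics(q, dq, tau, params: ArmParameters) -> np.ndarray:
    """Joint accelerations from torques (algebraic inversion of the dynamics)."""
    q = np.asarray(q, float)
    M, G, dM = dynamics_bundle(q, params)
    C = _coriolis_from_dM(dM, dq)
    rhs = np.asarray(tau, float) - np.einsum("...ij,...j->...i", C, dq) - G
    return np.linalg.solve(M, rhs[..., None])[..., 0]


# --------------------------------------------------------------------------
# kinematics

def _rot_y(a):
    ca, sa = np.cos(a), np.sin(a)
    zero, one = np.zeros_like(ca), np.ones_like(ca)
    return np.stack([np.stack([ca, zero, sa], -1),
                     np.stack([zero, one, zero], -1),
                     np.stack([-sa, zero, ca], -1)], -2)


def _rot_z(a):
    ca, sa = np.cos(a), np.sin(a)
    zero, one = np.zeros_like(ca), np.ones_like(ca)
    return np.stack([np.stack([ca, -sa, zero], -1),
                     np.stack([sa, ca, zero], -1),
                     np.stack([zero, zero, one], -1)], -2)


def forward_kinematics(q, params: ArmParameters):
    """Elbow and wrist positions in the shoulder-centered arm frame.

    ``q`` may be a single 3-vector or an (..., 3) batch.  Returns
    ``(elbow, wrist)`` with matching leading shape.
    """
    q = np.asarray(q, float)
    if not np.all(np.isfinite(q)):
        raise ValueError("q must be finite")
    Ru = _rot_y(q[..., 0]) @ _rot_z(q[..., 1])
    Rf = Ru @ _rot_z(q[..., 2])
    elbow = params.upper_arm_length * Ru[..., :, 0]
    wrist = elbow + params.forearm_length * Rf[..., :, 0]
    return elbow, wrist


def markers_to_joint_angles(frame, gimbal_tol: float = 1e-8) -> np.ndarray:
    """Joint angles from shoulder/elbow/wrist marker positions.

    Accepts a :class:`MarkerFrame` or a tuple of three (..., 3) arrays.
    Shoulder roll (rotation of the forearm plane about the upper-arm axis)
    is the neglected degree of freedom and is discarded.  Translation of the
    whole frame leaves the result unchanged.

    Raises ``ValueError`` for degenerate geometry (zero-length segments or
    gimbal alignment of the upper arm with the yaw axis); callers handling
    sampled data should interpolate over flagged samples.
    """
    if isinstance(frame, MarkerFrame):
        t_s, t_e, t_w = frame.t_s, frame.t_e, frame.t_w
    else:
        t_s, t_e, t_w = (np.asarray(a, float) for a in frame)
    v1 = t_e - t_s
    v2 = t_w - t_e
    n1 = np.linalg.norm(v1, axis=-1, keepdims=True)
    n2 = np.linalg.norm(v2, axis=-1, keepdims=True)
    if np.any(n1 < 1e-12) or np.any(n2 < 1e-12):
        raise ValueError("degenerate marker geometry: zero-length segment")
    u = v1 / n1
    uy = np.clip(u[..., 1], -1.0, 1.0)
    q2 = np.arcsin(uy)
    cxz = np.hypot(u[..., 0], u[..., 2])
    if np.any(cxz < gimbal_tol):
        raise ValueError("degenerate marker geometry: gimbal configuration")
    q1 = np.arctan2(-u[..., 2], u[..., 0])
    # (q1, q2) and (q1 - pi*sign(q1), pi*sign(q2) - q2) encode the same
    # upper-arm direction; pick the branch with |q1| <= pi/2, matching the
    # shoulder-pitch limit (yaw may exceed 90 deg, pitch may not)
    flip = np.abs(q1) > np.pi / 2
    q1 = np.where(flip, q1 - np.pi * np.sign(q1), q1)
    q2 = np.where(flip, np.pi * np.where(q2 >= 0, 1.0, -1.0) - q2, q2)
    # forearm direction in the upper-arm local frame
    Ru = _rot_y(q1) @ _rot_z(q2)
    w = np.einsum("...ji,...j->...i", Ru, v2 / n2)
    q3 = np.arctan2(w[..., 1], w[..., 0])
    return np.stack([q1, q2, q3], axis=-1)


def relative_endeffector_trajectory(q_obs: JointTrajectory,
                                    params: ArmParameters) -> CartesianTrajectory:
    """Wrist path re-projected through the model's own forward kinematics.

    Mapping observed joint angles back through the model geometry removes
    the effect of the subject's true arm length and of torso translation:
    the output lives in the shoulder-centered model frame and depends only
    on ``q_obs`` and the model parameters.
    """
    _, wrist = forward_kinematics(q_obs.q, params)
    return CartesianTrajectory(t=q_obs.t, pos=wrist)
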