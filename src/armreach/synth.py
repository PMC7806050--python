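"""Synthetic reaching data emulating the two mocap experiment designs.

No public recordings accompany the reaching experiments this package
models, so recovery studies run on synthetic subjects: reaches generated
by the package's own optimal-control rollouts under a known ("planted")
weight vector, then corrupted by the uncertainty sources a real pipeline
faces — per-reach weight jitter (motor variability at the planning
level), additive Gaussian marker noise, a subject arm longer or shorter
than the model's, and slow shoulder-translation drift (torso sway).  A
manifest records every ground truth, so any recovery experiment can be
scored without regeneration.

Two experiment templates are provided:

- a task grid crossing starting postures with board targets (the full
  design is 12 postures x 9 targets = 108 reaches);
- a repeated pick-and-place stream toward a few targets (4 targets x 4
  placements x 10 repetitions = 160 reaches, 40 per target), used by the
  online prediction experiment.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares

from .arm import (ArmParameters, CartesianTrajectory, forward_kinematics,
                  JointTrajectory)
from .costs import ScalarFactors, WeightVector
from .io import MarkerTrajectory, write_trajectory
from .ocp import OCPSettings, OCPTask, solve_ocp

__all__ = ["STARTING_POSTURES_DEG", "SubjectProfile", "TaskGrid",
           "build_task_grid", "board_targets", "inverse_kinematics",
           "generate_subject_reaches", "generate_reach_set"]

# Measured mean starting joint-angle configurations (degrees) of the twelve
# experiment postures P1-P12: three shoulder-pitch levels (middle/up/down)
# crossed with two shoulder-yaw and two elbow-flexion levels.
STARTING_POSTURES_DEG = (
    (10.95, 6.58, 12.72),
    (11.21, 8.78, 33.39),
    (11.93, 31.90, 13.15),
    (13.00, 34.45, 37.92),
    (-22.29, 12.46, 14.11),
    (-23.47, 15.82, 37.88),
    (-22.89, 37.31, 16.10),
    (-23.64, 41.07, 35.75),
    (42.15, 6.98, 12.28),
    (40.22, 7.08, 35.40),
    (35.36, 36.14, 10.06),
    (35.14, 36.88, 43.44),
)


@dataclass(frozen=True)
class SubjectProfile:
    """Generative description of one synthetic subject."""

    alpha_subject: tuple = (0.2, 0.4, 0.2, 0.1, 0.1)
    arm_scale: float = 1.0            # subject arm length / model arm length
    weight_jitter: float = 0.02       # per-reach sd added to alpha on the simplex
    motor_noise_sigma: float = 0.002  # m, iid Gaussian on marker positions
    shoulder_drift_amp: float = 0.01  # m, slow sinusoidal torso sway
    seed: int = 0

    def __post_init__(self):
        a = np.asarray(self.alpha_subject, float)
        if a.shape != (5,) or np.any(a < 0) or abs(a.sum() - 1.0) > 1e-9:
            raise ValueError("alpha_subject must lie on the 5-simplex")
        if self.arm_scale <= 0:
            raise ValueError("arm_scale must be positive")
        for name in ("weight_jitter", "motor_noise_sigma", "shoulder_drift_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class TaskGrid:
    tasks: list                      # OCPTask per admissible (posture, target)
    excluded: list = field(default_factory=list)

    def __len__(self):
        return len(self.tasks)


def board_targets(params: ArmParameters, n_side: int = 3,
                  spacing: float = 0.125, board_fraction: float = 0.8):
    """Target points on a vertical board in front of the subject.

    At zero joint angles the arm hangs stretched to the side (+x), so the
    facing direction is +y: the board plane sits at ``board_fraction`` of
    the total arm length along +y, and targets form an ``n_side x n_side``
    grid around the reference point (the shoulder's perpendicular
    projection onto the board), offset horizontally (x) and vertically (z).
    """
    y = board_fraction * params.total_length
    offs = (np.arange(n_side) - (n_side - 1) / 2) * spacing
    # columns sit half a spacing toward the arm side: without a shoulder
    # roll DoF, targets exactly in the reference-point column need |q1| =
    # 90 deg (the joint-limit boundary), so the grid avoids that column
    xoffs = offs + spacing / 2
    return [np.array([dx, y, dz]) for dz in offs[::-1] for dx in xoffs]


def inverse_kinematics(target, params: ArmParameters, q_init=None,
                       tol: float = 1e-6):
    """Joint angles placing the wrist at ``target`` (shoulder frame).

    Bounded least squares from ``q_init`` (default mid-range); returns
    ``None`` when the target is unreachable within the joint limits.
    """
    target = np.asarray(target, float)
    if np.linalg.norm(target) > params.total_length - 1e-9:
        return None
    lo, hi = np.asarray(params.q_min), np.asarray(params.q_max)
    x0 = np.clip(np.asarray(q_init, float) if q_init is not None
                 else (lo + hi) / 2, lo, hi)

    def resid(q):
        return forward_kinematics(q, params)[1] - target

    seeds = [x0] + [lo + (hi - lo) * f for f in (0.25, 0.5, 0.75)]
    best = None
    for seed in seeds:
        res = least_squares(resid, seed, bounds=(lo, hi), xtol=1e-12,
                            ftol=1e-12)
        if best is None or np.linalg.norm(res.fun) < np.linalg.norm(best.fun):
            best = res
        if np.linalg.norm(best.fun) <= tol:
            break
    if np.linalg.norm(best.fun) > tol:
        return None
    return best.x


def build_task_grid(postures_deg=STARTING_POSTURES_DEG, targets=None,
                    params: ArmParameters | None = None,
                    duration: float = 1.0, n_nodes: int = 50) -> TaskGrid:
    """Cross product of starting postures and board targets.

    Final joint configurations come from inverse kinematics seeded at the
    starting posture; unreachable targets are excluded with a record in
    ``grid.excluded``.
    """
    params = params or ArmParameters()
    targets = targets if targets is not None else board_targets(params)
    if len(postures_deg) == 0 or len(targets) == 0:
        raise ValueError("postures and targets must be nonempty")
    tasks, excluded = [], []
    for pi, post in enumerate(postures_deg):
        qs = np.deg2rad(np.asarray(post, float))
        if not params.admissible(qs):
            raise ValueError(f"posture {pi} outside the joint limits")
        for ti, tgt in enumerate(targets):
            qe = inverse_kinematics(tgt, params, q_init=qs)
            if qe is None:
                excluded.append((pi, ti, "unreachable"))
                continue
            tasks.append(OCPTask(tuple(qs), tuple(qe), duration,
                                 n_nodes=n_nodes))
    if excluded:
        import logging
        logging.getLogger(__name__).warning(
            "%d posture/target pairs excluded as unreachable", len(excluded))
    return TaskGrid(tasks=tasks, excluded=excluded)


def _jitter_simplex(alpha: np.ndarray, scale: float,
                    rng: np.random.Generator) -> np.ndarray:
    if scale == 0:
        return alpha.copy()
    a = np.clip(alpha + rng.normal(0.0, scale, 5), 1e-4, None)
    return a / a.sum()


def _reach_markers(sol, profile: SubjectProfile, params: ArmParameters,
                   rng: np.random.Generator, rate: float) -> MarkerTrajectory:
    """Map an OCP rollout to noisy subject markers at the mocap rate."""
    T = sol.task.duration
    t_fine = np.arange(0.0, T + 0.5 / rate, 1.0 / rate)
    t_fine = t_fine[t_fine <= T + 1e-12]
    q_fine = CubicSpline(sol.t, sol.q, axis=0)(t_fine)
    subject_arm = params.scaled(profile.arm_scale)
    elbow, wrist = forward_kinematics(q_fine, subject_arm)
    phase = rng.uniform(0.0, 2 * np.pi, 3)
    freq = 0.3  # Hz, slow torso sway
    drift = profile.shoulder_drift_amp * np.sin(
        2 * np.pi * freq * t_fine[:, None] + phase[None, :])
    shoulder = drift
    elbow = elbow + drift
    wrist = wrist + drift
    if profile.motor_noise_sigma > 0:
        shoulder = shoulder + rng.normal(0, profile.motor_noise_sigma, shoulder.shape)
        elbow = elbow + rng.normal(0, profile.motor_noise_sigma, elbow.shape)
        wrist = wrist + rng.normal(0, profile.motor_noise_sigma, wrist.shape)
    return MarkerTrajectory(t=t_fine, shoulder=shoulder, elbow=elbow,
                            wrist=wrist)


def generate_reach_set(profile: SubjectProfile, tasks: list,
                       params: ArmParameters,
                       settings: OCPSettings | None = None,
                       scalar_factors: dict | None = None,
                       rate: float = 250.0):
    """In-memory synthetic reaches: (MarkerTrajectory, planted alpha) pairs.

    ``scalar_factors`` maps task keys to pre-calibrated ScalarFactors; by
    default unit factors are used (the planted weights are then expressed
    on the unbalanced scale, which is fine for self-contained recovery
    experiments that reuse the same factors).
    """
    rng = np.random.default_rng(profile.seed)
    alpha0 = np.asarray(profile.alpha_subject, float)
    out = []
    skipped = []
    for task in tasks:
        a = _jitter_simplex(alpha0, profile.weight_jitter, rng)
        S = (scalar_factors or {}).get(task.key, ScalarFactors.ones())
        sol = solve_ocp(task, WeightVector(tuple(a)), S, params, settings)
        if sol.status == "infeasible":
            skipped.append(task.key)
            continue
        out.append((_reach_markers(sol, profile, params, rng, rate), a))
    if skipped:
        import logging
        logging.getLogger(__name__).warning("%d tasks skipped", len(skipped))
    return out


def generate_subject_reaches(profile: SubjectProfile, grid: TaskGrid,
                             reps: int, params: ArmParameters,
                             out_dir, settings: OCPSettings | None = None,
                             scalar_factors: dict | None = None,
                             rate: float = 250.0) -> Path:
    """Write ``reps`` noisy reaches per grid task as TSV plus a manifest.

    The manifest (JSON) records the profile, the seed, and the planted
    per-reach weight vector for every file, sufficient to score any
    recovery experiment without regeneration.  Fixed seed implies
    bit-identical output files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tasks = [t for t in grid.tasks for _ in range(reps)]
    reaches = generate_reach_set(profile, tasks, params, settings,
                                 scalar_factors, rate)
    manifest = {
        "profile": {
            "alpha_subject": list(profile.alpha_subject),
            "arm_scale": profile.arm_scale,
            "weight_jitter": profile.weight_jitter,
            "motor_noise_sigma": profile.motor_noise_sigma,
            "shoulder_drift_amp": profile.shoulder_drift_amp,
            "seed": profile.seed,
        },
        "rate_hz": rate,
        "reaches": [],
    }
    for i, ((markers, alpha), task) in enumerate(zip(reaches, tasks)):
        name = f"reach_{i:04d}.tsv"
        write_trajectory(markers, out_dir / name)
        manifest["reaches"].append({
            "file": name,
            "q_start_rad": list(task.q_start),
            "q_end_rad": list(task.q_end),
            "duration_s": task.duration,
            "alpha_true": alpha.tolist(),
        })
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path
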