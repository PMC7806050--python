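"""Hybrid online prediction: optimal-control prior + ProMP learning loop.

For a known reaching task the session is initialized from the model-based
side: the weight map predicts a cost-weight vector, the corresponding OCP
rollout seeds a single-trajectory ProMP with a wide prior.  Online, each
incoming observation is first predicted from its opening fraction
(conditioning the pre-update ProMP — honest forecasting), then absorbed
into the model; the KL divergence between successive weight distributions
monitors convergence.  Once the distribution is stable, the mean
trajectory is handed back to the inverse-optimal-control stage, and the
resulting person-specific weight vector updates a per-subject copy of the
weight map.  Deliberately, no correction is applied at initialization for
shoulder translation or arm-length mismatch: the update loop absorbs
those errors within the first few observations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arm import (ArmParameters, CartesianTrajectory, JointTrajectory,
                  markers_to_joint_angles, relative_endeffector_trajectory)
from .costs import ScalarFactors, WeightVector
from .io import MarkerTrajectory
from .ioc import IOCSettings, calibrate_scalar_factors, ioc_fit
from .metrics import dtw_distance
from .ocp import OCPSettings, OCPTask, solve_ocp
from . import promp
from .weight_map import WeightMapModel, predict_weights, update_with_subject

__all__ = ["SessionSettings", "SessionState", "FinalizeReport",
           "initialize_session", "observe_and_predict",
           "finalize_and_update_weights"]


@dataclass(frozen=True)
class SessionSettings:
    prefix_fraction: float = 0.3
    kl_threshold: float = 0.01    # on the per-weight-dimension KL
    kl_window: int = 3
    n_phase: int = 50
    large_prior: float = 100.0
    ocp: OCPSettings = field(default_factory=OCPSettings)


@dataclass
class SessionState:
    task: OCPTask
    params: ArmParameters
    settings: SessionSettings
    model: promp.ProMPModel
    alpha_init: WeightVector
    scalar_factors: ScalarFactors
    weight_map: WeightMapModel
    subject: str = "S1"
    n_observations: int = 0
    kl_trace: list = field(default_factory=list)
    error_trace: list = field(default_factory=list)
    rel_storage: list = field(default_factory=list)   # relative trajectories
    converged: bool = False

    def _check_convergence(self):
        w = self.settings.kl_window
        if len(self.kl_trace) >= w and all(
                k < self.settings.kl_threshold for k in self.kl_trace[-w:]):
            self.converged = True


def initialize_session(task: OCPTask, weight_map: WeightMapModel,
                       params: ArmParameters,
                       settings: SessionSettings | None = None,
                       subject: str = "S1",
                       scalar_factors: ScalarFactors | None = None) -> SessionState:
    """Create a session from the weight-map prediction for the task.

    The predicted mean weight vector drives one OCP solve; its relative
    end-effector trajectory becomes the single ProMP demonstration, with
    the weight variance set to the configured large prior.
    """
    settings = settings or SessionSettings()
    alpha, _ = predict_weights(weight_map, task.q_start, task.q_end)
    S = scalar_factors or calibrate_scalar_factors(task, params, settings.ocp)
    sol = solve_ocp(task, alpha, S, params, settings.ocp)
    if sol.status == "infeasible":
        raise RuntimeError(f"initialization OCP failed: {sol.status}")
    model = promp.fit([sol.endeffector], n_phase=settings.n_phase,
                      large_prior=settings.large_prior)
    return SessionState(task=task, params=params, settings=settings,
                        model=model, alpha_init=alpha, scalar_factors=S,
                        weight_map=weight_map, subject=subject)


def observe_and_predict(session: SessionState, observation):
    """Predict the incoming reach from its opening fraction, then learn it.

    ``observation`` is a :class:`MarkerTrajectory` (preferred: the wrist
    path drives prediction, and the marker-derived *relative* trajectory
    is stored for the weight update, free of arm-length and torso
    effects) or a bare wrist :class:`CartesianTrajectory`.

    Returns ``(mean, std)`` over the full phase axis, produced by the
    pre-update model.  The observation is then added to the storage, the
    ProMP refit, the prediction error (per-step DTW of predicted mean
    vs. the observation) and the KL step appended, and convergence
    re-checked.  Malformed observations are rejected with the session
    unchanged.
    """
    relative = None
    if isinstance(observation, MarkerTrajectory):
        markers = observation
        q_obs = markers_to_joint_angles((markers.shoulder, markers.elbow,
                                         markers.wrist))
        relative = relative_endeffector_trajectory(
            JointTrajectory(markers.t, q_obs), session.params)
        observation = CartesianTrajectory(markers.t, markers.wrist)
    elif not isinstance(observation, CartesianTrajectory):
        raise TypeError("observation must be a Marker- or CartesianTrajectory")
    if observation.t.size < 4 or not np.all(np.isfinite(observation.pos)):
        raise ValueError("malformed observation")

    part = promp.prefix(observation, session.settings.prefix_fraction)
    # roll out at the observation's own sampling so the DTW error is not
    # floored by a resolution mismatch between the two point sets
    mean, std = promp.condition_and_rollout(session.model, part,
                                            n_points=observation.t.size)
    pred = CartesianTrajectory(t=np.linspace(0, 1, mean.shape[0]), pos=mean)
    err = dtw_distance(pred, observation).normalized

    new_model = promp.update(session.model, observation)
    # per-weight-dimension KL: a dimension-free convergence measure (the
    # raw KL between successive refits scales with the weight dimension)
    kl = promp.kl_divergence(new_model, session.model) / (3 * session.model.basis.n)
    session.model = new_model
    session.n_observations += 1
    session.kl_trace.append(kl)
    session.error_trace.append(err)
    if relative is not None:
        session.rel_storage.append(relative)
    session._check_convergence()
    return (mean, std), session


@dataclass
class FinalizeReport:
    alpha_n: WeightVector
    updated_map: WeightMapModel
    dtw_before: float
    dtw_after: float
    ioc_traces: list


def finalize_and_update_weights(session: SessionState,
                                ioc_settings: IOCSettings | None = None,
                                force: bool = False) -> FinalizeReport:
    """Run the person-specific weight update from the converged mean.

    Extracts the converged mean trajectory t_m, fits a new weight vector
    to it by inverse optimal control, updates a per-subject copy of the
    weight map, and reports the DTW errors of the before/after OCP
    rollouts against t_m.  Raises unless the session has converged (or
    ``force`` is set).  The expensive IOC job runs synchronously here;
    callers wanting a live session during the update should run this in a
    worker process.
    """
    if not session.converged and not force:
        raise RuntimeError("session has not converged; pass force=True to override")
    ioc_settings = ioc_settings or IOCSettings(ocp=session.settings.ocp)
    if session.rel_storage:
        # mean of the relative-trajectory distribution: arm-length and
        # torso effects removed, directly comparable to OCP rollouts
        rel_model = promp.fit(session.rel_storage,
                              n_phase=session.settings.n_phase)
        t_m = rel_model.mean_trajectory(session.task.n_nodes)
    else:
        t_m = session.model.mean_trajectory(session.task.n_nodes)
    t_m = CartesianTrajectory(t=t_m.t * session.task.duration, pos=t_m.pos)

    result = ioc_fit(t_m, session.task, session.params, ioc_settings,
                     scalar_factors=session.scalar_factors)
    alpha_n = result.alpha_star

    before = solve_ocp(session.task, session.alpha_init,
                       session.scalar_factors, session.params,
                       session.settings.ocp)
    after = solve_ocp(session.task, alpha_n, session.scalar_factors,
                      session.params, session.settings.ocp)
    dtw_before = dtw_distance(before.endeffector, t_m).dtw_value
    dtw_after = dtw_distance(after.endeffector, t_m).dtw_value

    updated = update_with_subject(session.weight_map, session.task.q_start,
                                  session.task.q_end, alpha_n,
                                  subject=session.subject)
    return FinalizeReport(alpha_n=alpha_n, updated_map=updated,
                          dtw_before=dtw_before, dtw_after=dtw_after,
                          ioc_traces=result.traces)
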