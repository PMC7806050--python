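"""Gaussian-process map from reach boundary configurations to cost weights.

The inverse-optimal-control stage produces, per reaching task, a
normalized five-component weight vector over the basic costs.  To predict
weights for unseen tasks, a Gaussian-process regression maps the stacked
boundary joint configuration (q_start, q_end) in R^6 to each weight
component (independent GP per component, anisotropic squared-exponential
kernel plus a noise term, inputs standardized).  Predicted means are
clipped to [0, 1] and renormalized onto the simplex; the predictive
variance is passed through for diagnostics only.

Person-specific adaptation appends a subject's fitted weight vector for a
task and refits a copy, leaving the population model untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .costs import WeightVector

__all__ = ["WeightMapModel", "train", "predict_weights", "update_with_subject"]


@dataclass
class WeightMapModel:
    X: np.ndarray                 # (m, 6) stacked (q_start, q_end), radians
    Y: np.ndarray                 # (m, 5) normalized weight vectors
    subject: str = "population"
    noise: float = 1e-4
    _gps: list = field(default_factory=list, repr=False)
    _x_mean: np.ndarray | None = field(default=None, repr=False)
    _x_std: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_training(self) -> int:
        return self.X.shape[0]


def _fit_gps(model: WeightMapModel) -> None:
    model._x_mean = model.X.mean(axis=0)
    model._x_std = np.where(model.X.std(axis=0) > 1e-9, model.X.std(axis=0), 1.0)
    Xs = (model.X - model._x_mean) / model._x_std
    model._gps = []
    for k in range(5):
        kernel = (ConstantKernel(1.0, (1e-3, 1e3))
                  * RBF(np.ones(6), (1e-2, 1e2))
                  + WhiteKernel(model.noise, (1e-10, 1e-1)))
        gp = GaussianProcessRegressor(kernel=kernel, normalize_y=True,
                                      n_restarts_optimizer=0, random_state=0)
        gp.fit(Xs, model.Y[:, k])
        model._gps.append(gp)


def train(dataset, subject: str = "population",
          noise: float = 1e-4) -> WeightMapModel:
    """Fit the weight map from (q_start, q_end, alpha) examples.

    ``dataset`` is an iterable of triples; each alpha must lie on the
    simplex.  At least 3 examples are required.  Hyperparameters are set
    by marginal-likelihood optimization from a fixed deterministic start.
    Conflicting outputs at duplicate inputs are absorbed by the noise
    kernel.
    """
    X, Y = [], []
    for qs, qe, alpha in dataset:
        a = alpha.as_array() if isinstance(alpha, WeightVector) else np.asarray(alpha, float)
        if abs(a.sum() - 1.0) > 1e-6 or np.any(a < -1e-9):
            raise ValueError("training weights must lie on the simplex")
        X.append(np.concatenate([np.asarray(qs, float).reshape(3),
                                 np.asarray(qe, float).reshape(3)]))
        Y.append(a)
    X, Y = np.asarray(X), np.asarray(Y)
    if X.shape[0] < 3:
        raise ValueError("at least 3 training examples required")
    model = WeightMapModel(X=X, Y=Y, subject=subject, noise=noise)
    _fit_gps(model)
    return model


def predict_weights(model: WeightMapModel, q_start, q_end):
    """Predicted weight vector at a boundary pair.

    Returns ``(WeightVector, std)``: the per-component GP means clipped to
    [0, 1] and renormalized onto the simplex, and the raw predictive
    standard deviations (diagnostic only).
    """
    if not model._gps:
        raise RuntimeError("weight map is not trained")
    x = np.concatenate([np.asarray(q_start, float).reshape(3),
                        np.asarray(q_end, float).reshape(3)])
    xs = ((x - model._x_mean) / model._x_std).reshape(1, -1)
    mean = np.empty(5)
    std = np.empty(5)
    for k, gp in enumerate(model._gps):
        m, s = gp.predict(xs, return_std=True)
        mean[k], std[k] = m[0], s[0]
    clipped = np.clip(mean, 0.0, 1.0)
    if clipped.sum() <= 0:
        clipped = np.full(5, 0.2)
    return WeightVector(tuple(clipped)).normalize(), std


def update_with_subject(model: WeightMapModel, q_start, q_end,
                        alpha_n, subject: str | None = None) -> WeightMapModel:
    """Person-specific update: append one example and refit a copy.

    The input model (typically the population map) is left untouched, so
    concurrent subjects never share mutable state.
    """
    a = alpha_n.as_array() if isinstance(alpha_n, WeightVector) else np.asarray(alpha_n, float)
    if a.shape != (5,):
        raise ValueError("alpha must have 5 components")
    x = np.concatenate([np.asarray(q_start, float).reshape(3),
                        np.asarray(q_end, float).reshape(3)])
    new = WeightMapModel(X=np.vstack([model.X, x]),
                         Y=np.vstack([model.Y, a]),
                         subject=subject or model.subject,
                         noise=model.noise)
    _fit_gps(new)
    return new
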