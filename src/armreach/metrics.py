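"""Dynamic time warping distance between sampled 3D trajectories.

Classic symmetric DTW: dynamic programming over pairwise Euclidean
distances with unit-weight diagonal/horizontal/vertical steps and no
window constraint.  The aligned distance is the metric the inverse
optimal control upper level minimizes — it compares an optimal-control
rollout to an observed reach while remaining invariant to differences in
movement speed.  A per-step normalized value is reported alongside the
raw sum; the upper level uses the raw value.

A joint-angle variant (DTW over 3-vectors of joint angles instead of
wrist positions) is provided for completeness but is off by default in
the fitting pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arm import CartesianTrajectory

__all__ = ["AlignedDistance", "dtw_distance"]


@dataclass(frozen=True)
class AlignedDistance:
    dtw_value: float
    path: tuple
    normalized: float

    def __post_init__(self):
        if self.dtw_value < 0:
            raise ValueError("DTW distance cannot be negative")


def _as_points(x) -> np.ndarray:
    if isinstance(x, CartesianTrajectory):
        return x.pos
    a = np.asarray(x, float)
    if a.ndim == 1:
        a = a[:, None]
    return a


def dtw_distance(A, B, local: str = "euclidean") -> AlignedDistance:
    """Symmetric DTW between two point sequences.

    Accepts :class:`CartesianTrajectory` or plain (n, d) arrays.  Returns
    the accumulated cost, the optimal warping path (monotone, from (0, 0)
    to (n-1, m-1)) and the per-step normalized cost.

    ``local`` selects the pointwise distance: ``"euclidean"`` (reported
    distances) or ``"sqeuclidean"`` (squared; smooth near a perfect match,
    used as the search objective inside the inverse-optimal-control upper
    level).
    """
    a, b = _as_points(A), _as_points(B)
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW inputs must be non-empty")
    if a.shape[1] != b.shape[1]:
        raise ValueError("DTW inputs must share the point dimension")
    n, m = a.shape[0], b.shape[0]
    d = ((a[:, None, :] - b[None, :, :]) ** 2).sum(-1)
    if local == "euclidean":
        d = np.sqrt(d)
    elif local != "sqeuclidean":
        raise ValueError("local must be 'euclidean' or 'sqeuclidean'")

    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        di = d[i - 1]
        row = acc[i]
        prev = acc[i - 1]
        row[0] = np.inf
        for j in range(1, m + 1):
            row[j] = di[j - 1] + min(prev[j - 1], prev[j], row[j - 1])

    # backtrack
    path = []
    i, j = n, m
    while i > 1 or j > 1:
        path.append((i - 1, j - 1))
        choices = []
        if i > 1 and j > 1:
            choices.append((acc[i - 1, j - 1], (i - 1, j - 1)))
        if i > 1:
            choices.append((acc[i - 1, j], (i - 1, j)))
        if j > 1:
            choices.append((acc[i, j - 1], (i, j - 1)))
        _, (i, j) = min(choices, key=lambda c: c[0])
    path.append((0, 0))
    path.reverse()
    value = float(acc[n, m])
    return AlignedDistance(dtw_value=value, path=tuple(path),
                           normalized=value / len(path))
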