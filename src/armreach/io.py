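"""Tabular I/O for marker and end-effector trajectories.

The marker dialect mirrors optical motion-capture exports: one header
line, tab-separated columns ``time  s_x s_y s_z  e_x e_y e_z  w_x w_y w_z``
(seconds and meters, default 250 Hz).  Plain point trajectories use
``time  x y z``.  NaN gap rows are linearly interpolated on read (and
logged); write/read round-trips preserve full float precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .arm import CartesianTrajectory

logger = logging.getLogger(__name__)

MARKER_COLUMNS = ["time", "s_x", "s_y", "s_z", "e_x", "e_y", "e_z",
                  "w_x", "w_y", "w_z"]
POINT_COLUMNS = ["time", "x", "y", "z"]

__all__ = ["MarkerTrajectory", "read_trajectory", "write_trajectory"]


@dataclass
class MarkerTrajectory:
    """Shoulder/elbow/wrist marker paths on a common uniform time base."""

    t: np.ndarray
    shoulder: np.ndarray
    elbow: np.ndarray
    wrist: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, float).reshape(-1)
        for name in ("shoulder", "elbow", "wrist"):
            a = np.asarray(getattr(self, name), float)
            if a.shape != (self.t.size, 3):
                raise ValueError(f"{name} must have shape (len(t), 3)")
            setattr(self, name, a)

    @property
    def rate(self) -> float:
        return 1.0 / (self.t[1] - self.t[0])


def write_trajectory(traj, path) -> None:
    """Write a MarkerTrajectory or CartesianTrajectory as TSV."""
    if isinstance(traj, MarkerTrajectory):
        data = np.column_stack([traj.t, traj.shoulder, traj.elbow, traj.wrist])
        cols = MARKER_COLUMNS
    elif isinstance(traj, CartesianTrajectory):
        data = np.column_stack([traj.t, traj.pos])
        cols = POINT_COLUMNS
    else:
        raise TypeError("unsupported trajectory type")
    pd.DataFrame(data, columns=cols).to_csv(path, sep="\t", index=False,
                                            float_format="%.17g")


def read_trajectory(path):
    """Read a TSV trajectory; the column set selects the return type.

    Gap rows (NaNs) are linearly interpolated and logged.  Malformed files
    raise ``ValueError`` with the offending line where detectable.
    """
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty trajectory file") from None
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed trajectory file: {exc}") from None
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty trajectory (header only)")

    if list(df.columns) == MARKER_COLUMNS:
        kind = "marker"
    elif list(df.columns) == POINT_COLUMNS:
        kind = "point"
    else:
        raise ValueError(f"{path}: unrecognized column set {list(df.columns)}")

    if df.isna().any().any():
        n_gap = int(df.isna().any(axis=1).sum())
        logger.info("%s: interpolating %d gap row(s)", path, n_gap)
        df = df.interpolate(method="linear", limit_direction="both")

    vals = df.to_numpy(float)
    if kind == "marker":
        return MarkerTrajectory(t=vals[:, 0], shoulder=vals[:, 1:4],
                                elbow=vals[:, 4:7], wrist=vals[:, 7:10])
    return CartesianTrajectory(t=vals[:, 0], pos=vals[:, 1:4])
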