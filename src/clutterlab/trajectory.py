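"""The Trajectory container and its CSV round-trip.

A trajectory is a time-ordered series of 3-D positions sampled nominally at
100 Hz, keyed by (bee_id, trial, environment_id).  Provenance flags record
which preprocessing stages have touched it ("raw", "filtered", "trimmed").
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .environment import Environment

TRAJECTORY_COLUMNS = ["bee_id", "trial", "environment_id", "t_s", "x_mm", "y_mm", "z_mm"]


class TrajectoryError(ValueError):
    """Raised when a trajectory violates one of its invariants."""


@dataclass
class Trajectory:
    bee_id: str
    trial: int
    environment_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    provenance: frozenset = field(default_factory=lambda: frozenset({"raw"}))

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.z) == n):
            raise TrajectoryError("t, x, y, z must have equal length")
        self.provenance = frozenset(self.provenance)

    @property
    def n(self) -> int:
        return len(self.t)

    @property
    def key(self) -> tuple[str, int]:
        return (self.bee_id, self.trial)

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])

    def points_xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def points_xyz(self) -> np.ndarray:
        return np.column_stack([self.x, self.y, self.z])

    def sampling_rate(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t)))

    def with_provenance(self, *flags: str) -> "Trajectory":
        return replace(self, provenance=self.provenance | set(flags))

    def with_samples(self, t, x, y, z) -> "Trajectory":
        return replace(self, t=np.asarray(t), x=np.asarray(x), y=np.asarray(y), z=np.asarray(z))

    def validate(self, env: Environment | None = None, *, box_tol: float = 1.0,
                 dt_tol: float = 0.01) -> None:
        """Check sample-level invariants; raise :class:`TrajectoryError` on failure.

        box_tol: positional tolerance (mm) against the tunnel box;
        dt_tol: allowed relative deviation of any sampling interval from the median.
        """
        if self.n < 2:
            raise TrajectoryError(f"{self.key}: need >= 2 samples, got {self.n}")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise TrajectoryError(f"{self.key}: timestamps not strictly increasing")
        med = np.median(dt)
        if np.any(np.abs(dt - med) > dt_tol * med):
            raise TrajectoryError(f"{self.key}: sampling interval varies by more than {dt_tol:.0%}")
        if self.trial < 1:
            raise TrajectoryError(f"{self.key}: trial must be >= 1")
        if env is not None:
            half_w = env.tunnel_width / 2.0
            if (
                self.x.min() < -box_tol or self.x.max() > env.tunnel_length + box_tol
                or np.abs(self.y).max() > half_w + box_tol
                or self.z.min() < -box_tol or self.z.max() > env.tunnel_height + box_tol
            ):
                raise TrajectoryError(f"{self.key}: samples outside the tunnel box")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bee_id": self.bee_id,
                "trial": self.trial,
                "environment_id": self.environment_id,
                "t_s": self.t,
                "x_mm": self.x,
                "y_mm": self.y,
                "z_mm": self.z,
            }
        )


def to_frame(trajectories: list[Trajectory]) -> pd.DataFrame:
    """Stack trajectories into one long-format table."""
    if not trajectories:
        return pd.DataFrame(columns=TRAJECTORY_COLUMNS)
    return pd.concat([tr.to_frame() for tr in trajectories], ignore_index=True)


def from_frame(df: pd.DataFrame) -> list[Trajectory]:
    """Split a long-format table back into per-flight trajectories.

    Rows are grouped on (bee_id, trial, environment_id); within each flight
    the stored sample order is preserved.
    """
    out: list[Trajectory] = []
    for (bee, trial, env_id), g in df.groupby(["bee_id", "trial", "environment_id"], sort=True):
        out.append(
            Trajectory(
                bee_id=str(bee),
                trial=int(trial),
                environment_id=str(env_id),
                t=g["t_s"].to_numpy(),
                x=g["x_mm"].to_numpy(),
                y=g["y_mm"].to_numpy(),
                z=g["z_mm"].to_numpy(),
            )
        )
    return out


def write_csv(trajectories: list[Trajectory], path, *, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        to_frame(trajectories).to_csv(fh, index=False)


def read_csv(path) -> list[Trajectory]:
    return from_frame(pd.read_csv(path, comment="#"))


__all__ = [
    "Trajectory",
    "TrajectoryError",
    "TRAJECTORY_COLUMNS",
    "to_frame",
    "from_frame",
    "write_csv",
    "read_csv",
]
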