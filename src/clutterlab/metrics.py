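"""The six per-flight characteristics and the experiment-level table.

Per flight: flight time, SD of flight speed, path sinuosity, SD of lateral
position (plus its median and interquartile range), and the mean and SD of
the per-object minimal distance.  Path length and speed are 3-D; lateral
statistics use y only; object clearances are horizontal (the obstacles are
full-height vertical cuboids, so height is irrelevant to clearance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environment import Environment, Obstacle
from .trajectory import Trajectory, TrajectoryError

METRIC_NAMES = [
    "flight_time",
    "speed_sd",
    "sinuosity",
    "lateral_sd",
    "obj_dist_mean",
    "obj_dist_sd",
]


class DegeneratePathError(ValueError):
    """Raised when a path's endpoints coincide (sinuosity undefined)."""


class NoObjectsPassedError(ValueError):
    """Raised when a flight passes no obstacles (clearance metrics undefined)."""


def flight_time(traj: Trajectory) -> float:
    """Seconds between the first and last sample of the flight."""
    if traj.n < 2:
        raise TrajectoryError(f"{traj.key}: flight time needs >= 2 samples")
    return float(traj.t[-1] - traj.t[0])


def path_length(traj: Trajectory) -> float:
    """Total 3-D arc length (mm) summed over inter-sample segments."""
    seg = np.sqrt(np.diff(traj.x) ** 2 + np.diff(traj.y) ** 2 + np.diff(traj.z) ** 2)
    return float(seg.sum())


def sinuosity(traj: Trajectory, env: Environment | None = None) -> float:
    """Path length divided by the straight-line distance between endpoints.

    1.0 means a perfectly direct flight; values grow with detours.  ``env``
    is accepted for interface symmetry but the direct path is measured
    between the flight's own first and last samples.
    """
    if traj.n < 2:
        raise TrajectoryError(f"{traj.key}: sinuosity needs >= 2 samples")
    direct = float(
        np.sqrt(
            (traj.x[-1] - traj.x[0]) ** 2
            + (traj.y[-1] - traj.y[0]) ** 2
            + (traj.z[-1] - traj.z[0]) ** 2
        )
    )
    if direct <= 1e-6:  # mm; closed loops at float precision count as degenerate
        raise DegeneratePathError(f"{traj.key}: endpoints coincide")
    return path_length(traj) / direct


def speed_series(traj: Trajectory, *, mode: str = "3d") -> np.ndarray:
    """Per-sample speed (m/s) by central differences (one-sided at the ends).

    ``mode="3d"`` (default) uses all three coordinates; ``mode="ground"``
    uses the horizontal plane only.
    """
    if traj.n < 3:
        raise TrajectoryError(f"{traj.key}: speed series needs >= 3 samples")
    vx = np.gradient(traj.x, traj.t)
    vy = np.gradient(traj.y, traj.t)
    if mode == "3d":
        vz = np.gradient(traj.z, traj.t)
        v = np.sqrt(vx**2 + vy**2 + vz**2)
    elif mode == "ground":
        v = np.hypot(vx, vy)
    else:
        raise ValueError(f"unknown speed mode {mode!r}")
    return v / 1000.0


def speed_sd(traj: Trajectory, *, mode: str = "3d") -> float:
    """Sample SD (n-1 denominator) of the flight-speed series (m/s)."""
    return float(np.std(speed_series(traj, mode=mode), ddof=1))


def lateral_stats(traj: Trajectory) -> tuple[float, float, tuple[float, float]]:
    """(SD, median, (q25, q75)) of lateral position y in mm.

    Percentiles use linear interpolation between order statistics.
    """
    if traj.n < 2:
        raise TrajectoryError(f"{traj.key}: lateral stats need >= 2 samples")
    y = traj.y
    q25, q75 = np.percentile(y, [25.0, 75.0])
    return float(np.std(y, ddof=1)), float(np.median(y)), (float(q25), float(q75))


def objects_passed(traj: Trajectory, env: Environment) -> list[Obstacle]:
    """Obstacles whose axial position lies within the flight's x-range."""
    lo, hi = float(traj.x.min()), float(traj.x.max())
    return [o for o in env.obstacles if lo <= o.x <= hi]


def object_min_distances(
    traj: Trajectory, env: Environment
) -> tuple[float, float, np.ndarray]:
    """Per-object minimal horizontal clearance, and its mean and SD per flight.

    For each passed obstacle the minimum over samples of the (x, y) distance
    to the obstacle's central axis; then sample mean and SD over obstacles
    (SD of a single object is 0 by convention).
    """
    passed = objects_passed(traj, env)
    if not passed:
        raise NoObjectsPassedError(f"{traj.key}: flight passes no obstacles")
    oxy = np.array([(o.x, o.y) for o in passed])
    d = np.hypot(traj.x[:, None] - oxy[None, :, 0], traj.y[:, None] - oxy[None, :, 1])
    per_object = d.min(axis=0)
    sd = float(np.std(per_object, ddof=1)) if len(per_object) > 1 else 0.0
    return float(per_object.mean()), sd, per_object


@dataclass
class FlightMetrics:
    """One row of the flight-characteristics table."""

    bee_id: str
    trial: int
    environment_id: str
    flight_time: float
    speed_sd: float
    sinuosity: float
    lateral_sd: float
    lateral_median: float
    lateral_iqr: tuple[float, float]
    obj_dist_mean: float
    obj_dist_sd: float
    n_objects_passed: int
    note: str = ""


def compute_flight_metrics(traj: Trajectory, env: Environment, *, speed_mode: str = "3d") -> FlightMetrics:
    """All six characteristics for one flight; undefined metrics become NaN with a note."""
    sd, med, iqr = lateral_stats(traj)
    note = []
    try:
        sin = sinuosity(traj, env)
    except DegeneratePathError:
        sin = float("nan")
        note.append("degenerate_path")
    try:
        om, osd, per = object_min_distances(traj, env)
        n_obj = len(per)
    except NoObjectsPassedError:
        om = osd = float("nan")
        n_obj = 0
        note.append("no_objects_passed")
    return FlightMetrics(
        bee_id=traj.bee_id,
        trial=traj.trial,
        environment_id=traj.environment_id,
        flight_time=flight_time(traj),
        speed_sd=speed_sd(traj, mode=speed_mode),
        sinuosity=sin,
        lateral_sd=sd,
        lateral_median=med,
        lateral_iqr=iqr,
        obj_dist_mean=om,
        obj_dist_sd=osd,
        n_objects_passed=n_obj,
        note=";".join(note),
    )


def compute_metrics_table(
    trajectories: list[Trajectory], env: Environment, *, speed_mode: str = "3d"
) -> pd.DataFrame:
    """One row per flight; per-flight failures yield NaN fields plus a note,
    never a silently dropped row."""
    rows = []
    for tr in trajectories:
        try:
            m = compute_flight_metrics(tr, env, speed_mode=speed_mode)
            rows.append(
                {
                    "bee_id": m.bee_id,
                    "trial": m.trial,
                    "environment_id": m.environment_id,
                    "flight_time": m.flight_time,
                    "speed_sd": m.speed_sd,
                    "sinuosity": m.sinuosity,
                    "lateral_sd": m.lateral_sd,
                    "lateral_median": m.lateral_median,
                    "lateral_q25": m.lateral_iqr[0],
                    "lateral_q75": m.lateral_iqr[1],
                    "obj_dist_mean": m.obj_dist_mean,
                    "obj_dist_sd": m.obj_dist_sd,
                    "n_objects_passed": m.n_objects_passed,
                    "note": m.note,
                }
            )
        except (TrajectoryError, ValueError) as exc:
            rows.append(
                {
                    "bee_id": tr.bee_id,
                    "trial": tr.trial,
                    "environment_id": tr.environment_id,
                    "note": f"error:{exc}",
                }
            )
    cols = [
        "bee_id", "trial", "environment_id", "flight_time", "speed_sd", "sinuosity",
        "lateral_sd", "lateral_median", "lateral_q25", "lateral_q75",
        "obj_dist_mean", "obj_dist_sd", "n_objects_passed", "note",
    ]
    return pd.DataFrame(rows, columns=cols)


__all__ = [
    "METRIC_NAMES",
    "FlightMetrics",
    "DegeneratePathError",
    "NoObjectsPassedError",
    "flight_time",
    "path_length",
    "sinuosity",
    "speed_series",
    "speed_sd",
    "lateral_stats",
    "objects_passed",
    "object_min_distances",
    "compute_flight_metrics",
    "compute_metrics_table",
]
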