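"""Tunnel environments: geometry, random obstacle layouts, and file round-trips.

The experimental arena is a 200 x 50 x 30 cm flight tunnel filled with 110
thin vertical obstacles whose centres keep a minimum edge-to-edge gap of
7 cm, wide enough for a bumblebee to pass without yawing.  A second variant
of the layout replaces the 32 obstacles closest to the tunnel's central long
axis with transparent (low-salience) ones.

All lengths are millimetres.  x runs along the tunnel axis from the clutter
entrance (0) to the hive-side exit; y is lateral with 0 on the midline
(positive = left); z is height above the floor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

SALIENT = "salient"
TRANSPARENT = "transparent"
_SALIENCE_CLASSES = (SALIENT, TRANSPARENT)


class PackingError(RuntimeError):
    """Raised when an obstacle layout cannot be packed into the tunnel."""


class EnvironmentError_(ValueError):
    """Raised when an environment violates one of its invariants."""


@dataclass(frozen=True)
class Obstacle:
    """A vertical obstacle, reduced to its central axis in the horizontal plane.

    The physical objects are full-height 10 x 3 mm cuboids; for clearance
    metrics they are modelled as vertical axes with a circular cross-section
    of radius ``half_width``.
    """

    x: float
    y: float
    salience: str = SALIENT
    half_width: float = 5.0

    def __post_init__(self) -> None:
        if self.salience not in _SALIENCE_CLASSES:
            raise EnvironmentError_(f"unknown salience class {self.salience!r}")
        if self.half_width <= 0:
            raise EnvironmentError_("half_width must be positive")


@dataclass
class Environment:
    """A flight tunnel plus its obstacle layout."""

    obstacles: list[Obstacle] = field(default_factory=list)
    tunnel_length: float = 2000.0
    tunnel_width: float = 500.0
    tunnel_height: float = 300.0
    layout_id: str = "env"

    @property
    def entrance_x(self) -> float:
        return 0.0

    @property
    def exit_x(self) -> float:
        return self.tunnel_length

    @property
    def n_transparent(self) -> int:
        return sum(1 for o in self.obstacles if o.salience == TRANSPARENT)

    def obstacle_xy(self) -> np.ndarray:
        """(n, 2) array of obstacle axis positions."""
        if not self.obstacles:
            return np.empty((0, 2))
        return np.array([(o.x, o.y) for o in self.obstacles], dtype=float)

    def min_pairwise_gap(self) -> float:
        """Smallest edge-to-edge gap between any two obstacles (mm)."""
        xy = self.obstacle_xy()
        if len(xy) < 2:
            return np.inf
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        hw = np.array([o.half_width for o in self.obstacles])
        return float((d - hw[:, None] - hw[None, :]).min())

    def validate(self, expected_count: int | None = None, min_gap: float = 70.0) -> None:
        """Check count, bounds and spacing invariants; raise on violation."""
        if expected_count is not None and len(self.obstacles) != expected_count:
            raise EnvironmentError_(
                f"expected {expected_count} obstacles, found {len(self.obstacles)}"
            )
        half_w = self.tunnel_width / 2.0
        for i, o in enumerate(self.obstacles):
            if not (0.0 < o.x < self.tunnel_length and abs(o.y) < half_w):
                raise EnvironmentError_(
                    f"obstacle {i} at ({o.x:.1f}, {o.y:.1f}) outside tunnel footprint"
                )
        if self.min_pairwise_gap() < min_gap:
            raise EnvironmentError_(
                f"minimum obstacle gap {self.min_pairwise_gap():.1f} mm < {min_gap} mm"
            )

    # ---- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "layout_id": self.layout_id,
            "tunnel_length_mm": self.tunnel_length,
            "tunnel_width_mm": self.tunnel_width,
            "tunnel_height_mm": self.tunnel_height,
            "obstacles": [
                {"x_mm": o.x, "y_mm": o.y, "salience": o.salience, "half_width_mm": o.half_width}
                for o in self.obstacles
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Environment":
        return cls(
            obstacles=[
                Obstacle(
                    x=float(o["x_mm"]),
                    y=float(o["y_mm"]),
                    salience=o.get("salience", SALIENT),
                    half_width=float(o.get("half_width_mm", 5.0)),
                )
                for o in d["obstacles"]
            ],
            tunnel_length=float(d.get("tunnel_length_mm", 2000.0)),
            tunnel_width=float(d.get("tunnel_width_mm", 500.0)),
            tunnel_height=float(d.get("tunnel_height_mm", 300.0)),
            layout_id=str(d.get("layout_id", "env")),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Environment":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_mm": [o.x for o in self.obstacles],
                "y_mm": [o.y for o in self.obstacles],
                "salience": [o.salience for o in self.obstacles],
                "half_width_mm": [o.half_width for o in self.obstacles],
            }
        )


def generate_environment(
    n_obstacles: int = 110,
    *,
    min_gap: float = 70.0,
    n_transparent: int = 0,
    tunnel_length: float = 2000.0,
    tunnel_width: float = 500.0,
    tunnel_height: float = 300.0,
    half_width: float = 5.0,
    wall_margin: float = 15.0,
    end_margin: float = 60.0,
    layout_id: str | None = None,
    seed: int = 0,
    max_restarts: int = 60,
    tries_per_obstacle: int = 4000,
) -> Environment:
    """Generate a random cluttered layout by uniform rejection sampling.

    Obstacle axes are drawn uniformly inside the tunnel footprint (keeping
    ``end_margin`` from entrance/exit and ``wall_margin`` from the side
    walls) and accepted only if the edge-to-edge gap to every previously
    placed obstacle is at least ``min_gap``.  If ``n_transparent`` > 0, the
    that many obstacles nearest the central long axis (smallest |y|) are
    marked transparent, mirroring the second training environment.

    Deterministic given ``seed``.  Raises :class:`PackingError` if the
    requested density cannot be packed after bounded restarts.
    """
    if n_transparent > n_obstacles:
        raise ValueError("n_transparent cannot exceed n_obstacles")
    lo_x, hi_x = end_margin, tunnel_length - end_margin
    hi_y = tunnel_width / 2.0 - wall_margin
    if not (hi_x > lo_x and hi_y > 0):
        raise PackingError("tunnel too small for the requested margins")
    min_centre = min_gap + 2.0 * half_width
    rng = np.random.default_rng(seed)

    placed: np.ndarray | None = None
    for _ in range(max_restarts):
        pts: list[tuple[float, float]] = []
        arr = np.empty((0, 2))
        tries = 0
        while len(pts) < n_obstacles and tries < tries_per_obstacle * n_obstacles:
            tries += 1
            cand = (rng.uniform(lo_x, hi_x), rng.uniform(-hi_y, hi_y))
            if len(pts) == 0 or np.hypot(arr[:, 0] - cand[0], arr[:, 1] - cand[1]).min() >= min_centre:
                pts.append(cand)
                arr = np.asarray(pts)
        if len(pts) == n_obstacles:
            placed = arr
            break
    if placed is None:
        raise PackingError(
            f"could not place {n_obstacles} obstacles with gap >= {min_gap} mm "
            f"after {max_restarts} restarts"
        )

    salience = np.full(n_obstacles, SALIENT, dtype=object)
    if n_transparent:
        central = np.argsort(np.abs(placed[:, 1]), kind="stable")[:n_transparent]
        salience[central] = TRANSPARENT

    obstacles = [
        Obstacle(x=float(x), y=float(y), salience=str(s), half_width=half_width)
        for (x, y), s in zip(placed, salience)
    ]
    env = Environment(
        obstacles=obstacles,
        tunnel_length=tunnel_length,
        tunnel_width=tunnel_width,
        tunnel_height=tunnel_height,
        layout_id=layout_id or f"layout-{seed}",
    )
    env.validate(expected_count=n_obstacles, min_gap=min_gap)
    return env


def environment_pair(seed: int = 0, n_transparent: int = 32, **kwargs) -> tuple[Environment, Environment]:
    """The two training environments: identical geometry, differing salience.

    Environment 1 is all-salient; environment 2 has the ``n_transparent``
    most central obstacles transparent.  Both share the same obstacle
    positions (same seed), as in the experiment.
    """
    env1 = generate_environment(seed=seed, layout_id="env1", **kwargs)
    env2 = generate_environment(seed=seed, n_transparent=n_transparent, layout_id="env2", **kwargs)
    return env1, env2


__all__ = [
    "Obstacle",
    "Environment",
    "generate_environment",
    "environment_pair",
    "PackingError",
    "EnvironmentError_",
    "SALIENT",
    "TRANSPARENT",
]
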