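"""Synthetic bee flights through cluttered tunnels.

Two generators live here:

* :func:`simulate_trajectory` / :func:`simulate_experiment` — a kinematic
  waypoint-attraction agent integrated at 100 Hz.  The agent is pulled
  toward the exit, repelled by obstacles inside a sensing radius (halved
  for transparent, low-salience obstacles), attracted to a per-bee lateral
  route-preference curve, and perturbed by Gaussian velocity jitter.
  Naive flights interleave back-and-forth reversal episodes whose expected
  number decays geometrically with trial, reproducing the exploratory →
  directed transition of real foragers.  This is a behavioural stand-in
  for recorded flights, not a sensorimotor model.

* :func:`sample_route_population` — an idealized route-corridor sampler:
  each bee owns a smooth lateral preference curve with a configurable
  between-bee spread, and each flight scatters around it with a
  configurable within-bee jitter.  It produces analysis-ready directed
  trajectories with exactly known ground-truth variance structure, which
  is what the similarity-index calibration needs.

All randomness derives from integer seeds through ``numpy`` SeedSequences;
per-(bee, trial) streams use ``SeedSequence(master_seed, spawn_key=(bee_index,
trial))`` so any single flight can be regenerated in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .environment import Environment, TRANSPARENT
from .trajectory import Trajectory


class SimulationTimeout(RuntimeError):
    """The simulated bee failed to reach the exit within the time cap.

    Mirrors the experimental rule that a recording is abandoned when the bee
    does not locate the tunnel exit within five minutes.
    """

    def __init__(self, bee_id: str, trial: int, time_cap: float):
        self.bee_id, self.trial, self.time_cap = bee_id, trial, time_cap
        super().__init__(f"bee {bee_id} trial {trial}: no exit within {time_cap:.0f} s")


@dataclass
class BeeProfile:
    """Per-bee behavioural parameters.

    The lateral route preference is a constant offset plus a few harmonics
    over the tunnel axis; the constant carries most of the between-bee
    variance.  ``exploration_decay`` (per trial, dimensionless >= 0) sets how
    fast the expected number of back-and-forth reversal episodes falls:
    E[reversals at trial k] = n_reversals0 * exp(-decay * (k - 1)).
    """

    bee_id: str
    offset_const: float = 0.0
    wiggle_amps: np.ndarray = field(default_factory=lambda: np.zeros(3))
    wiggle_phases: np.ndarray = field(default_factory=lambda: np.zeros(3))
    exploration_decay: float = 0.5
    n_reversals0: float = 6.0
    speed_mean: float = 0.37        # m/s; cruise speed of bees in clutter
    speed_jitter_sd: float = 0.08   # m/s; stationary SD of velocity noise
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.speed_mean <= 0:
            raise ValueError("speed_mean must be positive")
        if self.exploration_decay < 0:
            raise ValueError("exploration_decay must be >= 0")

    def route_offset(self, x, tunnel_length: float = 2000.0):
        """Preferred lateral position (mm) as a function of axial position."""
        x = np.asarray(x, dtype=float)
        u = 2.0 * np.pi * x / tunnel_length
        out = np.full_like(x, self.offset_const, dtype=float)
        for k, (a, ph) in enumerate(zip(self.wiggle_amps, self.wiggle_phases), start=1):
            out = out + a * np.sin(k * u + ph)
        return out

    def expected_reversals(self, trial: int) -> float:
        return self.n_reversals0 * math.exp(-self.exploration_decay * (trial - 1))


def _flight_seed(master_seed: int, bee_index: int, trial: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(master_seed, spawn_key=(bee_index, trial))


def draw_profile(bee_id: str, bee_index: int, master_seed: int,
                 between_bee_offset_sd: float = 60.0, **profile_kwargs) -> BeeProfile:
    """Draw one bee's profile from the between-bee distribution.

    The constant lateral offset is N(0, between_bee_offset_sd); harmonic
    wiggle amplitudes scale with the same SD so a zero between-bee spread
    degenerates to all bees sharing the identical (flat) route curve.
    """
    rng = np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(bee_index,)))
    return BeeProfile(
        bee_id=bee_id,
        offset_const=rng.normal(0.0, between_bee_offset_sd),
        wiggle_amps=rng.normal(0.0, 0.3 * between_bee_offset_sd, size=3),
        wiggle_phases=rng.uniform(0.0, 2.0 * np.pi, size=3),
        rng_seed=bee_index,
        **profile_kwargs,
    )


def simulate_trajectory(
    profile: BeeProfile,
    trial: int,
    env: Environment,
    seed: int | np.random.SeedSequence = 0,
    *,
    dt: float = 0.01,
    time_cap: float = 300.0,
    sensing_radius: float = 120.0,
    transparent_factor: float = 0.5,
    clearance: float = 8.0,
    z_pref: float = 150.0,
) -> Trajectory:
    """Simulate one flight from tunnel entrance to exit.

    Returns a raw :class:`Trajectory` sampled at ``1/dt`` Hz.  The agent
    never collides: after each step any point closer than ``clearance`` mm
    to an obstacle axis is projected back out radially (obstacle gaps are
    >= 70 mm, so projection from one axis cannot enter another).  Raises
    :class:`SimulationTimeout` if the exit is not reached within
    ``time_cap`` seconds of simulated flight.

    Deterministic: the same (profile, trial, env, seed) always yields
    bit-identical sample arrays.
    """
    if trial < 1:
        raise ValueError("trial must be >= 1")
    rng = np.random.default_rng(seed)
    L, W, H = env.tunnel_length, env.tunnel_width, env.tunnel_height

    obs_xy = env.obstacle_xy()
    if len(obs_xy):
        order = np.argsort(obs_xy[:, 0], kind="stable")
        obs_xy = obs_xy[order]
        obs_radius = np.array(
            [sensing_radius * (transparent_factor if env.obstacles[i].salience == TRANSPARENT else 1.0)
             for i in order]
        )
        obs_x = obs_xy[:, 0]
        max_radius = float(obs_radius.max())
    else:
        obs_radius = np.empty(0)
        obs_x = np.empty(0)
        max_radius = sensing_radius

    # reversal episodes for this (bee, trial)
    n_rev = rng.poisson(profile.expected_reversals(trial))
    triggers = np.sort(rng.uniform(250.0, L - 200.0, size=n_rev))
    next_trigger = 0
    reversing = False
    back_target = 0.0

    s = profile.speed_mean * 1000.0       # mm/s
    jit = profile.speed_jitter_sd * 1000.0
    k_v = 4.0                             # 1/s velocity relaxation
    k_rep = 6.0 * s                       # mm/s^2 peak obstacle repulsion
    noise_scale = jit * math.sqrt(2.0 * k_v * dt)  # OU stationary SD == jit
    wall_margin = 30.0
    half_w = W / 2.0

    pos = np.array([0.0, float(np.clip(profile.route_offset(0.0, L), -half_w + wall_margin,
                                       half_w - wall_margin)), z_pref])
    vel = np.array([s, 0.0, 0.0])
    max_steps = int(round(time_cap / dt))
    xs, ys, zs = [pos[0]], [pos[1]], [pos[2]]
    run_max = pos[0]

    for _ in range(max_steps):
        x, y, z = pos
        if reversing and x <= back_target:
            reversing = False
        if not reversing and next_trigger < n_rev and run_max >= triggers[next_trigger]:
            reversing = True
            back_target = max(30.0, x - rng.uniform(300.0, 900.0))
            next_trigger += 1

        goal = -1.0 if reversing else 1.0
        y_err = float(profile.route_offset(x, L)) - y
        v_des = np.array([
            goal,
            0.9 * np.clip(y_err / 150.0, -1.0, 1.0),
            0.5 * np.clip((z_pref - z) / 150.0, -1.0, 1.0),
        ])
        v_des *= s / np.linalg.norm(v_des)

        acc = k_v * (v_des - vel)

        if len(obs_x):
            lo = np.searchsorted(obs_x, x - max_radius)
            hi = np.searchsorted(obs_x, x + max_radius)
            if hi > lo:
                dx = x - obs_xy[lo:hi, 0]
                dy = y - obs_xy[lo:hi, 1]
                d = np.hypot(dx, dy)
                r = obs_radius[lo:hi]
                near = d < r
                if near.any():
                    dn = np.maximum(d[near], 1.0)
                    w = k_rep * (1.0 - d[near] / r[near]) / dn
                    acc[0] += float((w * dx[near]).sum())
                    acc[1] += float((w * dy[near]).sum())

        # soft wall repulsion
        if y > half_w - wall_margin:
            acc[1] -= k_v * s * (y - (half_w - wall_margin)) / wall_margin
        elif y < -(half_w - wall_margin):
            acc[1] -= k_v * s * (y + (half_w - wall_margin)) / wall_margin
        if z > H - wall_margin:
            acc[2] -= k_v * s * (z - (H - wall_margin)) / wall_margin
        elif z < wall_margin:
            acc[2] -= k_v * s * (z - wall_margin) / wall_margin

        vel = vel + acc * dt + rng.normal(0.0, noise_scale, size=3)
        speed = np.linalg.norm(vel)
        if speed > 2.2 * s:
            vel *= 2.2 * s / speed
        elif speed < 0.25 * s:
            vel *= 0.25 * s / max(speed, 1e-9)

        pos = pos + vel * dt

        # hard box limits (reflect the offending velocity component)
        if pos[1] > half_w - 5.0:
            pos[1] = half_w - 5.0
            vel[1] = -abs(vel[1])
        elif pos[1] < -(half_w - 5.0):
            pos[1] = -(half_w - 5.0)
            vel[1] = abs(vel[1])
        if pos[2] > H - 5.0:
            pos[2] = H - 5.0
            vel[2] = -abs(vel[2])
        elif pos[2] < 5.0:
            pos[2] = 5.0
            vel[2] = abs(vel[2])
        if pos[0] < 0.0:
            pos[0] = 0.0
            vel[0] = abs(vel[0])

        # collision guard: project out of any obstacle's clearance disc
        if len(obs_x):
            lo = np.searchsorted(obs_x, pos[0] - clearance - 5.0)
            hi = np.searchsorted(obs_x, pos[0] + clearance + 5.0)
            for j in range(lo, hi):
                dx = pos[0] - obs_xy[j, 0]
                dy = pos[1] - obs_xy[j, 1]
                d = math.hypot(dx, dy)
                if d < clearance:
                    if d < 1e-9:
                        dx, dy, d = 1.0, 0.0, 1.0
                    pos[0] = obs_xy[j, 0] + dx / d * clearance
                    pos[1] = obs_xy[j, 1] + dy / d * clearance

        run_max = max(run_max, pos[0])
        done = pos[0] >= L
        if done:
            pos[0] = L
        xs.append(pos[0]); ys.append(pos[1]); zs.append(pos[2])
        if done:
            break
    else:
        raise SimulationTimeout(profile.bee_id, trial, time_cap)

    n = len(xs)
    return Trajectory(
        bee_id=profile.bee_id,
        trial=trial,
        environment_id=env.layout_id,
        t=np.arange(n) * dt,
        x=np.array(xs),
        y=np.array(ys),
        z=np.array(zs),
        provenance=frozenset({"raw"}),
    )


def simulate_experiment(
    n_bees: int,
    n_trials: int,
    env: Environment,
    master_seed: int = 0,
    *,
    between_bee_offset_sd: float = 60.0,
    bee_prefix: str | None = None,
    profile_kwargs: dict | None = None,
    **sim_kwargs,
) -> tuple[list[Trajectory], pd.DataFrame]:
    """Simulate a full training experiment: ``n_bees`` bees x ``n_trials`` trials.

    Each bee's route preference is drawn from the between-bee distribution
    (lateral offset SD = ``between_bee_offset_sd`` mm).  Returns the list of
    trajectories plus a provenance log, one row per (bee, trial), recording
    the derived seed and whether the flight timed out (timed-out flights are
    omitted from the trajectory list, as aborted recordings are in the
    experiment).
    """
    if n_bees < 1 or n_trials < 1:
        raise ValueError("n_bees and n_trials must be >= 1")
    prefix = bee_prefix if bee_prefix is not None else f"{env.layout_id}-bee"
    trajectories: list[Trajectory] = []
    rows = []
    for b in range(n_bees):
        profile = draw_profile(
            f"{prefix}{b + 1:02d}", b, master_seed,
            between_bee_offset_sd=between_bee_offset_sd,
            **(profile_kwargs or {}),
        )
        for trial in range(1, n_trials + 1):
            ss = _flight_seed(master_seed, b, trial)
            status = "ok"
            try:
                trajectories.append(simulate_trajectory(profile, trial, env, seed=ss, **sim_kwargs))
            except SimulationTimeout:
                status = "timeout"
            rows.append(
                {
                    "bee_id": profile.bee_id,
                    "trial": trial,
                    "environment_id": env.layout_id,
                    "master_seed": master_seed,
                    "spawn_key": f"({b},{trial})",
                    "status": status,
                }
            )
    return trajectories, pd.DataFrame(rows)


def sample_route_population(
    n_bees: int = 16,
    n_per_bee: int = 8,
    *,
    between_sd: float = 60.0,
    within_sd: float = 15.0,
    n_points: int = 300,
    x_range: tuple[float, float] = (250.0, 1750.0),
    speed: float = 0.4,
    environment_id: str = "corridor",
    seed: int = 0,
) -> list[Trajectory]:
    """Sample directed trajectories from an idealized route-corridor model.

    Bee *i* owns a smooth lateral curve b_i(x) whose pointwise SD across
    bees is exactly ``between_sd`` (a constant offset carrying 60% of the
    variance plus two harmonics carrying 20% each).  Flight *j* of bee *i*
    is y_ij(x) = b_i(x) + e_ij(x), with e_ij a smooth within-bee deviation
    of pointwise SD ``within_sd`` (constant + four harmonic pairs, equal
    variance shares).  x advances uniformly, z stays at mid-height, and
    timestamps assume a constant axial ``speed`` (m/s), so every flight is
    directed by construction.  Trajectories are emitted analysis-ready
    (provenance ``{filtered, trimmed}``) on ``x_range``.

    With ``between_sd=0`` all trajectories are i.i.d. — the exchangeable
    null of the similarity index; ``between_sd >> within_sd`` yields
    strongly idiosyncratic per-bee corridors.
    """
    rng = np.random.default_rng(seed)
    x = np.linspace(x_range[0], x_range[1], n_points)
    u = 2.0 * np.pi * (x - x_range[0]) / (x_range[1] - x_range[0])
    t = (x - x_range[0]) / (speed * 1000.0)
    z = np.full(n_points, 150.0)

    def _smooth_curve(total_sd: float, shares: list[float], n_harm: int) -> np.ndarray:
        # constant term + n_harm sin/cos pairs; sin^2+cos^2 == 1 makes the
        # pointwise variance exactly total_sd^2 * sum(shares)
        c = rng.normal(0.0, total_sd * math.sqrt(shares[0]))
        out = np.full(n_points, c)
        for k in range(1, n_harm + 1):
            sd_k = total_sd * math.sqrt(shares[k])
            a, b = rng.normal(0.0, sd_k, size=2)
            out = out + a * np.sin(k * u) + b * np.cos(k * u)
        return out

    trajectories = []
    for i in range(n_bees):
        base = _smooth_curve(between_sd, [0.6, 0.2, 0.2], 2) if between_sd > 0 else np.zeros(n_points)
        for j in range(n_per_bee):
            dev = _smooth_curve(within_sd, [0.2, 0.2, 0.2, 0.2, 0.2], 4) if within_sd > 0 else 0.0
            trajectories.append(
                Trajectory(
                    bee_id=f"bee{i + 1:02d}",
                    trial=j + 5,  # trials from the directed phase onwards
                    environment_id=environment_id,
                    t=t,
                    x=x,
                    y=np.clip(base + dev, -245.0, 245.0),
                    z=z,
                    provenance=frozenset({"raw", "filtered", "trimmed"}),
                )
            )
    return trajectories


__all__ = [
    "BeeProfile",
    "SimulationTimeout",
    "draw_profile",
    "simulate_trajectory",
    "simulate_experiment",
    "sample_route_population",
]
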