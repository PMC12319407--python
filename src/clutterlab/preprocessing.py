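"""Preprocessing: filtering, end-trimming and trajectory exclusion rules.

Raw reconstructed tracks are low-pass filtered (second-order Butterworth,
2 Hz cutoff, applied forward-backward for zero phase), flights where the
bee walked through the clutter are excluded from the characteristics set,
and the route-similarity set additionally trims the first and last 25 cm,
keeps only directed flights, and starts at the fifth trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .environment import Environment
from .trajectory import Trajectory, TrajectoryError


class FilterError(ValueError):
    """Raised when a trajectory cannot be filtered (too short / non-uniform)."""


class EmptyTrajectoryError(ValueError):
    """Raised when trimming leaves no samples."""


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing stage.

    filter_order / cutoff_hz: Butterworth low-pass design (2, 2 Hz).
    trim_mm: axial distance removed at each tunnel end (250 mm).
    directed_min_trial: first trial admitted to the similarity set (5).
    reversal_limit_mm: largest backward excursion (drop from the running
        maximum of x) a directed flight may contain (100 mm): small
        obstacle-avoidance backtracks pass, tunnel-scale returns fail.
    walking_z_mm / walking_speed_mps: a flight counts as walking when
        median height AND median ground speed both fall below these.
    """

    filter_order: int = 2
    cutoff_hz: float = 2.0
    trim_mm: float = 250.0
    directed_min_trial: int = 5
    reversal_limit_mm: float = 100.0
    walking_z_mm: float = 20.0
    walking_speed_mps: float = 0.05

    def __post_init__(self) -> None:
        if self.trim_mm < 0:
            raise ValueError("trim_mm must be >= 0")
        for name in ("cutoff_hz", "reversal_limit_mm", "walking_z_mm", "walking_speed_mps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def lowpass_filter(traj: Trajectory, cfg: PreprocessConfig = PreprocessConfig()) -> Trajectory:
    """Zero-phase Butterworth low-pass of each coordinate.

    The forward-backward pass squares the magnitude response of the
    second-order design, so attenuation at the cutoff is -6 dB rather than
    -3 dB; timestamps are unchanged and provenance gains ``filtered``.
    """
    fs = traj.sampling_rate()
    if cfg.cutoff_hz >= fs / 2.0:
        raise FilterError(f"cutoff {cfg.cutoff_hz} Hz >= Nyquist {fs / 2.0} Hz")
    dt = np.diff(traj.t)
    if traj.n >= 2 and np.any(np.abs(dt - np.median(dt)) > 0.01 * np.median(dt)):
        raise FilterError(f"{traj.key}: non-uniform sampling")
    b, a = signal.butter(cfg.filter_order, cfg.cutoff_hz, btype="low", fs=fs)
    min_len = max(3 * (2 * cfg.filter_order + 1), 3 * cfg.filter_order)
    if traj.n <= min_len:
        raise FilterError(f"{traj.key}: {traj.n} samples too few for order-{cfg.filter_order} filtering")
    # Gustafsson's forward-backward method: minimal end transients
    filt = lambda arr: signal.filtfilt(b, a, arr, method="gust")
    return traj.with_samples(traj.t, filt(traj.x), filt(traj.y), filt(traj.z)).with_provenance("filtered")


def trim_ends(traj: Trajectory, cfg: PreprocessConfig = PreprocessConfig(),
              env: Environment | None = None) -> Trajectory:
    """Drop samples within ``trim_mm`` of the entrance or exit plane.

    Trimming is by axial (x) distance.  The tunnel length comes from
    ``env`` when given, else defaults to 2000 mm.
    """
    length = env.tunnel_length if env is not None else 2000.0
    keep = (traj.x >= cfg.trim_mm) & (traj.x <= length - cfg.trim_mm)
    if not keep.any():
        raise EmptyTrajectoryError(f"{traj.key}: no samples survive trimming")
    return traj.with_samples(
        traj.t[keep], traj.x[keep], traj.y[keep], traj.z[keep]
    ).with_provenance("trimmed")


def _ground_speed(traj: Trajectory) -> np.ndarray:
    vx = np.gradient(traj.x, traj.t)
    vy = np.gradient(traj.y, traj.t)
    return np.hypot(vx, vy) / 1000.0  # m/s


def is_walking(traj: Trajectory, cfg: PreprocessConfig = PreprocessConfig()) -> bool:
    """True iff the bee crossed on foot: low height AND low ground speed (medians)."""
    return bool(
        np.median(traj.z) < cfg.walking_z_mm
        and np.median(_ground_speed(traj)) < cfg.walking_speed_mps
    )


def max_backward_excursion(traj: Trajectory) -> float:
    """Largest drop (mm) from the running maximum of x."""
    return float(np.max(np.maximum.accumulate(traj.x) - traj.x))


def is_directed(traj: Trajectory, cfg: PreprocessConfig = PreprocessConfig()) -> bool:
    """True iff no backward excursion along x strictly exceeds the limit."""
    return max_backward_excursion(traj) <= cfg.reversal_limit_mm


@dataclass
class PreprocessResult:
    """Output of a batch preprocessing run.

    metrics_set: filtered, non-walking flights of all trials (feeds the
        flight-characteristics table).
    similarity_set: additionally trimmed, directed, trial >= 5 (feeds the
        Hausdorff / similarity-index analysis).
    log: one row per exclusion, with the set it applies to and a single
        primary reason (priority walking > not_directed > too_short, plus
        early_trial for the similarity set's trial cut).
    """

    metrics_set: list[Trajectory]
    similarity_set: list[Trajectory]
    log: pd.DataFrame


_LOG_COLUMNS = ["bee_id", "trial", "excluded_from", "reason"]


def preprocess_experiment(
    trajectories: list[Trajectory],
    env: Environment,
    cfg: PreprocessConfig = PreprocessConfig(),
) -> PreprocessResult:
    """Run the full preprocessing cascade over an experiment's flights.

    Per-flight failures are logged, never raised, so one broken track does
    not abort the batch.
    """
    metrics_set: list[Trajectory] = []
    similarity_set: list[Trajectory] = []
    rows: list[dict] = []

    def _log(tr: Trajectory, which: str, reason: str) -> None:
        rows.append({"bee_id": tr.bee_id, "trial": tr.trial,
                     "excluded_from": which, "reason": reason})

    for tr in trajectories:
        # exclusion priority: walking > not_directed > too_short
        if is_walking(tr, cfg):
            _log(tr, "both", "walking")
            continue
        try:
            filtered = lowpass_filter(tr, cfg)
        except (FilterError, TrajectoryError) as exc:
            _log(tr, "both", "too_short")
            continue
        metrics_set.append(filtered)

        if tr.trial < cfg.directed_min_trial:
            _log(tr, "similarity", "early_trial")
            continue
        try:
            trimmed = trim_ends(filtered, cfg, env)
        except EmptyTrajectoryError:
            _log(tr, "similarity", "too_short")
            continue
        if not is_directed(trimmed, cfg):
            _log(tr, "similarity", "not_directed")
            continue
        similarity_set.append(trimmed)

    return PreprocessResult(
        metrics_set=metrics_set,
        similarity_set=similarity_set,
        log=pd.DataFrame(rows, columns=_LOG_COLUMNS),
    )


__all__ = [
    "PreprocessConfig",
    "PreprocessResult",
    "FilterError",
    "EmptyTrajectoryError",
    "lowpass_filter",
    "trim_ends",
    "is_walking",
    "is_directed",
    "max_backward_excursion",
    "preprocess_experiment",
]
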