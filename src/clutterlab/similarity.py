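"""Route idiosyncrasy: Hausdorff distances and the bootstrap similarity index.

The analysis asks whether an individual bee's directed flights resemble each
other more than randomly chosen flights from the whole population do.  All
pairwise trajectory distances are computed with the symmetric Hausdorff
distance on the top-view (x, y) point sets.  For each bee the similarity
index is

    SD(within-bee pairwise distances) / SD(pairwise distances of a random
    population sample of the same size),

where the denominator sample is redrawn (without replacement, focal bee
included) over ``n_boot`` bootstrap replicates and the per-bee index is the
mean over replicates.  An index below 1 means the bee's routes are
idiosyncratic.  At the population level a one-sample Wilcoxon signed-rank
test asks whether the median per-bee index differs from 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import directed_hausdorff

from .trajectory import Trajectory


class InsufficientDataError(ValueError):
    """Raised when a bee has too few directed flights for an index."""


class DegenerateTestError(ValueError):
    """Raised when the signed-rank test has no nonzero differences."""


def hausdorff(traj_a: Trajectory, traj_b: Trajectory, *, dims: int = 2) -> float:
    """Symmetric Hausdorff distance (mm) between two trajectories.

    max(h(A,B), h(B,A)) with h(A,B) = max over points of A of the distance
    to the nearest point of B.  ``dims=2`` (default) compares top-view
    (x, y) point sets; ``dims=3`` includes height.
    """
    if traj_a.n < 1 or traj_b.n < 1:
        raise ValueError("hausdorff needs non-empty trajectories")
    if dims == 2:
        a, b = traj_a.points_xy(), traj_b.points_xy()
    elif dims == 3:
        a, b = traj_a.points_xyz(), traj_b.points_xyz()
    else:
        raise ValueError("dims must be 2 or 3")
    return max(directed_hausdorff(a, b)[0], directed_hausdorff(b, a)[0])


@dataclass
class DistanceMatrix:
    """Symmetric pairwise Hausdorff distances with (bee_id, trial) labels."""

    labels: list[tuple[str, int]]
    values: np.ndarray

    @property
    def bee_ids(self) -> list[str]:
        return [b for b, _ in self.labels]

    def indices_of(self, bee_id: str) -> np.ndarray:
        return np.array([i for i, (b, _) in enumerate(self.labels) if b == bee_id], dtype=int)

    def submatrix_sd(self, idx: np.ndarray) -> float:
        """Sample SD of the upper-triangle pairwise distances among ``idx``."""
        sub = self.values[np.ix_(idx, idx)]
        vals = sub[np.triu_indices(len(idx), k=1)]
        return float(np.std(vals, ddof=1))

    def to_frame(self) -> pd.DataFrame:
        names = [f"{b}:{t}" for b, t in self.labels]
        return pd.DataFrame(self.values, index=names, columns=names)


def distance_matrix(trajectories: list[Trajectory], *, dims: int = 2) -> DistanceMatrix:
    """All pairwise symmetric Hausdorff distances over a trajectory set."""
    if len(trajectories) < 2:
        raise ValueError("distance matrix needs >= 2 trajectories")
    labels = [tr.key for tr in trajectories]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate (bee_id, trial) labels in trajectory set")
    env_ids = {tr.environment_id for tr in trajectories}
    if len(env_ids) != 1:
        raise ValueError(f"trajectories span several environments: {sorted(env_ids)}")
    n = len(trajectories)
    m = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = hausdorff(trajectories[i], trajectories[j], dims=dims)
    return DistanceMatrix(labels=labels, values=m)


def similarity_index(
    bee_id: str,
    dm: DistanceMatrix,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    *,
    max_redraws: int = 100,
) -> tuple[float, np.ndarray]:
    """Bootstrap similarity index of one bee against the population.

    The numerator — the SD of the bee's own n_i(n_i-1)/2 pairwise distances
    — is fixed; each replicate redraws n_i trajectories from the whole
    matrix without replacement and uses the SD of their pairwise distances
    as the denominator.  Replicates with a zero denominator are redrawn up
    to ``max_redraws`` times.  Returns (mean over replicates, all replicate
    indices); deterministic given ``seed``.
    """
    own = dm.indices_of(bee_id)
    n_i = len(own)
    if n_i < 3:
        raise InsufficientDataError(f"bee {bee_id}: {n_i} directed flights, need >= 3")
    n_total = len(dm.labels)
    if n_total <= n_i:
        raise InsufficientDataError(f"bee {bee_id}: population not larger than own flight count")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    numerator = dm.submatrix_sd(own)
    indices = np.empty(n_boot)
    for r in range(n_boot):
        for _ in range(max_redraws):
            sample = rng.choice(n_total, size=n_i, replace=False)
            denom = dm.submatrix_sd(sample)
            if denom > 0:
                break
        else:
            raise RuntimeError(f"bee {bee_id}: zero-SD population sample in every redraw")
        indices[r] = numerator / denom
    return float(indices.mean()), indices


def similarity_test(per_bee_means) -> tuple[float, float]:
    """Two-sided one-sample Wilcoxon signed-rank test of the indices against 1.

    Uses the exact null distribution when n <= 25 with no ties or zero
    differences, otherwise the normal approximation with continuity and tie
    correction.
    """
    vals = np.asarray(per_bee_means, dtype=float)
    if len(vals) < 5:
        raise InsufficientDataError(f"signed-rank test needs >= 5 values, got {len(vals)}")
    diffs = vals - 1.0
    if np.all(diffs == 0.0):
        raise DegenerateTestError("all indices exactly 1: no nonzero differences")
    nz = diffs[diffs != 0.0]
    exact = len(nz) <= 25 and len(np.unique(np.abs(nz))) == len(nz) and np.all(diffs != 0.0)
    res = stats.wilcoxon(diffs, alternative="two-sided",
                         method="exact" if exact else "approx", correction=True)
    return float(res.statistic), float(res.pvalue)


@dataclass
class RouteSimilarityResults:
    """Fitted similarity analysis: per-bee indices plus the population test."""

    per_bee: pd.DataFrame            # bee_id, n_trajs, mean_index
    bootstrap_indices: dict          # bee_id -> (n_boot,) replicate indices
    population_median: float
    statistic: float
    p_value: float
    n_boot: int
    rng_seed: int
    skipped: pd.DataFrame            # bees without enough directed flights

    def summary(self) -> str:
        lines = [
            "Route similarity (bootstrap Hausdorff index)",
            "=" * 44,
            f"bees analysed:      {len(self.per_bee)}"
            + (f"  (skipped: {len(self.skipped)})" if len(self.skipped) else ""),
            f"bootstrap reps:     {self.n_boot}   seed: {self.rng_seed}",
            f"population median:  {self.population_median:.4f}",
            f"Wilcoxon signed-rank vs 1: W = {self.statistic:.1f}, p = {self.p_value:.3g}",
            "",
            self.per_bee.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


class RouteSimilarity:
    """Model object for the route-idiosyncrasy analysis.

    Build it from a set of directed, trimmed trajectories (or a precomputed
    :class:`DistanceMatrix`); :meth:`fit` runs the bootstrap for every bee
    with at least ``min_flights`` directed flights and the population-level
    signed-rank test.
    """

    def __init__(self, dm: DistanceMatrix):
        self.dm = dm

    @classmethod
    def from_trajectories(cls, trajectories: list[Trajectory], *, dims: int = 2) -> "RouteSimilarity":
        return cls(distance_matrix(trajectories, dims=dims))

    def fit(self, n_boot: int = 1000, seed: int = 0, *, min_flights: int = 3) -> RouteSimilarityResults:
        bees = sorted(set(self.dm.bee_ids))
        per_bee_rows, skipped_rows, boots = [], [], {}
        for k, bee in enumerate(bees):
            sub_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))
            n_i = len(self.dm.indices_of(bee))
            if n_i < min_flights or len(self.dm.labels) <= n_i:
                skipped_rows.append({"bee_id": bee, "n_trajs": n_i})
                continue
            mean_idx, reps = similarity_index(bee, self.dm, n_boot=n_boot, seed=sub_rng)
            boots[bee] = reps
            per_bee_rows.append({"bee_id": bee, "n_trajs": n_i, "mean_index": mean_idx})
        per_bee = pd.DataFrame(per_bee_rows, columns=["bee_id", "n_trajs", "mean_index"])
        if len(per_bee) >= 5:
            stat, p = similarity_test(per_bee["mean_index"].to_numpy())
        else:
            stat, p = float("nan"), float("nan")
        return RouteSimilarityResults(
            per_bee=per_bee,
            bootstrap_indices=boots,
            population_median=float(per_bee["mean_index"].median()) if len(per_bee) else float("nan"),
            statistic=stat,
            p_value=p,
            n_boot=n_boot,
            rng_seed=seed,
            skipped=pd.DataFrame(skipped_rows, columns=["bee_id", "n_trajs"]),
        )


__all__ = [
    "hausdorff",
    "DistanceMatrix",
    "distance_matrix",
    "similarity_index",
    "similarity_test",
    "RouteSimilarity",
    "RouteSimilarityResults",
    "InsufficientDataError",
    "DegenerateTestError",
]
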