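"""Run configuration: one YAML file drives the whole pipeline.

A single master seed feeds per-stage substreams (environment layout,
each environment's simulation, the similarity bootstrap) through numpy
SeedSequence spawn keys, so any stage can be rerun in isolation and still
reproduce bit-identically.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .preprocessing import PreprocessConfig


def _substream(master_seed: int, key: int) -> int:
    """Derive a stage seed (< 2^31) from the master seed."""
    return int(np.random.SeedSequence(master_seed, spawn_key=(key,)).generate_state(1)[0] % (2**31))


@dataclass
class EnvironmentConfig:
    n_obstacles: int = 110
    min_gap_mm: float = 70.0
    n_transparent_env2: int = 32
    tunnel_length_mm: float = 2000.0
    tunnel_width_mm: float = 500.0
    tunnel_height_mm: float = 300.0


@dataclass
class SimulationConfig:
    n_bees_env1: int = 8
    n_bees_env2: int = 8
    n_trials: int = 15
    between_bee_offset_sd_mm: float = 60.0
    speed_mean_mps: float = 0.37
    speed_jitter_sd_mps: float = 0.08
    exploration_decay: float = 0.5
    n_reversals0: float = 6.0
    transparent_factor: float = 0.5
    time_cap_s: float = 300.0


@dataclass
class SimilarityConfig:
    n_boot: int = 1000
    dims: int = 2
    min_flights: int = 3


@dataclass
class StatsConfig:
    m_tests: int = 6
    family: str = "lognormal_lmm"


@dataclass
class RunConfig:
    master_seed: int = 0
    environment: EnvironmentConfig = field(default_factory=EnvironmentConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    similarity: SimilarityConfig = field(default_factory=SimilarityConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)

    # stage seed derivation (documented substream keys)
    @property
    def env_seed(self) -> int:
        return _substream(self.master_seed, 0)

    @property
    def sim_seed_env1(self) -> int:
        return _substream(self.master_seed, 1)

    @property
    def sim_seed_env2(self) -> int:
        return _substream(self.master_seed, 2)

    @property
    def similarity_seed(self) -> int:
        return _substream(self.master_seed, 3)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            master_seed=int(d.get("master_seed", 0)),
            environment=EnvironmentConfig(**d.get("environment", {})),
            simulation=SimulationConfig(**d.get("simulation", {})),
            preprocess=PreprocessConfig(**d.get("preprocess", {})),
            similarity=SimilarityConfig(**d.get("similarity", {})),
            stats=StatsConfig(**d.get("stats", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def demo_config(master_seed: int = 0, *, n_bees: int = 8, n_trials: int = 15,
                n_boot: int = 1000) -> RunConfig:
    """The default demo experiment: two environments, ``n_bees`` bees each."""
    cfg = RunConfig(master_seed=master_seed)
    cfg.simulation.n_bees_env1 = n_bees
    cfg.simulation.n_bees_env2 = n_bees
    cfg.simulation.n_trials = n_trials
    cfg.similarity.n_boot = n_boot
    return cfg


__all__ = [
    "RunConfig",
    "EnvironmentConfig",
    "SimulationConfig",
    "SimilarityConfig",
    "StatsConfig",
    "demo_config",
]
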