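"""End-to-end orchestration: simulate -> preprocess -> metrics -> similarity -> stats.

``run_all`` executes the whole pipeline from one :class:`RunConfig` and a
master seed, writing every artifact (environments, trajectories, exclusion
log, metrics table, similarity results, model summaries, a markdown report
and figures) into one output directory.  Identical config + seed yields
bit-identical numeric outputs: no artifact contains a timestamp, and every
CSV carries a provenance comment (config hash + master seed) in its first
line.
"""

from __future__ import annotations

import json
import traceback
from pathlib import Path

import numpy as np
import pandas as pd
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .config import RunConfig
from .environment import Environment, environment_pair
from .trajectory import Trajectory, write_csv, read_csv, from_frame
from .synthetic import simulate_experiment
from .preprocessing import preprocess_experiment, PreprocessResult
from .metrics import compute_metrics_table, METRIC_NAMES
from .similarity import RouteSimilarity, RouteSimilarityResults
from .stats import (ModelSpec, fit_mixed_model, lrt_compare, random_effect_gain,
                    compare_groups, ConvergenceError)
from .plotting import plot_trajectories, plot_metric_by_trial


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _provenance(cfg: RunConfig) -> str:
    return f"clutterlab {__version__} config={cfg.config_hash()} master_seed={cfg.master_seed}"


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {_provenance(cfg)}\n")
        df.to_csv(fh, index=False)


def run_all(cfg: RunConfig, out_dir, *, make_plots: bool = True) -> Path:
    """Run the full pipeline; returns the artifact directory.

    On a stage failure the partial artifacts are preserved and a
    :class:`StageError` naming the stage is raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        cfg.to_yaml(out / "config.yaml")
        (out / "manifest.json").write_text(json.dumps({
            "package": "clutterlab",
            "version": __version__,
            "master_seed": cfg.master_seed,
            "config_hash": cfg.config_hash(),
            "stage_seeds": {
                "environment": cfg.env_seed,
                "simulate_env1": cfg.sim_seed_env1,
                "simulate_env2": cfg.sim_seed_env2,
                "similarity": cfg.similarity_seed,
            },
        }, indent=1))

        stage = "environment"
        ec = cfg.environment
        env1, env2 = environment_pair(
            seed=cfg.env_seed,
            n_obstacles=ec.n_obstacles,
            min_gap=ec.min_gap_mm,
            n_transparent=ec.n_transparent_env2,
            tunnel_length=ec.tunnel_length_mm,
            tunnel_width=ec.tunnel_width_mm,
            tunnel_height=ec.tunnel_height_mm,
        )
        env1.to_json(out / "env1.json")
        env2.to_json(out / "env2.json")

        stage = "simulate"
        sc = cfg.simulation
        profile_kwargs = dict(
            speed_mean=sc.speed_mean_mps,
            speed_jitter_sd=sc.speed_jitter_sd_mps,
            exploration_decay=sc.exploration_decay,
            n_reversals0=sc.n_reversals0,
        )
        sim_kwargs = dict(transparent_factor=sc.transparent_factor, time_cap=sc.time_cap_s)
        batches: dict[str, list[Trajectory]] = {}
        sim_logs = []
        for env, n_bees, seed in (
            (env1, sc.n_bees_env1, cfg.sim_seed_env1),
            (env2, sc.n_bees_env2, cfg.sim_seed_env2),
        ):
            trajs, log = simulate_experiment(
                n_bees, sc.n_trials, env, master_seed=seed,
                between_bee_offset_sd=sc.between_bee_offset_sd_mm,
                profile_kwargs=profile_kwargs, **sim_kwargs,
            )
            batches[env.layout_id] = trajs
            sim_logs.append(log)
        write_csv(batches["env1"] + batches["env2"], out / "trajectories.csv",
                  header_comment=_provenance(cfg))
        _write_csv(pd.concat(sim_logs, ignore_index=True), out / "simulation_log.csv", cfg)

        stage = "preprocess"
        pre: dict[str, PreprocessResult] = {
            "env1": preprocess_experiment(batches["env1"], env1, cfg.preprocess),
            "env2": preprocess_experiment(batches["env2"], env2, cfg.preprocess),
        }
        _write_csv(
            pd.concat(
                [r.log.assign(environment_id=k) for k, r in pre.items()], ignore_index=True
            ),
            out / "exclusions.csv", cfg,
        )

        stage = "metrics"
        metrics_tables = {
            "env1": compute_metrics_table(pre["env1"].metrics_set, env1),
            "env2": compute_metrics_table(pre["env2"].metrics_set, env2),
        }
        metrics_all = pd.concat(metrics_tables.values(), ignore_index=True)
        _write_csv(metrics_all, out / "metrics.csv", cfg)

        stage = "similarity"
        sim_results: dict[str, RouteSimilarityResults] = {}
        per_bee_frames = []
        for k in ("env1", "env2"):
            trajs = pre[k].similarity_set
            if len(trajs) < 4:
                continue
            model = RouteSimilarity.from_trajectories(trajs, dims=cfg.similarity.dims)
            _write_csv(model.dm.to_frame().reset_index().rename(columns={"index": "label"}),
                       out / f"distance_matrix_{k}.csv", cfg)
            res = model.fit(cfg.similarity.n_boot, seed=cfg.similarity_seed,
                            min_flights=cfg.similarity.min_flights)
            sim_results[k] = res
            per_bee_frames.append(res.per_bee.assign(environment_id=k))
        if per_bee_frames:
            _write_csv(pd.concat(per_bee_frames, ignore_index=True), out / "similarity.csv", cfg)
        (out / "similarity_test.json").write_text(json.dumps({
            k: {
                "population_median": r.population_median,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "n_bees": len(r.per_bee),
                "n_boot": r.n_boot,
            } for k, r in sim_results.items()
        }, indent=1, allow_nan=True))

        stage = "stats"
        model_rows = []
        for response in METRIC_NAMES:
            usable = metrics_all.dropna(subset=[response])
            if usable.empty or usable["bee_id"].nunique() < 2:
                continue
            spec_full = ModelSpec(response, ("trial", "environment"), "bee", cfg.stats.family)
            full = fit_mixed_model(metrics_all, spec_full)
            row = {
                "response": response,
                "n_obs": full.n_obs,
                "coef_trial": full.params.get("trial", np.nan),
                "se_trial": full.bse.get("trial", np.nan),
                "coef_environment": full.params.get("environment", np.nan),
                "se_environment": full.bse.get("environment", np.nan),
                "re_var_bee": full.random_effect_var,
                "log_likelihood": full.log_likelihood,
                "converged": full.converged,
            }
            for drop in ("trial", "environment"):
                kept = tuple(f for f in spec_full.fixed_effects if f != drop)
                reduced = fit_mixed_model(metrics_all, ModelSpec(response, kept, "bee", cfg.stats.family))
                try:
                    chi2, df, p = lrt_compare(full, reduced)
                except ConvergenceError:
                    chi2, p = np.nan, np.nan
                    row["converged"] = False
                row[f"lrt_chi2_{drop}"] = chi2
                row[f"lrt_p_{drop}"] = p
            try:
                chi2_re, p_re = random_effect_gain(metrics_all, spec_full)
            except ConvergenceError:
                chi2_re, p_re = np.nan, np.nan
                row["converged"] = False
            row["re_chi2"] = chi2_re
            row["re_p"] = p_re
            model_rows.append(row)
        models_df = pd.DataFrame(model_rows)
        _write_csv(models_df, out / "models.csv", cfg)

        comp_frames = []
        if not metrics_tables["env1"].empty and not metrics_tables["env2"].empty:
            for sel in ("first", "last"):
                comp_frames.append(
                    compare_groups(metrics_tables["env1"], metrics_tables["env2"], sel,
                                   m_tests=cfg.stats.m_tests)
                )
            _write_csv(pd.concat(comp_frames, ignore_index=True), out / "comparisons.csv", cfg)

        stage = "report"
        _write_report(out, cfg, pre, metrics_all, sim_results, models_df,
                      pd.concat(comp_frames, ignore_index=True) if comp_frames else None)
        if make_plots:
            fig, axes = plt.subplots(2, 1, figsize=(10, 6))
            plot_trajectories(pre["env1"].similarity_set, env1, ax=axes[0])
            plot_trajectories(pre["env2"].similarity_set, env2, ax=axes[1])
            fig.tight_layout()
            fig.savefig(out / "trajectories.png", dpi=110)
            plt.close(fig)
            fig, axes = plt.subplots(2, 3, figsize=(12, 6))
            for ax, m in zip(axes.ravel(), METRIC_NAMES):
                plot_metric_by_trial(metrics_all, m, ax=ax)
            fig.tight_layout()
            fig.savefig(out / "metrics_by_trial.png", dpi=110)
            plt.close(fig)
    except Exception as exc:
        (out / "error.log").write_text(f"stage: {stage}\n{traceback.format_exc()}")
        raise StageError(stage, exc) from exc
    return out


def _write_report(out: Path, cfg: RunConfig, pre, metrics_all, sim_results, models_df, comparisons):
    """Markdown report mirroring the study's figure logic, tables first."""
    lines = [
        "# clutterlab run report",
        "",
        f"provenance: `{_provenance(cfg)}`",
        "",
        "## Exclusions",
        "",
        pd.concat([r.log.assign(environment_id=k) for k, r in pre.items()], ignore_index=True)
        .groupby(["environment_id", "reason"]).size().rename("n").reset_index()
        .to_string(index=False) if any(len(r.log) for r in pre.values()) else "none",
        "",
        "## Flight characteristics by trial (medians)",
        "",
        metrics_all.groupby(["environment_id", "trial"])[METRIC_NAMES]
        .median().round(3).reset_index().to_string(index=False),
        "",
        "## Route similarity",
        "",
    ]
    for k, r in sim_results.items():
        lines += [f"### {k}", "", "```", r.summary(), "```", ""]
    if not models_df.empty:
        lines += ["## Mixed models (log scale, ML)", "",
                  models_df.round(4).to_string(index=False), ""]
    if comparisons is not None:
        lines += ["## Naive vs experienced, between environments (rank-sum, Bonferroni)", "",
                  comparisons.round(4).to_string(index=False), ""]
    (out / "report.md").write_text("\n".join(lines))


def validate_inputs(traj_csv, env_file) -> pd.DataFrame:
    """Schema and invariant checks of external inputs.

    Returns a violation table (source, location, issue); empty when the
    inputs are well-formed.
    """
    rows = []
    env = None
    try:
        env = Environment.from_json(env_file)
    except Exception as exc:
        rows.append({"source": str(env_file), "location": "", "issue": f"unreadable: {exc}"})
    if env is not None:
        half_w = env.tunnel_width / 2.0
        for i, o in enumerate(env.obstacles):
            if not (0.0 < o.x < env.tunnel_length and abs(o.y) < half_w):
                rows.append({"source": str(env_file), "location": f"obstacle {i}",
                             "issue": "outside tunnel footprint"})

    df = pd.read_csv(traj_csv, comment="#")
    missing = [c for c in ("bee_id", "trial", "environment_id", "t_s", "x_mm", "y_mm", "z_mm")
               if c not in df.columns]
    if missing:
        rows.append({"source": str(traj_csv), "location": "header",
                     "issue": f"missing columns: {missing}"})
        return pd.DataFrame(rows, columns=["source", "location", "issue"])
    for (bee, trial, _), g in df.groupby(["bee_id", "trial", "environment_id"]):
        t = g["t_s"].to_numpy()
        if len(t) < 2:
            rows.append({"source": str(traj_csv), "location": f"({bee},{trial})",
                         "issue": "fewer than 2 samples"})
            continue
        bad = np.where(np.diff(t) <= 0)[0]
        for b in bad:
            rows.append({"source": str(traj_csv),
                         "location": f"({bee},{trial}) row {g.index[b + 1]}",
                         "issue": "non-monotone t_s"})
        if env is not None and len(bad) == 0:
            tr = from_frame(g)[0]
            try:
                tr.validate(env)
            except Exception as exc:
                rows.append({"source": str(traj_csv), "location": f"({bee},{trial})",
                             "issue": str(exc)})
    return pd.DataFrame(rows, columns=["source", "location", "issue"])


__all__ = ["run_all", "validate_inputs", "StageError"]
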