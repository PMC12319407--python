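"""Plot helpers for the pipeline report: top-view trajectories and
per-trial characteristic development."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .environment import Environment, TRANSPARENT
from .trajectory import Trajectory


def plot_trajectories(trajectories: list[Trajectory], env: Environment, ax=None):
    """Top view of flights over the obstacle layout (open circles = transparent)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    for o in env.obstacles:
        filled = o.salience != TRANSPARENT
        ax.plot(o.x, o.y, "o", ms=3, mfc="k" if filled else "none", mec="k", mew=0.6)
    for tr in trajectories:
        ax.plot(tr.x, tr.y, lw=0.7, alpha=0.6)
    ax.set_xlim(0, env.tunnel_length)
    ax.set_ylim(-env.tunnel_width / 2, env.tunnel_width / 2)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title(env.layout_id)
    return ax


def plot_metric_by_trial(table, metric: str, ax=None):
    """Boxplots of one flight characteristic per trial."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    trials = sorted(table["trial"].unique())
    data = [table.loc[table["trial"] == t, metric].dropna().to_numpy() for t in trials]
    ax.boxplot(data, positions=trials, widths=0.6)
    ax.set_xlabel("trial")
    ax.set_ylabel(metric)
    return ax


__all__ = ["plot_trajectories", "plot_metric_by_trial"]
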