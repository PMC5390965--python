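"""Figures for the lifespan analysis: per-task curves, mean curves, and the
speed-accuracy path."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .tasks import TASK_ORDER

__all__ = ["plot_task_trajectories", "plot_mean_trajectories", "plot_speed_accuracy"]


def _band(ax, fit, color):
    ax.fill_between(fit.age_grid, fit.ci_lower, fit.ci_upper, alpha=0.25, color=color, lw=0)
    ax.plot(fit.age_grid, fit.fitted, color=color, lw=1.8)


def plot_task_trajectories(fits: dict, path) -> None:
    """CT (top row) and complexity (bottom row) by age, one column per task."""
    fig, axes = plt.subplots(2, len(TASK_ORDER), figsize=(16, 6), sharex=True)
    for j, tid in enumerate(TASK_ORDER):
        _band(axes[0, j], fits[f"ct_{tid}"], "tab:blue")
        axes[0, j].set_title(tid)
        _band(axes[1, j], fits[f"z_{tid}"], "tab:red")
        axes[1, j].set_xlabel("age (years)")
    axes[0, 0].set_ylabel("completion time (s)")
    axes[1, 0].set_ylabel("normalized complexity (z)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_mean_trajectories(ct_fit, z_fit, path) -> None:
    """(A) total CT and (B) mean complexity as a function of age."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    _band(ax1, ct_fit, "tab:blue")
    ax1.set_xlabel("age (years)")
    ax1.set_ylabel("total completion time (s)")
    ax1.set_title("A")
    _band(ax2, z_fit, "tab:red")
    ax2.set_xlabel("age (years)")
    ax2.set_ylabel("mean normalized complexity")
    ax2.set_title("B")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_speed_accuracy(path_df, scores, path) -> None:
    """Scatter of (total CT, mean z) with the age-parametrized trend path."""
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(scores["total_ct"], scores["mean_z"], s=4, alpha=0.15, color="gray")
    ax.plot(path_df["ct"], path_df["z"], color="tab:red", lw=2)
    for age in (10, 25, 40, 60, 75, 90):
        sel = path_df[path_df["age"] == age]
        if len(sel):
            ax.annotate(
                str(age),
                (sel["ct"].iloc[0], sel["z"].iloc[0]),
                fontsize=8,
                color="tab:red",
            )
    ax.set_xlabel("total completion time (s)")
    ax.set_ylabel("mean normalized complexity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
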