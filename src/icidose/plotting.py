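"""Matplotlib rendering of trajectories and sweep/population/sensitivity grids."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .simulate import Trajectory


def plot_trajectory(traj: Trajectory, F2: float | None = None):
    """Three-panel time course: tumor, immune compartments + F, central drug."""
    fig, axes = plt.subplots(3, 1, figsize=(7, 8), sharex=True)
    t = traj.times
    axes[0].plot(t, traj.series("x"), color="tab:red")
    axes[0].set_ylabel("tumor volume")
    for name, color in (("y1", "tab:green"), ("y2", "tab:orange"), ("y3", "tab:purple")):
        axes[1].plot(t, traj.series(name), label=name, color=color)
    axes[1].plot(t, traj.series("F"), label="F", color="tab:blue", ls="--")
    if F2 is not None:
        axes[1].axhline(F2, color="k", lw=0.8, ls=":", label="F2")
    axes[1].legend(loc="upper right", fontsize=8)
    axes[1].set_ylabel("immune / inflammation")
    axes[2].plot(t, traj.series("D_p"), color="tab:gray")
    axes[2].set_ylabel("central drug")
    axes[2].set_xlabel("time (days)")
    for td in traj.dose_times:
        axes[2].axvline(td, color="tab:gray", lw=0.4, alpha=0.5)
    fig.tight_layout()
    return fig


def heatmap(pivot: pd.DataFrame, title: str = "", cbar_label: str = "",
            ax=None, cmap="viridis", boundary: pd.DataFrame | None = None,
            log_scale: bool = False, vmin=None, vmax=None):
    """Render a (spacing x dose-count) pivot table as a heatmap.

    ``boundary`` is an optional boolean pivot of the same shape whose
    True region is outlined (used to overlay the effective-protocol
    boundary on metric maps).
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    values = pivot.values.astype(float)
    if log_scale:
        values = np.log10(np.maximum(values, 1e-12))
    im = ax.imshow(values, origin="lower", aspect="auto", cmap=cmap,
                   vmin=vmin, vmax=vmax,
                   extent=(pivot.columns.min() - 0.5, pivot.columns.max() + 0.5,
                           pivot.index.min() - 0.5, pivot.index.max() + 0.5))
    if boundary is not None:
        mask = boundary.reindex(index=pivot.index, columns=pivot.columns).values
        ax.contour(pivot.columns, pivot.index, mask.astype(float),
                   levels=[0.5], colors="red", linewidths=1.2)
    ax.set_xlabel("number of doses")
    ax.set_ylabel("spacing (days)")
    ax.set_title(title)
    plt.colorbar(im, ax=ax, label=cbar_label)
    return ax


def sweep_figure(grid, metrics=("eliminated", "auc_0_tau", "c_min", "c_avg")):
    """Outcome map plus PK-metric maps for a fractionation sweep."""
    fig, axes = plt.subplots(2, 2, figsize=(10, 8))
    for metric, ax in zip(metrics, axes.ravel()):
        piv = grid.pivot(metric)
        heatmap(piv.astype(float), title=metric, ax=ax,
                cmap="RdYlGn" if metric == "eliminated" else "viridis")
    fig.tight_layout()
    return fig


def area_figure(grid):
    """Inflammation-burden map with the effective-region boundary overlaid."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    heatmap(grid.pivot("area_above_F2"), title="area of F above F2",
            cbar_label="log10(signal-days)", ax=ax, log_scale=True,
            boundary=grid.pivot("eliminated").astype(float) > 0.5)
    fig.tight_layout()
    return fig


def population_figure(frames: dict):
    """One success-fraction heatmap per cumulative dose."""
    n = len(frames)
    fig, axes = plt.subplots(1, n, figsize=(4.5 * n, 4), squeeze=False)
    for ax, (total, frame) in zip(axes.ravel(), sorted(frames.items())):
        piv = frame.pivot(index="spacing_days", columns="n_doses", values="fraction")
        heatmap(piv, title=f"cumulative dose {total}", cbar_label="fraction eliminated",
                ax=ax, vmin=0, vmax=1)
    fig.tight_layout()
    return fig


def sensitivity_figure(frame: pd.DataFrame):
    """Grid of per-parameter flip-fraction heatmaps (censored cells = 1)."""
    names = list(dict.fromkeys(frame["parameter"]))
    ncol = 6
    nrow = int(np.ceil(len(names) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.8 * nrow), squeeze=False)
    for ax in axes.ravel()[len(names):]:
        ax.axis("off")
    for name, ax in zip(names, axes.ravel()):
        sub = frame[frame["parameter"] == name]
        piv = sub.pivot(index="spacing_days", columns="n_doses", values="flip_fraction")
        heatmap(piv, title=name, ax=ax, cmap="viridis_r", vmin=0, vmax=1)
    fig.tight_layout()
    return fig


def save_figure(fig, stem):
    """Write both raster and vector renderings next to each other."""
    paths = [f"{stem}.png", f"{stem}.pdf"]
    for path in paths:
        fig.savefig(path, dpi=150)
    plt.close(fig)
    return paths
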