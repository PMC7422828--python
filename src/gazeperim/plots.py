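"""Analysis figures: Bland-Altman and hill-of-vision plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .grid import TestGrid
from .stats import RepeatabilitySummary

__all__ = ["bland_altman_plot", "hill_plot"]


def bland_altman_plot(run1, run2, summary: RepeatabilitySummary,
                      path: str | Path, label: str = "MS (dB)") -> None:
    """Scatter of paired differences with mean and 95% limits of agreement."""
    run1 = np.asarray(run1, dtype=float)
    run2 = np.asarray(run2, dtype=float)
    mean = (run1 + run2) / 2.0
    diff = run2 - run1
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(mean, diff, s=18, alpha=0.7)
    ax.axhline(summary.mean_difference, color="k", lw=1)
    for lim in summary.limits_of_agreement:
        ax.axhline(lim, color="r", ls="--", lw=1)
    ax.set_xlabel(f"mean of runs, {label}")
    ax.set_ylabel(f"run 2 - run 1, {label}")
    ax.set_title(f"CoR95 = {summary.cor95:.2f} dB")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def hill_plot(values, grid: TestGrid, path: str | Path,
              title: str = "Hill of vision") -> None:
    """Top-down sensitivity map over the test grid (blind spots marked)."""
    values = np.asarray(values, dtype=float)
    xs = np.array([l.x for l in grid])
    ys = np.array([l.y for l in grid])
    blind = np.array([l.role == "blind_spot" for l in grid])
    fig, ax = plt.subplots(figsize=(6, 4))
    sc = ax.scatter(xs[~blind], ys[~blind], c=values[~blind], s=180,
                    cmap="viridis", vmin=0, vmax=34, marker="s")
    ax.scatter(xs[blind], ys[blind], c=values[blind], s=180, cmap="viridis",
               vmin=0, vmax=34, marker="o", edgecolors="r")
    for x, y, v in zip(xs, ys, values):
        ax.text(x, y, f"{v:.0f}", ha="center", va="center", fontsize=6, color="w")
    fig.colorbar(sc, ax=ax, label="DLS (dB)")
    ax.set_xlabel("x (deg, right-eye format)")
    ax.set_ylabel("y (deg)")
    ax.set_title(title)
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
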