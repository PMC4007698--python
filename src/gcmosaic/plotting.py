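"""Optional matplotlib output: GC weight histograms and regression scatterplots."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .codons import OrthologPair, RegressionFit
from .families import BinnedProfile

__all__ = ["plot_profile", "plot_fit"]


def plot_profile(profile: BinnedProfile, path: str | Path, title: str = "") -> None:
    """Bar plot of DNA weight (Mb) per GC bin."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(
        profile.bin_edges[:-1],
        profile.weight_mb,
        width=profile.bin_width,
        align="edge",
        color="steelblue",
        edgecolor="none",
    )
    ax.set_xlabel("GC, %")
    ax.set_ylabel("DNA, Mb")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_fit(
    x: Sequence[float],
    y: Sequence[float],
    fit: RegressionFit,
    path: str | Path,
    xlabel: str = "x",
    ylabel: str = "y",
) -> None:
    """Scatterplot with the fitted major axis and the main diagonal (dashed)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(x, y, ".", ms=2, alpha=0.4, color="k")
    lo = min(x.min(), y.min())
    hi = max(x.max(), y.max())
    grid = np.linspace(lo, hi, 2)
    ax.plot(grid, grid, "--", color="grey", lw=1)
    ax.plot(grid, fit.slope * grid + fit.intercept, "-", color="crimson", lw=1.5)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_title(f"y = {fit.slope:.2f}x + {fit.intercept:.1f}  R = {fit.r:.2f}  N = {fit.n}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
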