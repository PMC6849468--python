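"""Deterministic figure generation for screening reports."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .growth import BrokenStickFit

__all__ = ["plot_growth_fits", "plot_correlation_heatmap", "plot_timecourse_heatmap"]


def plot_growth_fits(
    series: pd.DataFrame,
    fits: list[BrokenStickFit],
    path: str | Path,
    *,
    max_panels: int = 6,
) -> Path:
    """Overlay fitted split lines on variety-mean growth series.

    ``series`` needs columns ``variety, n_level, das, eb_kpix``; one panel per
    fit, up to ``max_panels``.
    """
    fits = fits[:max_panels]
    ncol = min(3, len(fits))
    nrow = int(np.ceil(len(fits) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    for ax, fit in zip(axes.ravel(), fits):
        sub = series[
            (series["variety"] == fit.variety) & (series["n_level"] == fit.n_level)
        ]
        mean = sub.groupby("das")["eb_kpix"].mean()
        ax.plot(mean.index, mean.values, "o", ms=4, color="tab:green")
        xs = np.linspace(mean.index.min(), mean.index.max(), 200)
        ax.plot(xs, fit.predict(xs), "-", color="tab:red")
        ax.axvline(fit.breakpoint_x, ls=":", color="grey")
        ax.set_title(f"{fit.variety} ({fit.n_level}): bp {fit.breakpoint_x:.1f} DAS")
        ax.set_xlabel("DAS")
        ax.set_ylabel("EB (kPix)")
    for ax in axes.ravel()[len(fits) :]:
        ax.axis("off")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def plot_correlation_heatmap(r: pd.DataFrame, path: str | Path) -> Path:
    """Heatmap of a trait correlation matrix with r annotated per cell."""
    fig, ax = plt.subplots(figsize=(1.1 * len(r) + 2, 1.0 * len(r) + 1.5))
    im = ax.imshow(r.values, vmin=-1, vmax=1, cmap="RdYlGn")
    ax.set_xticks(range(len(r.columns)), r.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(r.index)), r.index)
    for i in range(len(r)):
        for j in range(len(r)):
            v = r.values[i, j]
            ax.text(j, i, "" if np.isnan(v) else f"{v:.2f}", ha="center", va="center")
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path


def plot_timecourse_heatmap(tc: pd.DataFrame, path: str | Path) -> Path:
    """Heatmap of EB-vs-harvest correlations by DAS and N level."""
    piv = tc.pivot_table(index=["n_level", "trait"], columns="das", values="r")
    fig, ax = plt.subplots(figsize=(0.5 * piv.shape[1] + 3, 0.6 * piv.shape[0] + 2))
    im = ax.imshow(piv.values, vmin=-1, vmax=1, cmap="RdYlGn", aspect="auto")
    ax.set_xticks(range(piv.shape[1]), [f"{d:g}" for d in piv.columns])
    ax.set_yticks(range(piv.shape[0]), [f"{a} {b}" for a, b in piv.index])
    ax.set_xlabel("DAS")
    fig.colorbar(im, ax=ax, label="Pearson r")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
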