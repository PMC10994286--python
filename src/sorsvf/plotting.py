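"""Plots: test-order maps and PCA compressibility / component maps."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .grid import GridSpec
from .sors import SORSPlan

#: order-map colour bands: first 4 locations, next 16, next 16, remainder
BAND_COLORS = ((4, "tab:red"), (20, "tab:blue"), (36, "tab:green"), (54, "0.6"))


def plot_sequence_map(plan: SORSPlan, ax=None, title: str | None = None):
    """Scatter the grid with each location labeled by its test rank."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    for x, y, rank in plan.sequence_map():
        color = next(c for lim, c in BAND_COLORS if rank <= lim)
        ax.scatter([x], [y], s=380, c=color, alpha=0.35, edgecolors="none")
        ax.text(x, y, str(rank), ha="center", va="center", fontsize=8)
    ax.set_xlabel("temporal  <-  x (deg)  ->  nasal" if False else "x (deg, temporal +)")
    ax.set_ylabel("y (deg, superior +)")
    ax.set_aspect("equal")
    ax.set_title(title or f"SORS order ({plan.kind})")
    return ax


def plot_compressibility(eigenvalues: np.ndarray, rmse_by_n: np.ndarray, ax=None):
    """PCA reconstruction RMSE as a function of retained components."""
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(np.arange(1, len(rmse_by_n) + 1), rmse_by_n, marker="o", ms=3)
    ax.set_xlabel("number of principal components")
    ax.set_ylabel("reconstruction RMSE (dB)")
    return ax


def plot_component_maps(basis, grid: GridSpec, n_show: int = 4):
    """Eigen-visual-fields: the leading components drawn on the grid."""
    fig, axes = plt.subplots(1, n_show, figsize=(4 * n_show, 4))
    xy = grid.coordinates()
    for i, ax in enumerate(np.atleast_1d(axes)):
        w = basis.components[:, i]
        lim = np.abs(w).max()
        sc = ax.scatter(xy[:, 0], xy[:, 1], c=w, cmap="RdBu_r", vmin=-lim, vmax=lim, s=300)
        ax.set_title(f"PC{i + 1}")
        ax.set_aspect("equal")
        fig.colorbar(sc, ax=ax, shrink=0.7)
    return fig
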