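"""Scatter and funnel plots for the surrogacy analysis.

The scatter mirrors the standard trial-level surrogacy display: one
circle per randomized comparison at (log-OR surrogate, log-OR final),
circle area proportional to randomized patients, with the
patient-weighted regression line overlaid.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .surrogacy import RegressionFit

__all__ = ["scatter_plot", "funnel_plot"]

# strip volatile metadata so identical inputs give identical SVG bytes
_SVG_META = {"Date": None}


def scatter_plot(pairs, fit: RegressionFit, path, *,
                 xlabel: str = "log OR (bleeding)",
                 ylabel: str = "log OR (mortality)",
                 title: str = "") -> Path:
    """Plot one endpoint pairing with patient-proportional circles."""
    x = np.array([p.x for p in pairs])
    y = np.array([p.y for p in pairs])
    w = np.array([p.w for p in pairs])
    fig, ax = plt.subplots(figsize=(5.5, 5))
    ax.scatter(x, y, s=1200 * w / w.max(), alpha=0.45,
               edgecolors="tab:blue", facecolors="lightsteelblue")
    grid = np.linspace(x.min(), x.max(), 50)
    ax.plot(grid, fit.predict(grid), color="tab:red", linewidth=1.5,
            label=f"weighted fit (R² = {fit.r2:.2f})")
    ax.axhline(0.0, color="grey", linewidth=0.6)
    ax.axvline(0.0, color="grey", linewidth=0.6)
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    if title:
        ax.set_title(title)
    ax.legend(loc="best", frameon=False)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, metadata=_SVG_META if path.suffix == ".svg" else None)
    plt.close(fig)
    return path


def funnel_plot(funnel, path, *, xlabel: str = "log OR") -> Path:
    """Standard-error-vs-effect funnel with the fixed-effect centerline."""
    effects = np.array([p[0] for p in funnel.points])
    ses = np.array([p[1] for p in funnel.points])
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    ax.scatter(effects, ses, s=18, color="tab:blue", alpha=0.7)
    ax.axvline(funnel.center, color="tab:red", linewidth=1.0)
    se_grid = np.linspace(0, ses.max() * 1.05, 50)
    for sign in (-1, 1):
        ax.plot(funnel.center + sign * 1.959964 * se_grid, se_grid,
                linestyle="--", color="grey", linewidth=0.8)
    ax.set_ylim(ses.max() * 1.05, 0)
    ax.set_xlabel(xlabel)
    ax.set_ylabel("standard error")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, metadata=_SVG_META if path.suffix == ".svg" else None)
    plt.close(fig)
    return path
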