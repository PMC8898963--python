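"""Simple matplotlib renderings of the pipeline's main outputs.

Deliberately plain: consensus heatmap, CDF family, KM step curves with the
log-rank p, forest plot of Cox fits, module-trait heatmap and the
association radar. Aesthetics are not part of any contract; every function
returns the Axes so callers can restyle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .consensus import CDF_GRID, ConsensusResult
from .survival import KMCurve

__all__ = ["plot_consensus_heatmap", "plot_cdf_curves", "plot_km",
           "plot_forest", "plot_module_trait", "plot_radar"]


def _save(fig, path):
    if path is not None:
        fig.savefig(path, bbox_inches="tight", dpi=120)
        plt.close(fig)


def plot_consensus_heatmap(result: ConsensusResult, path=None):
    order = result.assignment.labels.sort_values().index
    mat = result.consensus.loc[order, order]
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(mat.to_numpy(), vmin=0, vmax=1, cmap="Blues",
                   interpolation="nearest")
    ax.set_title(f"Consensus matrix, k={result.k}")
    ax.set_xticks([]); ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="consensus")
    _save(fig, path)
    return ax


def plot_cdf_curves(results: list[ConsensusResult], path=None):
    fig, ax = plt.subplots(figsize=(5, 4))
    for r in results:
        ax.plot(CDF_GRID, r.cdf, label=f"k={r.k}")
    ax.set_xlabel("consensus value")
    ax.set_ylabel("CDF")
    ax.legend(fontsize=8)
    _save(fig, path)
    return ax


def plot_km(curves: dict[str, KMCurve], logrank_p: float | None = None,
            path=None):
    fig, ax = plt.subplots(figsize=(5.5, 4))
    for label, c in sorted(curves.items()):
        t = np.concatenate([[0.0], np.repeat(c.times, 2)])
        s = np.concatenate([[1.0, 1.0], np.repeat(c.survival, 2)[:-1]]) \
            if len(c.times) else np.array([1.0])
        if len(c.times):
            ax.plot(t, s, drawstyle="default", label=f"{label} (n={c.n})")
        else:
            ax.axhline(1.0, label=f"{label} (n={c.n})")
    if logrank_p is not None:
        ax.text(0.55, 0.9, f"log-rank p = {logrank_p:.3g}",
                transform=ax.transAxes)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(fontsize=8)
    _save(fig, path)
    return ax


def plot_forest(table: pd.DataFrame, path=None):
    fig, ax = plt.subplots(figsize=(5.5, 0.5 * max(len(table), 2) + 1))
    ypos = np.arange(len(table))[::-1]
    ax.errorbar(table["HR"], ypos,
                xerr=[table["HR"] - table["ci95_low"],
                      table["ci95_high"] - table["HR"]],
                fmt="s", color="k", capsize=3)
    ax.axvline(1.0, color="grey", ls="--")
    ax.set_yticks(ypos)
    ax.set_yticklabels(table["term"])
    ax.set_xlabel("hazard ratio (95% CI)")
    _save(fig, path)
    return ax


def plot_module_trait(r_table: pd.DataFrame, p_table: pd.DataFrame, path=None):
    fig, ax = plt.subplots(figsize=(1.2 * r_table.shape[1] + 2,
                                    0.5 * r_table.shape[0] + 1.5))
    im = ax.imshow(r_table.to_numpy(dtype=float), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(r_table.shape[1]))
    ax.set_xticklabels(r_table.columns, rotation=45, ha="right")
    ax.set_yticks(range(r_table.shape[0]))
    ax.set_yticklabels(r_table.index)
    for i in range(r_table.shape[0]):
        for j in range(r_table.shape[1]):
            r = r_table.iat[i, j]
            p = p_table.iat[i, j]
            if np.isfinite(r):
                ax.text(j, i, f"{r:.2f}\n({p:.1g})", ha="center", va="center",
                        fontsize=7)
    fig.colorbar(im, ax=ax, label="Pearson r")
    _save(fig, path)
    return ax


def plot_radar(panel: pd.DataFrame, path=None):
    """Radar chart of an association panel (columns 'covariate' and 'r')."""
    labels = panel["covariate"].tolist()
    values = panel["r"].to_numpy(dtype=float)
    angles = np.linspace(0, 2 * np.pi, len(labels), endpoint=False)
    fig, ax = plt.subplots(figsize=(5, 5), subplot_kw={"polar": True})
    ax.plot(np.concatenate([angles, angles[:1]]),
            np.concatenate([values, values[:1]]), "o-")
    ax.fill(np.concatenate([angles, angles[:1]]),
            np.concatenate([values, values[:1]]), alpha=0.2)
    ax.set_xticks(angles)
    ax.set_xticklabels(labels, fontsize=8)
    ax.set_title("score associations (r)")
    _save(fig, path)
    return ax
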