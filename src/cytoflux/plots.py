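"""Plotting helpers: fold-change line plots, difference heatmaps, cow-plots.

All helpers return the matplotlib figure and, when given a path, save it
(SVG by default).  They are deliberately thin — the DataFrames produced by
:mod:`cytoflux.dynamics` are the primary interface.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def _finish(fig, path):
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def fold_change_lineplot(
    fc: pd.DataFrame, markers: list[str], path=None, ncols: int = 4
):
    """Mean +/- SEM fold-change time courses, one panel per marker."""
    nrows = int(np.ceil(len(markers) / ncols))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows), squeeze=False
    )
    for ax, marker in zip(axes.flat, markers):
        d = fc[fc["marker"] == marker]
        for (cond, stim), grp in d.groupby(
            ["condition", "stimulus"], observed=True
        ):
            agg = grp.groupby("timepoint_h")["fold_change"].agg(
                ["mean", "sem"]
            )
            ax.errorbar(
                agg.index, agg["mean"], yerr=agg["sem"],
                label=f"{cond}/{stim}", marker="o", ms=3, capsize=2,
            )
        ax.set_xscale("symlog", linthresh=1)
        ax.set_title(marker, fontsize=9)
        ax.set_xlabel("time (h)")
        ax.set_ylabel("fold change")
    for ax in axes.flat[len(markers):]:
        ax.axis("off")
    axes.flat[0].legend(fontsize=6)
    return _finish(fig, path)


def max_difference_heatmap(diff: pd.DataFrame, path=None):
    """Signed maximal fold-change-difference heatmap (one column)."""
    d = diff.sort_values("max_difference", ascending=False)
    fig, ax = plt.subplots(figsize=(3, 0.28 * len(d) + 1))
    v = d["max_difference"].to_numpy()[:, None]
    lim = max(abs(v).max(), 1e-9)
    im = ax.imshow(v, cmap="coolwarm", vmin=-lim, vmax=lim, aspect="auto")
    ax.set_yticks(range(len(d)), d["marker"])
    ax.set_xticks([])
    fig.colorbar(im, ax=ax, label="max FC difference")
    return _finish(fig, path)


def cowplot(norm_traj: pd.DataFrame, path=None):
    """Time-normalized cluster-abundance ridgeline ("cow-plot").

    Clusters are stacked by ordering index: early-peaking clusters at the
    top-left, late-peaking at the bottom-right.
    """
    times = [c for c in norm_traj.columns if c != "ordering_index"]
    t = np.asarray(times, dtype=float)
    xi = np.arange(len(t))
    fig, ax = plt.subplots(figsize=(6, 0.45 * len(norm_traj) + 1))
    for row, (cid, traj) in enumerate(norm_traj.iterrows()):
        y = traj[times].to_numpy(dtype=float)
        offset = len(norm_traj) - row
        ax.fill_between(xi, offset, offset + 0.9 * y, alpha=0.7)
        ax.text(-0.4, offset + 0.2, str(cid), ha="right", fontsize=7)
    ax.set_xticks(xi, [f"{v:g}" for v in t])
    ax.set_xlabel("time (h)")
    ax.set_yticks([])
    ax.set_ylabel("cluster (early to late)")
    return _finish(fig, path)


def umap_scatter(coords: np.ndarray, labels: np.ndarray, path=None):
    """2-D embedding colored by cluster label."""
    fig, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(
        coords[:, 0], coords[:, 1], c=labels, s=2, cmap="tab20", lw=0
    )
    fig.colorbar(sc, ax=ax, label="cluster")
    ax.set_xlabel("UMAP1")
    ax.set_ylabel("UMAP2")
    return _finish(fig, path)
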