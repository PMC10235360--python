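"""Optional figures: correlation heatmap, dendrogram, PCA scatter, SI radar.

All functions take an ``ax``/figure-free API and write straight to a file;
matplotlib's Agg backend is forced so plotting works headless.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram

from .qc import ClusterResult, PCAResult


def correlation_heatmap(pearson: pd.DataFrame, path: str | Path,
                        title: str = "sample-sample Pearson r") -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(pearson.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(pearson.columns)), pearson.columns, rotation=90, fontsize=5)
    ax.set_yticks(range(len(pearson.index)), pearson.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def cluster_dendrogram(result: ClusterResult, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(8, 4))
    dendrogram(result.linkage_matrix, labels=list(result.labels.index),
               leaf_font_size=6, ax=ax)
    ax.set_ylabel("1 - Pearson r")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def pca_scatter(result: PCAResult, path: str | Path,
                color_by: pd.Series | None = None) -> None:
    fig, ax = plt.subplots(figsize=(6, 5))
    xs, ys = result.scores.iloc[:, 0], result.scores.iloc[:, 1]
    if color_by is not None:
        groups = color_by.reindex(result.scores.index).fillna("n/a")
        for g in sorted(groups.unique()):
            m = groups == g
            ax.scatter(xs[m], ys[m], s=15, label=str(g))
        ax.legend(fontsize=7)
    else:
        ax.scatter(xs, ys, s=15)
    evr = result.explained_variance_ratio
    ax.set_xlabel(f"PC1 ({evr[0] * 100:.1f}%)")
    ax.set_ylabel(f"PC2 ({evr[1] * 100:.1f}%)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def si_radar(normalized_si: pd.Series, path: str | Path, top: int = 30) -> None:
    """Radar map of the top-SI samples, the standard screen summary figure."""
    vals = normalized_si.sort_values(ascending=False).head(top)
    angles = np.linspace(0, 2 * np.pi, len(vals), endpoint=False)
    fig, ax = plt.subplots(figsize=(6, 6), subplot_kw={"projection": "polar"})
    ax.plot(np.concatenate([angles, angles[:1]]),
            np.concatenate([vals.to_numpy(), vals.to_numpy()[:1]]), lw=1)
    ax.fill(angles, vals.to_numpy(), alpha=0.25)
    ax.set_xticks(angles)
    ax.set_xticklabels(vals.index, fontsize=6)
    ax.set_ylim(0, 1.05)
    ax.set_title(f"normalized SI, top {len(vals)} samples", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
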