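"""Plotting utilities for the synthesis outputs (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from landconn.ordination import OrdinationResult, PartitionResult


def plot_surface(surface: np.ndarray, path: str, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(surface, cmap="viridis")
    ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def grouped_boxplots(
    table: pd.DataFrame, by: str, path: str, stats: tuple[str, ...] = ("rmse", "pearson", "overlap")
) -> None:
    """One panel per accuracy statistic, boxes grouped by a factor column."""
    levels = list(pd.unique(table[by]))
    fig, axes = plt.subplots(1, len(stats), figsize=(4 * len(stats), 3.5), squeeze=False)
    for ax, stat in zip(axes[0], stats):
        data = [table.loc[table[by] == lev, stat].to_numpy() for lev in levels]
        ax.boxplot(data, tick_labels=[str(v) for v in levels])
        ax.set_title(stat)
        ax.set_xlabel(by)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ordination_biplot(result: OrdinationResult, path: str, title: str = "") -> None:
    """Centroid biplot on the first two constrained axes."""
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    for factor, levels in result.centroid_scores.items():
        for lev, xy in levels.items():
            x = xy[0]
            y = xy[1] if xy.size > 1 else 0.0
            ax.plot(x, y, "o", ms=3)
            ax.annotate(f"{factor}={lev}", (x, y), fontsize=7)
    names = ["rmse", "pearson", "overlap"]
    for i in range(min(result.response_scores.shape[0], len(names))):
        vx = result.response_scores[i, 0]
        vy = result.response_scores[i, 1] if result.response_scores.shape[1] > 1 else 0.0
        ax.annotate(
            "", xy=(vx, vy), xytext=(0, 0), arrowprops=dict(arrowstyle="->", color="tab:red")
        )
        ax.annotate(names[i], (vx, vy), color="tab:red", fontsize=8)
    ax.set_xlabel("axis 1")
    ax.set_ylabel("axis 2")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def partition_barplot(result: PartitionResult, path: str, title: str = "") -> None:
    labels = ["+".join(t) for t in result.components] + ["residual"]
    values = list(result.components.values()) + [result.residual]
    fig, ax = plt.subplots(figsize=(max(5, 0.7 * len(labels)), 3.5))
    ax.bar(range(len(values)), values)
    ax.set_xticks(range(len(values)))
    ax.set_xticklabels(labels, rotation=60, ha="right", fontsize=7)
    ax.set_ylabel("variance fraction")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
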