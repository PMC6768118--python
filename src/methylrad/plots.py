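"""Figure helpers: correlation scatter matrix, element distribution bars,
cluster heat-map, enrichment bar/bubble plots. Thin matplotlib wrappers used
by the analysis drivers; everything plotted is computed elsewhere."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def correlation_heatmap(corr: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(corr.to_numpy(), vmin=0, vmax=1, cmap="viridis")
    ax.set_xticks(range(len(corr.columns)), corr.columns, rotation=45)
    ax.set_yticks(range(len(corr.index)), corr.index)
    for i in range(len(corr.index)):
        for j in range(len(corr.columns)):
            ax.text(j, i, f"{corr.iloc[i, j]:.2f}", ha="center", va="center", fontsize=7)
    fig.colorbar(im, label="Pearson r (log2 RPM+1)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def element_distribution_bars(dist: pd.DataFrame, path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(dist.index))
    width = 0.8 / max(1, len(dist.columns))
    for i, sample in enumerate(dist.columns):
        ax.bar(x + i * width, dist[sample], width, label=sample)
    ax.set_xticks(x + 0.4, dist.index, rotation=30)
    ax.set_ylabel("authentic methylation sites")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def cluster_heatmap(zscores: pd.DataFrame, leaf_order: list[str], path: str | Path) -> None:
    data = zscores.loc[leaf_order]
    fig, ax = plt.subplots(figsize=(5, max(3, 0.25 * len(leaf_order))))
    im = ax.imshow(data.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-2, vmax=2)
    ax.set_xticks(range(len(data.columns)), data.columns, rotation=45)
    ax.set_yticks(range(len(data.index)), data.index, fontsize=7)
    fig.colorbar(im, label="row z-score of log2(RPM+1)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def enrichment_bubbles(enrichment: pd.DataFrame, path: str | Path, top: int = 20) -> None:
    sub = enrichment.head(top).iloc[::-1]
    if sub.empty:
        return
    score = sub["k"] / sub["K"]
    fig, ax = plt.subplots(figsize=(6, max(3, 0.3 * len(sub))))
    sc = ax.scatter(
        score,
        range(len(sub)),
        s=20 + 30 * sub["k"],
        c=-np.log10(sub["p_value"].clip(lower=1e-300)),
        cmap="plasma",
    )
    ax.set_yticks(range(len(sub)), sub["term_name"].where(sub["term_name"] != "", sub.index))
    ax.set_xlabel("enrichment score (k / K)")
    fig.colorbar(sc, label="-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
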