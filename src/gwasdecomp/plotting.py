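"""Static plots: scree, Manhattan-like component plots, embedding scatter."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .decomposition import DecompositionResult
from .embedding import EmbeddingResult
from .loading_stats import manhattan_table

__all__ = ["plot_scree", "plot_manhattan", "plot_embedding"]


def plot_scree(result: DecompositionResult, dims=None, path=None):
    """Cumulative variance explained against dimensionality."""
    s = np.asarray(result.singular_spectrum, dtype=float)
    frac = np.cumsum(s**2) / np.sum(s**2)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(np.arange(1, len(s) + 1), frac, lw=1.2)
    if dims:
        for d in dims:
            ax.axvline(d, color="grey", ls=":", lw=0.8)
    ax.set_xlabel("components (K)")
    ax.set_ylabel("cumulative variance explained")
    ax.set_ylim(0, 1.02)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_manhattan(result: DecompositionResult, component: int, path=None, tails="two"):
    """Manhattan-like plot of one component's per-SNP loading significance."""
    tab = manhattan_table(result, component, tails=tails)
    fig, ax = plt.subplots(figsize=(8, 3))
    chroms = tab["chrom"].unique()
    offset = 0
    ticks, tick_labels = [], []
    for ci, c in enumerate(chroms):
        sub = tab[tab["chrom"] == c]
        x = offset + (sub["pos"] - sub["pos"].min()).to_numpy()
        ax.scatter(x, sub["neglog10_p"], s=4, color="C0" if ci % 2 == 0 else "C1")
        ticks.append(x.mean() if len(x) else offset)
        tick_labels.append(str(c))
        offset = x.max() + (sub["pos"].max() - sub["pos"].min()) * 0.05 + 1 if len(x) else offset
    ax.set_xticks(ticks, tick_labels, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} p$")
    ax.set_title(f"component {component + 1}")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_embedding(emb: EmbeddingResult, path=None):
    """Scatter of the 2-D trait-loading embedding, coloured by modality."""
    df = emb.to_frame()
    fig, ax = plt.subplots(figsize=(5, 4.5))
    if "modality" in df.columns:
        for mod, sub in df.groupby("modality"):
            ax.scatter(sub["x"], sub["y"], s=8, label=str(mod))
        ax.legend(fontsize=7, markerscale=1.5)
    else:
        ax.scatter(df["x"], df["y"], s=8)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
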