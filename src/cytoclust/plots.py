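"""Optional matplotlib exports: category heatmap and DAC volcano plot.

matplotlib is an optional dependency (``pip install cytoclust[plot]``); it
is imported only when a plotting function is called.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phenotyping import hclust_order
from .stats import DACRecord

__all__ = ["category_heatmap", "dac_volcano"]


def _plt():
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plotting requires matplotlib "
                          "(install the 'plot' extra)") from exc
    return plt


def category_heatmap(categories: pd.DataFrame, path: str | None = None):
    """White-to-dark-red heatmap of the five-tier category grid, with rows
    and columns ordered by complete-linkage clustering."""
    plt = _plt()
    row_order, _ = hclust_order(categories, axis=0)
    col_order, _ = hclust_order(categories, axis=1)
    M = categories.loc[row_order, col_order].to_numpy(dtype=float)
    fig, ax = plt.subplots(
        figsize=(0.32 * M.shape[1] + 2, 0.18 * M.shape[0] + 1.5))
    im = ax.imshow(M, cmap="Reds", vmin=1, vmax=5, aspect="auto")
    ax.set_xticks(range(len(col_order)), col_order, rotation=90, fontsize=7)
    ax.set_yticks(range(len(row_order)), row_order, fontsize=6)
    ax.set_xlabel("marker")
    ax.set_ylabel("cluster")
    fig.colorbar(im, ax=ax, label="expression tier (1=neg .. 5=very high)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def dac_volcano(dacs: list[DACRecord], fc_min: float = 2.0,
                p_max: float = 0.05, path: str | None = None):
    """log2 fold change vs -log10 p, significant clusters highlighted."""
    plt = _plt()
    fc = np.array([r.fold_change if r.direction == "up" else 1.0 / r.fold_change
                   for r in dacs])
    fc = np.clip(fc, 1e-6, 1e6)
    p = np.clip(np.array([r.p for r in dacs]), 1e-300, 1.0)
    sig = np.array([r.significant for r in dacs])
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(np.log2(fc)[~sig], -np.log10(p)[~sig], s=12, c="grey", alpha=0.6)
    ax.scatter(np.log2(fc)[sig], -np.log10(p)[sig], s=18, c="crimson")
    ax.axhline(-np.log10(p_max), ls="--", lw=0.8, c="k")
    for x in (np.log2(fc_min), -np.log2(fc_min)):
        ax.axvline(x, ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold change")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
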