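"""Figure generation (backend-free: builds Figure objects directly)."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from matplotlib.figure import Figure

from .genesets import ClusterResult

__all__ = ["plot_mean_trace", "plot_heatmap", "plot_enrichment_bars"]


def plot_mean_trace(
    times: np.ndarray,
    values: np.ndarray,
    peak_times: Optional[Sequence[float]] = None,
    title: str = "Population mean normalized N/C ratio",
) -> Figure:
    """Mean normalised trace with arrowheads at detected population maxima."""
    fig = Figure(figsize=(6, 3.5))
    ax = fig.add_subplot(111)
    ax.plot(times, values, color="tab:green", lw=1.5)
    if peak_times is not None:
        for tp in peak_times:
            v = float(np.interp(tp, times, values))
            ax.annotate(
                "", xy=(tp, v), xytext=(tp, v + 0.12),
                arrowprops=dict(arrowstyle="-|>", color="black"),
            )
    ax.set_xlabel("time after TNFα (min)")
    ax.set_ylabel("normalized ratio")
    ax.set_title(title)
    fig.tight_layout()
    return fig


def plot_heatmap(result: ClusterResult, title: str = "log2 fold change") -> Figure:
    fig = Figure(figsize=(6, 8))
    ax = fig.add_subplot(111)
    m = result.matrix.to_numpy()
    vmax = max(np.abs(m).max(), 1e-9)
    im = ax.imshow(m, cmap="coolwarm", vmin=-vmax, vmax=vmax, aspect="auto")
    ax.set_xticks(range(len(result.treatment_order)))
    ax.set_xticklabels(result.treatment_order, rotation=90, fontsize=7)
    ax.set_yticks([])
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.5, label="log2FC")
    fig.tight_layout()
    return fig


def plot_enrichment_bars(df: pd.DataFrame, title: str = "Pathway enrichment") -> Figure:
    """−log10 p bars with mean fold-change arrow vectors above them."""
    fig = Figure(figsize=(max(4, 0.6 * len(df)), 4))
    ax = fig.add_subplot(111)
    x = np.arange(len(df))
    ax.bar(x, df["neg_log10_p"], color="tab:blue")
    if "mean_abs_lfc" in df.columns:
        top = df["neg_log10_p"].max() if len(df) else 1.0
        for xi, (_, row) in zip(x, df.iterrows()):
            dy = row["mean_abs_lfc"] * np.sign(row.get("direction", 0)) * 0.1 * top
            ax.annotate(
                "", xy=(xi, row["neg_log10_p"] + 0.15 * top + dy),
                xytext=(xi, row["neg_log10_p"] + 0.15 * top - dy),
                arrowprops=dict(arrowstyle="-|>" if dy >= 0 else "-|>", color="dimgray"),
            )
    ax.set_xticks(x)
    ax.set_xticklabels(df["pathway"], rotation=45, ha="right", fontsize=7)
    ax.set_ylabel(r"$-\log_{10}\,p$")
    ax.set_title(title)
    fig.tight_layout()
    return fig
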