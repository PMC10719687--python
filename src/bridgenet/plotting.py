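"""Figures: centrality bar charts and focus-edge stability whiskers."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .metrics import MEASURES

__all__ = ["plot_centrality", "plot_focus_edges"]


def plot_centrality(table: pd.DataFrame, path: str | Path,
                    top_only: bool = True) -> None:
    """Grouped horizontal bars of the scaled centrality measures.

    With ``top_only`` only nodes flagged as top-3 in at least one measure
    are shown (the usual display of highly-central variables).
    """
    sub = table[table["top3"]] if top_only else table
    scaled = sub[[m + "_scaled" for m in MEASURES]]
    fig, ax = plt.subplots(figsize=(8, max(3, 0.4 * len(sub))))
    scaled.plot.barh(ax=ax, width=0.8)
    ax.set_xlabel("scaled centrality (0-1)")
    ax.legend([m.replace("_", " ") for m in MEASURES], fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_focus_edges(focus: pd.DataFrame, path: str | Path,
                     max_edges: int = 30) -> None:
    """Horizontal bars of mean bootstrap strength with 95% CI whiskers;
    presence fractions annotate the bars."""
    sub = focus.head(max_edges)
    labels = [f"{a} -- {b}" for a, b in sub.index]
    fig, ax = plt.subplots(figsize=(8, max(3, 0.3 * len(sub))))
    y = range(len(sub))[::-1]
    ax.barh(list(y), sub["mean_strength"], color="#4878a8")
    err_lo = (sub["mean_strength"] - sub["ci_low"]).clip(lower=0)
    err_hi = (sub["ci_high"] - sub["mean_strength"]).clip(lower=0)
    ax.errorbar(sub["mean_strength"], list(y), xerr=[err_lo, err_hi],
                fmt="none", ecolor="black", capsize=2, lw=1)
    for yy, (_, row) in zip(y, sub.iterrows()):
        ax.text(row["ci_high"] + 0.01, yy, f"{row['presence_fraction']:.2f}",
                va="center", fontsize=7)
    ax.set_yticks(list(y))
    ax.set_yticklabels(labels, fontsize=7)
    ax.set_xlabel("mean bootstrap edge strength (95% CI; label = presence fraction)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
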