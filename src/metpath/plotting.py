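"""Plot helpers: embedding scatters, metric bar plots, KM curves."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .classify import ClassificationReport
from .explore import Embedding

__all__ = ["plot_embedding", "plot_metric_bars", "plot_km"]


def plot_embedding(
    emb: Embedding, labels=None, path: str | Path | None = None
) -> plt.Figure:
    """Scatter of a 2-D embedding, colored by label when given."""
    fig, ax = plt.subplots(figsize=(5, 4))
    if labels is None:
        ax.scatter(emb.coords[:, 0], emb.coords[:, 1], s=12)
    else:
        labels = np.asarray(labels)
        for lab in np.unique(labels):
            sel = labels == lab
            ax.scatter(emb.coords[sel, 0], emb.coords[sel, 1], s=12, label=str(lab))
        ax.legend(frameon=False)
    if emb.method == "pca" and emb.explained_variance:
        ax.set_xlabel(f"PC1 ({100 * emb.explained_variance[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({100 * emb.explained_variance[1]:.1f}%)")
    else:
        ax.set_xlabel(f"{emb.method} 1")
        ax.set_ylabel(f"{emb.method} 2")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_metric_bars(
    report: ClassificationReport, split: str = "test", path: str | Path | None = None
) -> plt.Figure:
    """Grouped bars of the five metrics per algorithm for one split."""
    metrics = report.test if split == "test" else report.train
    frame = pd.DataFrame({a: m.as_dict() for a, m in metrics.items()})
    algos = list(frame.columns)
    names = list(frame.index)
    width = 0.8 / len(names)
    fig, ax = plt.subplots(figsize=(1.4 * len(algos) + 2, 4))
    x = np.arange(len(algos))
    for i, name in enumerate(names):
        ax.bar(x + i * width, frame.loc[name], width=width, label=name)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(algos)
    ax.set_ylim(0, 1.05)
    ax.set_ylabel(f"{split} metric")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_km(km: pd.DataFrame, path: str | Path | None = None) -> plt.Figure:
    """Kaplan-Meier step curves from a (group, time, survival) table."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for grp, sub in km.groupby("group"):
        ax.step(sub.time, sub.survival, where="post", label=str(grp))
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
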