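"""Optional matplotlib figures for relevance analytics.

Each function draws onto a fresh figure and returns it; pass ``path``
to save (PNG/SVG inferred from the suffix).
"""

from __future__ import annotations

import numpy as np

from .analysis import HiddenRelevanceMatrix, QuadrantPoint
from .synthetic import CHANNEL_NAMES

__all__ = ["plot_temporal_relevance", "plot_quadrants", "plot_hidden_matrix"]


def _new_axes():
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    return plt.subplots()


def plot_temporal_relevance(signal, temporal, channel: int, fs: float = 100.0, path=None):
    """One channel's raw signal colored by its temporal relevance."""
    fig, ax = _new_axes()
    t = np.arange(signal.shape[0]) / fs
    ax.plot(t, signal[:, channel], color="black", lw=0.8)
    rel = temporal[:, channel]
    sc = ax.scatter(t, signal[:, channel], c=rel, cmap="Reds", s=8)
    fig.colorbar(sc, ax=ax, label="relevance share")
    ax.set_xlabel("time [s]")
    ax.set_ylabel(CHANNEL_NAMES[channel])
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
    return fig


def plot_quadrants(points: list[QuadrantPoint], zcr_threshold: float, count_threshold: float, path=None):
    """Scatter of (ZCR, relevance count) with median threshold lines."""
    fig, ax = _new_axes()
    markers = {0: "o", 1: "s", 2: "^"}
    for p in points:
        ax.scatter(p.zcr, p.rel_count, marker=markers.get(p.class_id, "x"), color="tab:blue")
    ax.axvline(zcr_threshold, ls="--", color="gray")
    ax.axhline(count_threshold, ls="--", color="gray")
    ax.set_xlabel("zero-crossing rate [Hz]")
    ax.set_ylabel("relevance count")
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
    return fig


def plot_hidden_matrix(hmat: HiddenRelevanceMatrix, class_names=None, path=None):
    """Heatmap of per-class hidden-unit relevance, rows pre-sorted."""
    fig, ax = _new_axes()
    vals = hmat.values[hmat.row_order]
    im = ax.imshow(vals, cmap="viridis", aspect="auto")
    for (r, c), v in np.ndenumerate(vals):
        ax.text(c, r, f"{v:.2f}", ha="center", va="center", color="white", fontsize=8)
    ax.set_xticks(range(len(hmat.class_ids)))
    ax.set_xticklabels(
        [class_names[c] if class_names else str(c) for c in hmat.class_ids]
    )
    ax.set_yticks(range(len(hmat.row_order)))
    ax.set_yticklabels([f"unit {u}" for u in hmat.row_order])
    fig.colorbar(im, ax=ax, label="relevance share")
    if path is not None:
        fig.savefig(path, bbox_inches="tight")
    return fig
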