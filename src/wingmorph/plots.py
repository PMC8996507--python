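"""Report figures: discriminant-score histograms, phylomorphospace plots,
displacement-vector models and pixel heatmaps.  All functions draw onto a
supplied or fresh matplotlib Axes and return it; callers save the figure."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .discriminant import DiscriminantModel
from .phylosignal import Phylomorphospace


def _ax(ax):
    if ax is None:
        _fig, ax = plt.subplots(figsize=(6, 4))
    return ax


def score_histogram(model: DiscriminantModel, labels, bins: int = 20, ax=None):
    """Frequency histogram of LD scores per group."""
    ax = _ax(ax)
    labels = np.asarray(labels)
    for g in model.groups:
        ax.hist(model.scores[labels == g], bins=bins, alpha=0.6, label=str(g))
    ax.set_xlabel("linear discriminant score")
    ax.set_ylabel("frequency")
    ax.legend()
    return ax


def phylomorphospace_plot(pm: Phylomorphospace, tip_labels=None, ax=None):
    """Tips, ancestral nodes and connecting branches on PC1-PC2."""
    ax = _ax(ax)
    pts = np.vstack([pm.tip_scores, pm.node_scores])
    for a, b in pm.edges:
        ax.plot(pts[[a, b], 0], pts[[a, b], 1], "-", color="0.6", lw=0.8)
    ax.plot(pm.node_scores[:, 0], pm.node_scores[:, 1], "o", ms=4,
            color="0.3", label="ancestral nodes")
    ax.plot(pm.tip_scores[:, 0], pm.tip_scores[:, 1], "o", ms=6,
            color="tab:blue", label="species")
    if tip_labels is not None:
        for (x, y), name in zip(pm.tip_scores, tip_labels):
            ax.annotate(str(name), (x, y), fontsize=6)
    ax.set_xlabel("PC 1")
    ax.set_ylabel("PC 2")
    ax.legend()
    return ax


def displacement_plot(base_points: np.ndarray, vectors: np.ndarray, ax=None):
    """Vector-displacement shape model (arrows already exaggerated)."""
    ax = _ax(ax)
    ax.plot(base_points[:, 0], base_points[:, 1], "o", ms=3, color="0.4")
    ax.quiver(base_points[:, 0], base_points[:, 1], vectors[:, 0], vectors[:, 1],
              angles="xy", scale_units="xy", scale=1.0, color="tab:red", width=0.004)
    ax.set_aspect("equal")
    return ax


def heatmap_plot(ranked_map: np.ndarray, ax=None):
    """Rank-normalized pixel-difference heatmap (blue = least, red = most)."""
    ax = _ax(ax)
    im = ax.imshow(ranked_map, cmap="jet", vmin=0, vmax=1)
    ax.figure.colorbar(im, ax=ax, shrink=0.7)
    return ax
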