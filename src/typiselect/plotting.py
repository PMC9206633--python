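"""Plots: MDS embedding scatter and attention heatmaps."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

__all__ = ["plot_embedding"]


def plot_embedding(
    coords: np.ndarray,
    labels: np.ndarray,
    subtype_names=None,
    path=None,
    highlight: dict | None = None,
):
    """Scatter of the first two MDS components, colored by subtype.

    ``highlight`` maps case index -> text label to annotate individual cases
    (e.g. the typical/atypical examples of a table).
    """
    coords = np.asarray(coords)
    labels = np.asarray(labels)
    fig, ax = plt.subplots(figsize=(6, 5))
    for k in np.unique(labels):
        m = labels == k
        name = subtype_names[k] if subtype_names is not None else f"subtype {k}"
        ax.scatter(coords[m, 0], coords[m, 1], s=18, alpha=0.8, label=name)
    if highlight:
        for i, text in highlight.items():
            ax.annotate(text, coords[i, :2], fontsize=9, fontweight="bold")
    ax.set_xlabel("MDS component 1")
    ax.set_ylabel("MDS component 2")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig, ax
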