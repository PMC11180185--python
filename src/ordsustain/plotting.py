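"""Matplotlib renderings of positional variance diagrams and staging
histograms.  Plots are data summaries only — no anatomical schematics."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .assign import PositionalVarianceDiagram


def plot_positional_variance(
    pvd: PositionalVarianceDiagram, path=None, cmap: str = "Purples"
):
    """One heatmap per subtype: event rows, stage columns, certainty shading."""
    n = len(pvd.matrices)
    fig, axes = plt.subplots(1, n, figsize=(5.5 * n, 6), squeeze=False)
    labels = [f"{r} ≥{z}" for r, z in pvd.events]
    for c, (ax, mat) in enumerate(zip(axes[0], pvd.matrices), start=1):
        ax.imshow(mat, aspect="auto", cmap=cmap, vmin=0, vmax=1)
        ax.set_title(f"Subtype {c}")
        ax.set_xlabel("stage")
        ax.set_yticks(np.arange(len(labels)))
        ax.set_yticklabels(labels, fontsize=6)
        ax.set_xticks(np.arange(0, mat.shape[1], max(1, mat.shape[1] // 8)))
        ax.set_xticklabels(
            np.arange(1, mat.shape[1] + 1, max(1, mat.shape[1] // 8))
        )
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_staging_histogram(histogram, path=None):
    """Stacked bar chart of included subjects per stage, split by subtype."""
    fig, ax = plt.subplots(figsize=(9, 4))
    bottom = np.zeros(len(histogram.index))
    for subtype in histogram.columns:
        ax.bar(
            histogram.index,
            histogram[subtype].to_numpy(),
            bottom=bottom,
            label=f"Subtype {subtype}",
        )
        bottom += histogram[subtype].to_numpy()
    ax.set_xlabel("stage")
    ax.set_ylabel("subjects")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
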