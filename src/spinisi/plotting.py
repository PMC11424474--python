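"""Diagnostic plots: spinodendrograms and Monte Carlo histograms."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt
import numpy as np

from .clustering import METRICS, MonteCarloResult

__all__ = ["plot_spinodendrogram", "plot_mc_histograms"]

_CLASS_COLORS = {
    "increasing": "tab:green",
    "decreasing": "tab:pink",
    "stable": "0.6",
}


def plot_spinodendrogram(spines_df, tau: float = 0.14, ax=None):
    """Spine positions per dendrite, coloured by size-change class.

    Each dendrite is a horizontal line with one marker per persistent spine
    at its path position; marker colour encodes increasing / decreasing /
    stable at threshold ``tau``.
    """
    from .clustering import classify_spine

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    persistent = spines_df[spines_df["persistent"]]
    dendrite_ids = sorted(persistent["dendrite_id"].unique())
    for row_idx, dend_id in enumerate(dendrite_ids):
        group = persistent[persistent["dendrite_id"] == dend_id]
        ax.hlines(row_idx, 0, group["position_um"].max(), color="0.85", lw=1)
        for _, spine in group.iterrows():
            label = classify_spine(spine["delta_bar"], tau)
            ax.plot(
                spine["position_um"], row_idx, "o",
                color=_CLASS_COLORS[label], ms=5,
            )
    ax.set_xlabel("position along dendrite (μm)")
    ax.set_ylabel("dendrite")
    ax.set_yticks(range(len(dendrite_ids)))
    ax.set_yticklabels([str(d) for d in dendrite_ids])
    return ax


def plot_mc_histograms(result: MonteCarloResult, axes=None):
    """Shuffle distributions with the observed fraction per metric."""
    if axes is None:
        _, axes = plt.subplots(2, 2, figsize=(8, 6))
    axes = np.ravel(axes)
    for ax, metric in zip(axes, METRICS):
        ax.hist(result.shuffled[metric], bins=30, color="0.7")
        ax.axvline(
            result.observed[metric], color="tab:blue", ls="--",
            label=f"observed (p={result.p_values[metric]:.3g})",
        )
        ax.set_title(metric.replace("_", " "))
        ax.set_xlabel("% of pairs")
        ax.legend(fontsize=8)
    return axes
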