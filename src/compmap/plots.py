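"""Conditioning-plot rendering.

A coplot has an upper panel of overlapping disease-load interval "slabs" and
a row of scatterplots of performance against the fMRI feature, one per
interval, each with an illustrative least-squares line. The regression lines
are display aids only — inference lives in the interaction test.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .model import CoplotSpec

__all__ = ["plot_coplot"]


def plot_coplot(
    spec: CoplotSpec,
    d: Sequence[float],
    f: Sequence[float],
    y: Sequence[float],
    path=None,
    d_label: str = "structural disease load (volume fraction)",
    f_label: str = "fMRI signal",
    y_label: str = "performance",
):
    """Render a conditioning plot for a fitted :class:`CoplotSpec`."""
    d = np.asarray(d, float)
    f = np.asarray(f, float)
    y = np.asarray(y, float)
    k = spec.k
    cmap = plt.get_cmap("coolwarm_r")
    colors = [cmap(i / max(k - 1, 1)) for i in range(k)]

    fig = plt.figure(figsize=(3.0 * k, 4.5))
    gs = fig.add_gridspec(2, k, height_ratios=[1, 3], hspace=0.35)

    ax_top = fig.add_subplot(gs[0, :])
    for j, (lo, hi) in enumerate(spec.intervals):
        ax_top.plot([lo, hi], [j, j], lw=6, color=colors[j], solid_capstyle="butt")
    ax_top.set_xlabel(d_label)
    ax_top.set_yticks([])
    ax_top.set_ylim(-0.5, k - 0.5)
    ax_top.set_title("overlapping equal-count intervals")

    ylim = (y.min() - 0.05 * np.ptp(y), y.max() + 0.05 * np.ptp(y)) if len(y) else (0, 1)
    for j, idx in enumerate(spec.index_sets):
        ax = fig.add_subplot(gs[1, j])
        ax.scatter(f[idx], y[idx], s=12, color=colors[j], alpha=0.8)
        if spec.slopes is not None:
            xs = np.linspace(f[idx].min(), f[idx].max(), 2)
            ax.plot(xs, spec.intercepts[j] + spec.slopes[j] * xs, color="k", lw=1)
        ax.set_ylim(*ylim)
        ax.set_xlabel(f_label)
        if j == 0:
            ax.set_ylabel(y_label)
        else:
            ax.set_yticklabels([])
    if path is not None:
        fig.savefig(path, dpi=110, bbox_inches="tight")
        plt.close(fig)
    return fig
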