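"""Visualisation of per-epoch explanations.

One figure per epoch: the raw signal drawn as a line whose colour
encodes the per-timepoint class contribution, with the relative
band-power bars underneath — the standard evidence panel for inspecting
what a classification was based on.
"""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")  # headless backend; figures are written, not shown
import matplotlib.pyplot as plt
from matplotlib.collections import LineCollection

from .cam import BandPowerSummary, Heatmap


def plot_explanation(signal, heatmap: Heatmap,
                     band_power: BandPowerSummary | None = None,
                     fs: float = 128.0, title: str | None = None):
    """Build the explanation figure for one epoch.

    Returns the matplotlib ``Figure``; the caller saves or embeds it.
    """
    signal = np.asarray(signal, dtype=float)
    contrib = heatmap.upsampled
    if signal.shape != contrib.shape:
        raise ValueError("signal and heatmap lengths differ")

    n_rows = 2 if band_power is not None else 1
    fig, axes = plt.subplots(n_rows, 1, figsize=(9, 3 * n_rows),
                             squeeze=False)
    ax = axes[0, 0]
    t = np.arange(signal.size) / fs
    pts = np.array([t, signal]).T.reshape(-1, 1, 2)
    segs = np.concatenate([pts[:-1], pts[1:]], axis=1)
    lc = LineCollection(segs, cmap="coolwarm",
                        norm=plt.Normalize(contrib.min(), contrib.max()))
    lc.set_array(contrib[:-1])
    lc.set_linewidth(1.2)
    ax.add_collection(lc)
    ax.set_xlim(t[0], t[-1])
    pad = 0.1 * (signal.max() - signal.min() + 1e-9)
    ax.set_ylim(signal.min() - pad, signal.max() + pad)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("amplitude")
    fig.colorbar(lc, ax=ax, label="contribution (z)")
    ax.set_title(title or
                 f"class {heatmap.class_index} "
                 f"(p={heatmap.probability:.2f})")

    if band_power is not None:
        axb = axes[1, 0]
        names = ["delta", "theta", "alpha", "beta"]
        vals = [getattr(band_power, n) for n in names]
        axb.bar(names, vals, color="tab:gray")
        axb.set_ylabel("relative power")
        axb.set_ylim(0, 1)
    fig.tight_layout()
    return fig
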