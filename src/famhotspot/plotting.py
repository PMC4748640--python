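"""Static plots of the consensus mutational profile.

One figure: pooled per-column mutation counts as bars, the Trident
conservation track below, and significant hotspot columns highlighted.
Matplotlib's Agg backend is forced so the function works headless.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .hotspot import HotspotResult

__all__ = ["profile_plot"]


def profile_plot(result: HotspotResult, path: str | Path, title: str = "") -> None:
    """Barplot of pooled counts with a Trident track; hotspots in red."""
    df = result.table
    cols = df["column"].to_numpy()
    counts = df["n_mut"].to_numpy()
    sig = set(result.significant()["column"]) if not result.nothing_to_test else set()
    colors = ["crimson" if c in sig else "steelblue" for c in cols]

    fig, (ax0, ax1) = plt.subplots(
        2, 1, figsize=(max(6, len(cols) / 12), 4.5),
        sharex=True, height_ratios=[3, 1], constrained_layout=True,
    )
    ax0.bar(cols, counts, color=colors, width=1.0)
    ax0.set_ylabel("pooled mutations")
    if title:
        ax0.set_title(title)
    if result.global_p is not None:
        ax0.text(
            0.99, 0.95, f"global p = {result.global_p:.3g}",
            transform=ax0.transAxes, ha="right", va="top", fontsize=9,
        )
    ax1.fill_between(cols, df["trident"].to_numpy(), color="darkseagreen", step="mid")
    ax1.axhline(0.1, color="gray", lw=0.8, ls="--")
    ax1.set_ylim(0, 1)
    ax1.set_ylabel("Trident")
    ax1.set_xlabel("consensus column")
    fig.savefig(path, dpi=150)
    plt.close(fig)
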