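"""Optional plot sidecars rendered from the output tables.

Requires matplotlib (the ``plot`` extra); all analysis outputs are the
tables themselves, never the images.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotype import chromosome_sort_key


def manhattan_plot(manhattan: pd.DataFrame, path, threshold_neglog10: float | None = None):
    """Scatter of -log10(p) by cumulative genomic position, one color band per chromosome."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    key = chromosome_sort_key(manhattan["chrom"])
    chroms = sorted(manhattan["chrom"].unique(), key=key)
    fig, ax = plt.subplots(figsize=(9, 3))
    offset = 0
    ticks = []
    for ci, chrom in enumerate(chroms):
        sub = manhattan[manhattan.chrom == chrom].sort_values("pos")
        x = sub["pos"].to_numpy() + offset
        ax.scatter(x, sub["neglog10_p"], s=6, color="C0" if ci % 2 == 0 else "C1")
        ticks.append((offset + x[-1]) / 2 if len(x) else offset)
        offset = x[-1] + 1 if len(x) else offset
    if threshold_neglog10 is not None:
        ax.axhline(threshold_neglog10, color="k", lw=0.8)
    ax.set_xticks(ticks)
    ax.set_xticklabels(chroms)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ld_heatmap(ld_long: pd.DataFrame, path):
    """Square r^2 heatmap from the long-format LD table."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    positions = sorted(set(ld_long.pos_i) | set(ld_long.pos_j))
    idx = {p: i for i, p in enumerate(positions)}
    grid = np.full((len(positions), len(positions)), np.nan)
    for row in ld_long.itertuples():
        i, j = idx[row.pos_i], idx[row.pos_j]
        grid[i, j] = grid[j, i] = row.r2
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(grid, vmin=0, vmax=1, cmap="Greys", origin="lower")
    fig.colorbar(im, ax=ax, label="r$^2$")
    ax.set_xlabel("site index (by position)")
    ax.set_ylabel("site index (by position)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
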