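"""Optional rendered plots; the underlying tables are the tested artifact."""

from __future__ import annotations

import numpy as np

from .mixedmodel import AssocResult


def plot_manhattan(assoc: AssocResult, path, suggestive: float | None = None,
                   genomewide: float | None = None, title: str = "") -> None:
    """Render a Manhattan plot to ``path`` (requires matplotlib).

    Chromosomes alternate shading; optional horizontal lines mark the
    suggestive and genome-wide thresholds.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = assoc.manhattan_table()
    fig, ax = plt.subplots(figsize=(10, 3.2))
    offset = 0
    ticks, labels = [], []
    for i, (chrom, grp) in enumerate(t.groupby("chrom", sort=False)):
        x = offset + np.arange(len(grp))
        ax.scatter(x, grp["neglog10p"], s=4,
                   color="steelblue" if i % 2 == 0 else "lightsteelblue")
        ticks.append(offset + len(grp) / 2)
        labels.append(str(chrom))
        offset += len(grp)
    if suggestive:
        ax.axhline(-np.log10(suggestive), ls="--", color="grey", lw=0.8)
    if genomewide:
        ax.axhline(-np.log10(genomewide), ls="-", color="grey", lw=0.8)
    ax.set_xticks(ticks, labels, fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} p$")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
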