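"""Basic locus-wide association plot."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def manhattan(table: pd.DataFrame, path, threshold: float | None = None, title=""):
    """-log10 p against position for one scan table (columns pos, neglog10p)."""
    fig, ax = plt.subplots(figsize=(8, 3))
    ax.scatter(table["pos"], table["neglog10p"], s=12, c="#33557a")
    if threshold is not None:
        ax.axhline(threshold, color="#b03030", lw=1, ls="--")
    ax.set_xlabel("position (bp)")
    ax.set_ylabel(r"$-\log_{10} p$")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
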