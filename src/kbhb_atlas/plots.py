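"""Optional figures: volcano plot of a differential table."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .differential import ALPHA, CLASS_DOWN, CLASS_UP, FC_THRESHOLD


def volcano(records: pd.DataFrame, path: str | Path, alpha: float = ALPHA,
            fc_threshold: float = FC_THRESHOLD, title: str = "") -> None:
    """-log10 p vs log2 fold change, colored by significance class."""
    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {CLASS_UP: "#c0392b", CLASS_DOWN: "#2980b9", "ns": "#bdbdbd"}
    for cls, color in colors.items():
        sub = records[records["class"] == cls]
        ax.scatter(sub["log2fc"], -np.log10(sub["p_value"]), s=6, c=color,
                   label=f"{cls} ({len(sub)})", alpha=0.7, linewidths=0)
    ax.axhline(-np.log10(alpha), ls="--", lw=0.8, c="k")
    ax.axvline(fc_threshold, ls="--", lw=0.8, c="k")
    ax.axvline(-fc_threshold, ls="--", lw=0.8, c="k")
    ax.set_xlabel("log2 fold change (starved / control)")
    ax.set_ylabel("-log10 p")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
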