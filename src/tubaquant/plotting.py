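"""Optional plots: tumor-size dot plots and Q-Q ratio curves."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def size_dot_plot(tumor_table: pd.DataFrame, path: str | Path, group_col: str = "sgRNA_name"):
    """One column of dots per group, sizes on a log scale."""
    fig, ax = plt.subplots(figsize=(max(4, 0.5 * tumor_table[group_col].nunique()), 4))
    groups = sorted(tumor_table[group_col].unique())
    rng = np.random.default_rng(0)
    for i, g in enumerate(groups):
        y = tumor_table.loc[tumor_table[group_col] == g, "cells"]
        x = i + rng.uniform(-0.25, 0.25, len(y))
        ax.scatter(x, y, s=4, alpha=0.4)
    ax.set_yscale("log")
    ax.set_xticks(range(len(groups)), groups, rotation=90, fontsize=7)
    ax.set_ylabel("neoplastic cells per tumor")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)


def qq_plot(spectrum: pd.DataFrame, path: str | Path, label: str = ""):
    """Percentile-by-percentile size ratio relative to the inerts."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ok = ~spectrum["undefined"]
    ax.plot(spectrum.loc[ok, "percentile"], spectrum.loc[ok, "ratio"], "o-", label=label or None)
    ax.axhline(1.0, color="grey", lw=0.8, ls="--")
    ax.set_xlabel("percentile of tumor size")
    ax.set_ylabel("size relative to inerts")
    ax.set_yscale("log")
    if label:
        ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return Path(path)
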