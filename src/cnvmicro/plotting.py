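"""Minimal plots: Manhattan-style association panel and group boxplots."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["manhattan", "group_boxplot"]


def manhattan(assoc: pd.DataFrame, ax=None, fdr_line: float | None = None):
    """-log10(p) against genomic midpoint, one point per CNVR.

    ``assoc`` needs columns chrom, start, end, p (the association TSV the
    pipeline writes).  Returns the matplotlib axis.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    offset, ticks = 0.0, {}
    for chrom, grp in assoc.groupby("chrom", sort=True):
        mid = (grp["start"] + grp["end"]) / 2.0 + offset
        ax.scatter(mid, -np.log10(grp["p"]), s=14, label=str(chrom))
        ticks[str(chrom)] = float(mid.mean())
        offset += float(grp["end"].max())
    if fdr_line is not None:
        ax.axhline(-np.log10(fdr_line), ls="--", c="grey")
    ax.set_xticks(list(ticks.values()), list(ticks.keys()))
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10} P$")
    return ax


def group_boxplot(values: pd.Series, groups: pd.Series, ax=None,
                  ylabel: str | None = None):
    """Boxplot of a per-sample statistic split by group label."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(3, 3))
    labels = sorted(groups.dropna().unique().tolist())
    data = [values[groups == lab].dropna().to_numpy() for lab in labels]
    ax.boxplot(data, tick_labels=labels)
    if ylabel:
        ax.set_ylabel(ylabel)
    return ax
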