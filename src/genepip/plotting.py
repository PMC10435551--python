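"""Minimal plotting helpers for partition and enrichment summaries."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def plot_partition(table: pd.DataFrame, path: str | None = None):
    """Stacked bar of PIP proportions per scope from partition_table output."""
    pivot = table.pivot(index="scope", columns="category", values="proportion").fillna(0.0)
    ax = pivot.plot(kind="barh", stacked=True, figsize=(8, max(2, 0.3 * len(pivot))))
    ax.set_xlabel("proportion of summed PIP")
    ax.set_xlim(0, 1)
    fig = ax.get_figure()
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax


def plot_enrichment(report: pd.DataFrame, path: str | None = None):
    """Log2 fold-enrichment dot-and-CI plot from enrichment_report output."""
    fig, ax = plt.subplots(figsize=(6, max(2, 0.4 * len(report))))
    y = range(len(report))
    ax.errorbar(
        report["log2_fe"], list(y),
        xerr=[report["log2_fe"] - report["ci_low"], report["ci_high"] - report["log2_fe"]],
        fmt="o", capsize=3,
    )
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(list(y), report["annotation"])
    ax.set_xlabel("log2 fold enrichment")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax
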