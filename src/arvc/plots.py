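"""Simple figure output: prevalence bars, co-occurrence oncoprint, AR box plot."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .cohort_stats import oncoprint_order

__all__ = ["plot_prevalence", "plot_oncoprint", "plot_ar_by_positivity"]


def plot_prevalence(prevalence: pd.DataFrame, path: str | Path) -> None:
    """Bar chart of per-variant positivity prevalence (percent)."""
    fig, ax = plt.subplots(figsize=(5, 3))
    order = prevalence.sort_values("prevalence_pct", ascending=False)
    ax.bar(order.index, order["prevalence_pct"], color="#3b6ea5")
    ax.set_ylabel("samples positive (%)")
    ax.set_ylim(0, 100)
    ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_oncoprint(positivity: pd.DataFrame, path: str | Path) -> None:
    """Binary co-occurrence matrix in memo-sort order (variants by
    prevalence, samples by positivity bit pattern)."""
    sample_order, variant_order = oncoprint_order(positivity)
    mat = positivity.loc[sample_order, variant_order].T.to_numpy().astype(float)
    fig, ax = plt.subplots(figsize=(max(4, len(sample_order) * 0.15), 2.5))
    ax.imshow(mat, aspect="auto", cmap="Blues", vmin=0, vmax=1, interpolation="none")
    ax.set_yticks(range(len(variant_order)), variant_order)
    ax.set_xticks([])
    ax.set_xlabel(f"samples (n={len(sample_order)})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_ar_by_positivity(ar: pd.Series, positivity: pd.DataFrame,
                          path: str | Path) -> None:
    """Box plot of normalized AR expression, any-variant-positive vs none
    (square-root axis scale for display only)."""
    common = ar.index.intersection(positivity.index)
    any_pos = positivity.loc[common].any(axis=1)
    groups = [ar.loc[common][~any_pos].to_numpy(), ar.loc[common][any_pos].to_numpy()]
    fig, ax = plt.subplots(figsize=(3.2, 3.2))
    ax.boxplot(groups, tick_labels=["AR-V negative", "AR-V positive"])
    ax.set_ylabel("normalized AR expression")
    if np.all(np.concatenate(groups) >= 0):
        ax.set_yscale("function", functions=(np.sqrt, np.square))
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
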