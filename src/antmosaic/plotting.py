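"""Plots: null-distribution histograms and per-group abundance bars."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .data import AbundanceTable  # noqa: E402


def plot_null_distribution(result, ax=None, bins: int = 30, title: str | None = None):
    """Histogram of null summed-CU counts with the observed value marked.

    The observed count is a vertical broken line; an observed line to the
    right of the histogram mass indicates more checkerboard units than
    expected, i.e. species segregation.
    """
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist(result.null_cus, bins=bins, color="0.7", edgecolor="0.4")
    ax.axvline(result.observed_cu, color="crimson", linestyle="--", linewidth=1.5)
    sig = result.p_value <= 0.05
    ax.set_xlabel("summed checkerboard units")
    ax.set_ylabel("null frequency")
    label = title or f"{result.scale}-group scale"
    ax.set_title(f"{label}  (p = {result.p_value:.3g}{'*' if sig else ''})", fontsize=10)
    ax.figure.tight_layout()
    return ax


def plot_group_abundances(table: AbundanceTable, ax=None, max_species: int = 12):
    """Stacked per-group abundance bars (most abundant species coloured)."""
    df = table.records
    totals = df.groupby("species_id")["count"].sum().sort_values(ascending=False)
    top = list(totals.index[:max_species])
    pivot = (
        df.assign(species=np.where(df["species_id"].isin(top), df["species_id"], "other"))
        .groupby(["group_id", "species"])["count"]
        .sum()
        .unstack(fill_value=0)
        .sort_index()
    )
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    pivot.plot(kind="bar", stacked=True, ax=ax, width=0.85, colormap="tab20", legend=True)
    ax.set_ylabel("worker abundance")
    ax.set_xlabel("group (tree)")
    ax.legend(fontsize=6, ncol=2)
    ax.figure.tight_layout()
    return ax
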