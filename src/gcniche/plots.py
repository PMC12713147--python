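"""Static diagnostic plots: PPV rank plot, three-way scatter, decay curve."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def rank_plot(specificity, highlight=(), ax=None):
    """PPV vs rank for included genes; selected genes labeled."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    inc = specificity[specificity["included"]].sort_values("rank")
    ax.plot(inc["rank"], 100 * inc["ppv"], ".", ms=3, color="0.6")
    for g in highlight:
        row = inc[inc["gene"] == g]
        if len(row):
            ax.plot(row["rank"], 100 * row["ppv"], "o", color="crimson")
            ax.annotate(g, (row["rank"].iloc[0], 100 * row["ppv"].iloc[0]),
                        textcoords="offset points", xytext=(4, 4), fontsize=8)
    ax.set_xlabel("PPV rank")
    ax.set_ylabel("% positive Tfh inside GC")
    return ax


def three_way_scatter(three_way, ax=None):
    """In-GC-vs-out fold change against Tfh-vs-other, colored by reference."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 4))
    df = three_way[three_way["passes_filter"]]
    sc = ax.scatter(
        df["lfc_gc_vs_out"], df["lfc_tfh_vs_other_in_gc"],
        c=df["lfc_reference"], cmap="coolwarm", s=14,
        vmin=-abs(df["lfc_reference"]).max(), vmax=abs(df["lfc_reference"]).max(),
    )
    plt.colorbar(sc, ax=ax, label="reference log2FC (Tfh vs other)")
    ax.axhline(0, lw=0.5, color="0.7")
    ax.axvline(0, lw=0.5, color="0.7")
    ax.set_xlabel("log2FC Tfh in GC vs outside")
    ax.set_ylabel("log2FC Tfh vs other in GC")
    return ax


def decay_plot(curve, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3))
    ax.plot(curve.grid, curve.values, lw=1.5)
    ax.set_xlabel("distance to nearest LZ GC B cell (µm)")
    ax.set_ylabel(f"{curve.gene} smoothed expression")
    return ax
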