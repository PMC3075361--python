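"""Figure-style plots: PCA hemispheres, average pattern profiles, and qPCR vs
microarray trajectory overlays."""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_pca_hemispheres", "plot_pattern_profiles", "plot_qpcr_overlay"]

_COLORS = {"decreasing": "green", "increasing": "magenta"}


def plot_pca_hemispheres(patterns: pd.DataFrame, ax=None):
    """PC1 vs PC2 scatter, genes colored by temporal pattern."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, sub in patterns.groupby("pattern"):
        ax.scatter(sub["pc1"], sub["pc2"], s=4, alpha=0.5,
                   color=_COLORS.get(name, "gray"), label=name)
    ax.axvline(0.0, color="black", lw=0.5)
    ax.set_xlabel("PC1 score")
    ax.set_ylabel("PC2 score")
    ax.legend(title="temporal pattern")
    return ax


def plot_pattern_profiles(pattern_profiles: pd.DataFrame, crossing_day=None, ax=None):
    """Average standardized profile of each temporal pattern across days."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for name, row in pattern_profiles.iterrows():
        ax.plot(list(pattern_profiles.columns), row.to_numpy(), marker="o",
                color=_COLORS.get(name, "gray"), label=name)
    if crossing_day is not None:
        ax.axvline(crossing_day, color="black", ls="--", lw=0.8,
                   label=f"crossing (day {crossing_day})")
    ax.set_xlabel("day of differentiation")
    ax.set_ylabel("mean standardized log2 signal")
    ax.legend()
    return ax


def plot_qpcr_overlay(per_day: pd.DataFrame, gene: str, ax=None):
    """Overlay of qPCR (ddCT) and microarray per-day log2 FC for one gene."""
    import matplotlib.pyplot as plt

    sub = per_day[per_day["gene_id"] == gene].sort_values("day")
    if sub.empty:
        raise ValueError(f"gene {gene!r} absent from comparison table")
    if ax is None:
        _, ax = plt.subplots()
    ax.plot(sub["day"], sub["qpcr_log2_fc"], "m--o", label="qPCR (ddCT)")
    ax.plot(sub["day"], sub["array_log2_fc"], "g-o", label="microarray")
    ax.axhline(0.0, color="black", lw=0.5)
    ax.set_xlabel("day of differentiation")
    ax.set_ylabel("log2 FC vs day 0")
    ax.set_title(gene)
    ax.legend()
    return ax
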