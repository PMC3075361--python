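"""Fold-change contrasts on the log2 expression matrix.

The primary contrast is late-vs-early: the average log2 signal over the late
days (default 10 and 14) minus the average over the early days (default 0 and
1), pooling replicates as independent arrays. Because signals are log2, the
difference *is* the log2 fold change.

The day-4 contrast compares the arrays at the temporal switch point against
all other arrays with a Welch two-sided t-test per gene and Benjamini-Hochberg
adjustment across genes.
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["fold_change_late_vs_early", "day4_contrast"]


def _arrays_for_days(design: pd.DataFrame, days: Iterable[int], label: str) -> list[str]:
    days = set(days)
    if not days:
        raise ValueError(f"{label} day set is empty")
    missing = days - set(design["day"].unique())
    if missing:
        raise ValueError(f"{label} days absent from design: {sorted(missing)}")
    return list(design.index[design["day"].isin(days)])


def fold_change_late_vs_early(
    gene_expr: pd.DataFrame,
    design: pd.DataFrame,
    early_days: Iterable[int] = (0, 1),
    late_days: Iterable[int] = (10, 14),
) -> pd.DataFrame:
    """log2 FC = mean log2 signal over late-day arrays minus early-day arrays.

    Returns columns mean_early, mean_late, log2_fc (= mean_late - mean_early
    exactly).
    """
    early = _arrays_for_days(design, early_days, "early")
    late = _arrays_for_days(design, late_days, "late")
    mean_early = gene_expr[early].mean(axis=1)
    mean_late = gene_expr[late].mean(axis=1)
    return pd.DataFrame(
        {
            "mean_early": mean_early,
            "mean_late": mean_late,
            "log2_fc": mean_late - mean_early,
        },
        index=gene_expr.index,
    )


def day4_contrast(
    gene_expr: pd.DataFrame,
    design: pd.DataFrame,
    day: int = 4,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Per-gene differential test of the switch day against all other days.

    Two-sided two-sample t-test of day-``day`` arrays vs all remaining
    arrays, BH-adjusted across genes; direction is 'up'/'down' by the sign of
    the mean difference among genes significant at FDR ``alpha``, otherwise
    'ns'. The pooled-variance (Student) test is the default: the switch-day
    group has only two arrays under the study design, which leaves the Welch
    approximation with ~1 effective degree of freedom and essentially no
    power; ``equal_var=False`` selects Welch for sensitivity analysis.
    """
    in_day = design["day"] == day
    group_a = list(design.index[in_day])
    group_b = list(design.index[~in_day])
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError(
            f"need >= 2 arrays at day {day} and >= 2 elsewhere "
            f"(got {len(group_a)} and {len(group_b)})"
        )
    A = gene_expr[group_a].to_numpy(dtype=float)
    B = gene_expr[group_b].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(A, B, axis=1, equal_var=equal_var)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance genes: no evidence
    diff = A.mean(axis=1) - B.mean(axis=1)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    significant = p_adj < alpha
    direction = np.where(~significant, "ns", np.where(diff > 0, "up", "down"))
    return pd.DataFrame(
        {
            "log2_fc_day_vs_rest": diff,
            "p_value": p,
            "adjusted_p": p_adj,
            "direction": direction,
        },
        index=gene_expr.index,
    )
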