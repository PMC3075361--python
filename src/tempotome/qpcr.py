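"""ddCT relative quantification from qPCR CT tables.

CT (cycle threshold) values are normalized to a reference (loading-control)
gene within each (day, replicate) block: dCT = CT(target) - CT(reference).
The log2 fold change of day N relative to the baseline day is

    ddCT log2 FC = mean dCT(baseline) - mean dCT(day N)

assuming an amplification efficiency of exactly 2 (one doubling per cycle); a
different efficiency E rescales the estimate by log2(E). Significance against
the baseline day uses a two-tailed two-sample t-test on the per-replicate dCT
values (Welch by default).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ddct_log2fc", "compare_qpcr_microarray"]

logger = logging.getLogger(__name__)

DEFAULT_REFERENCE = "ef1a"


def ddct_log2fc(
    ct: pd.DataFrame,
    reference: str = DEFAULT_REFERENCE,
    baseline_day: int = 0,
    efficiency: float = 2.0,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-gene, per-day ddCT log2 fold change relative to the baseline day.

    ``ct`` has columns gene, day, replicate, ct. The reference gene must be
    measured at every (day, replicate) where any target is; a missing
    reference raises an error naming the condition. Returns columns gene_id,
    day, log2_fc_vs_day0, se, p_value; the baseline-day fold change is 0 by
    construction (se/p undefined there).
    """
    if efficiency <= 1.0:
        raise ValueError("amplification efficiency must exceed 1")
    required = {"gene", "day", "replicate", "ct"}
    missing_cols = required - set(ct.columns)
    if missing_cols:
        raise ValueError(f"CT table missing columns {sorted(missing_cols)}")
    ref = ct[ct["gene"] == reference].set_index(["day", "replicate"])["ct"]
    if ref.index.has_duplicates:
        ref = ref.groupby(level=[0, 1]).mean()
    targets = ct[ct["gene"] != reference]
    conditions = targets[["day", "replicate"]].drop_duplicates()
    for day, rep in conditions.itertuples(index=False):
        if (day, rep) not in ref.index:
            raise ValueError(
                f"reference gene {reference!r} not measured at day={day} replicate={rep!r}"
            )
    dct = targets.copy()
    dct["dct"] = dct["ct"].to_numpy() - ref.loc[
        list(zip(dct["day"], dct["replicate"]))
    ].to_numpy()

    scale = math.log2(efficiency)
    rows = []
    for gene, sub in dct.groupby("gene", sort=True):
        base = sub.loc[sub["day"] == baseline_day, "dct"]
        if base.empty:
            raise ValueError(f"gene {gene!r} has no baseline-day ({baseline_day}) measurements")
        for day, day_sub in sub.groupby("day", sort=True):
            vals = day_sub["dct"]
            if day == baseline_day:
                rows.append((gene, day, 0.0, np.nan, np.nan))
                continue
            fc = (base.mean() - vals.mean()) * scale
            se = scale * math.sqrt(
                base.var(ddof=1) / len(base) + vals.var(ddof=1) / len(vals)
            ) if len(base) > 1 and len(vals) > 1 else np.nan
            if len(base) > 1 and len(vals) > 1 and (base.var() > 0 or vals.var() > 0):
                _, p = stats.ttest_ind(base, vals, equal_var=equal_var)
            else:
                p = np.nan
            rows.append((gene, day, float(fc), se, float(p) if p == p else np.nan))
    return pd.DataFrame(
        rows, columns=["gene_id", "day", "log2_fc_vs_day0", "se", "p_value"]
    )


def compare_qpcr_microarray(
    qpcr_fc: pd.DataFrame,
    gene_expr: pd.DataFrame,
    design: pd.DataFrame,
    early_days: tuple[int, ...] = (0, 1),
    late_days: tuple[int, ...] = (10, 14),
    baseline_day: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Side-by-side qPCR vs microarray fold changes for the shared genes.

    Returns ``(per_day, summary)``. ``per_day`` holds both platforms' per-day
    log2 FC relative to the baseline day (microarray: mean log2 signal at day
    N minus at baseline) and whether the signs agree. ``summary`` holds each
    gene's late-vs-early log2 FC on both platforms (late/early day-set means,
    the defined fold-change convention), sign agreement, and — as attribute
    ``summary.attrs['pearson_r']`` — the Pearson correlation of the two
    platforms' fold changes across genes.
    """
    genes = sorted(set(qpcr_fc["gene_id"]) & set(gene_expr.index))
    skipped = sorted(set(qpcr_fc["gene_id"]) - set(gene_expr.index))
    if skipped:
        logger.warning("genes absent on the microarray platform, skipped: %s", skipped)
    if not genes:
        logger.warning("no genes shared between qPCR and microarray tables")
        empty = pd.DataFrame(columns=["gene_id", "day", "qpcr_log2_fc", "array_log2_fc", "sign_agree"])
        summary = pd.DataFrame(columns=["gene_id", "qpcr_log2_fc", "array_log2_fc", "sign_agree"])
        summary.attrs["pearson_r"] = np.nan
        return empty, summary

    days = sorted(design["day"].unique())
    day_means = pd.DataFrame(
        {d: gene_expr.loc[genes, design.index[design["day"] == d]].mean(axis=1) for d in days}
    )
    per_day_rows = []
    for gene in genes:
        q = qpcr_fc[qpcr_fc["gene_id"] == gene].set_index("day")["log2_fc_vs_day0"]
        for d in days:
            if d not in q.index:
                continue
            array_fc = float(day_means.at[gene, d] - day_means.at[gene, baseline_day])
            qv = float(q.loc[d])
            per_day_rows.append(
                (gene, d, qv, array_fc, bool(np.sign(qv) == np.sign(array_fc)))
            )
    per_day = pd.DataFrame(
        per_day_rows, columns=["gene_id", "day", "qpcr_log2_fc", "array_log2_fc", "sign_agree"]
    )

    summary_rows = []
    for gene in genes:
        q = qpcr_fc[qpcr_fc["gene_id"] == gene].set_index("day")["log2_fc_vs_day0"]
        if not (set(early_days) <= set(q.index) and set(late_days) <= set(q.index)):
            logger.warning("gene %s lacks early/late qPCR days, skipped from summary", gene)
            continue
        q_fc = float(q.loc[list(late_days)].mean() - q.loc[list(early_days)].mean())
        a_fc = float(
            day_means.loc[gene, list(late_days)].mean()
            - day_means.loc[gene, list(early_days)].mean()
        )
        summary_rows.append((gene, q_fc, a_fc, bool(np.sign(q_fc) == np.sign(a_fc))))
    summary = pd.DataFrame(
        summary_rows, columns=["gene_id", "qpcr_log2_fc", "array_log2_fc", "sign_agree"]
    )
    if len(summary) >= 2:
        r = float(np.corrcoef(summary["qpcr_log2_fc"], summary["array_log2_fc"])[0, 1])
    else:
        r = np.nan
    summary.attrs["pearson_r"] = r
    return per_day, summary
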