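"""Cross-dataset fold-change concordance.

Two datasets in different gene namespaces are joined over a user-supplied
homolog map. Pairs that are reproducible in *both* datasets (replicate-profile
r > 0.8 on each side, strict) and at least 2-fold changed in *both*
(|log2 FC| >= 1, inclusive) enter a 2x2 contingency table of fold-change
directions, tested for association with the two-sided Fisher exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "join_homologs",
    "concordance_table",
    "fisher_exact",
    "ContingencyResult",
]

logger = logging.getLogger(__name__)

DEFAULT_REPRO_THRESHOLD = 0.8
DEFAULT_FOLD_THRESHOLD_LOG2 = 1.0


@dataclass(frozen=True)
class ContingencyResult:
    """2x2 direction contingency (dataset-1 up/down x dataset-2 up/down)."""

    counts: np.ndarray  # [[up/up, up/down], [down/up, down/down]]
    n_pairs: int  # pairs passing both 2-fold filters
    odds_ratio: float
    p_value: float

    def summary(self) -> str:
        c = self.counts
        return (
            "Direction concordance (rows: dataset 1, cols: dataset 2)\n"
            f"            up    down\n"
            f"  up    {c[0, 0]:6d}  {c[0, 1]:6d}\n"
            f"  down  {c[1, 0]:6d}  {c[1, 1]:6d}\n"
            f"  pairs >= 2-fold in both: {self.n_pairs}\n"
            f"  odds ratio: {self.odds_ratio:.4g}\n"
            f"  Fisher exact P (two-sided): {self.p_value:.4g}"
        )


def join_homologs(
    fc_a: pd.DataFrame,
    repro_a: pd.Series,
    fc_b: pd.DataFrame,
    repro_b: pd.Series,
    homolog_map: pd.DataFrame,
    repro_threshold: float = DEFAULT_REPRO_THRESHOLD,
) -> pd.DataFrame:
    """Inner-join fold changes and reproducibility over homolog pairs.

    ``fc_a``/``fc_b`` carry a ``log2_fc`` column indexed by gene;
    ``repro_a``/``repro_b`` map gene -> replicate-profile r. Many-to-many
    homolog pairs are collapsed to the pair maximizing min(r_a, r_b) per gene
    (ties break on the pair's ids), mirroring the max-correlation
    representative rule. The joint-reproducible flag requires r strictly
    above ``repro_threshold`` on both sides.
    """
    pairs = homolog_map[["gene_a", "gene_b"]].drop_duplicates()
    joined = pairs[
        pairs["gene_a"].isin(fc_a.index) & pairs["gene_b"].isin(fc_b.index)
    ].copy()
    joined["fc_a"] = fc_a.loc[joined["gene_a"], "log2_fc"].to_numpy()
    joined["fc_b"] = fc_b.loc[joined["gene_b"], "log2_fc"].to_numpy()
    joined["r_a"] = repro_a.reindex(joined["gene_a"]).to_numpy()
    joined["r_b"] = repro_b.reindex(joined["gene_b"]).to_numpy()
    joined["min_r"] = np.fmin(joined["r_a"], joined["r_b"])

    before = len(joined)
    joined = joined.sort_values(
        ["min_r", "gene_a", "gene_b"], ascending=[False, True, True], kind="stable"
    )
    joined = joined.drop_duplicates(subset="gene_a", keep="first")
    joined = joined.drop_duplicates(subset="gene_b", keep="first")
    if len(joined) < before:
        logger.info("collapsed %d many-to-many homolog pairs", before - len(joined))
    joined = joined.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)
    joined["joint_reproducible"] = (joined["r_a"] > repro_threshold) & (
        joined["r_b"] > repro_threshold
    )
    return joined.drop(columns="min_r")


def concordance_table(
    pairs: pd.DataFrame,
    fold_threshold_log2: float = DEFAULT_FOLD_THRESHOLD_LOG2,
    joint_reproducible_only: bool = True,
) -> np.ndarray:
    """2x2 direction counts among pairs >= 2-fold changed in both datasets.

    The magnitude filter is inclusive (|log2 FC| >= threshold). Rows are
    dataset-1 direction (up, down); columns dataset-2 direction.
    """
    if fold_threshold_log2 < 0:
        raise ValueError("fold threshold must be >= 0")
    sel = pairs
    if joint_reproducible_only and "joint_reproducible" in pairs.columns:
        sel = pairs[pairs["joint_reproducible"]]
    qualifying = sel[
        (sel["fc_a"].abs() >= fold_threshold_log2)
        & (sel["fc_b"].abs() >= fold_threshold_log2)
    ]
    up_a = qualifying["fc_a"] > 0
    up_b = qualifying["fc_b"] > 0
    counts = np.array(
        [
            [int((up_a & up_b).sum()), int((up_a & ~up_b).sum())],
            [int((~up_a & up_b).sum()), int((~up_a & ~up_b).sum())],
        ]
    )
    return counts


def fisher_exact(counts: np.ndarray) -> ContingencyResult:
    """Two-sided Fisher exact test of a 2x2 table.

    The p-value sums hypergeometric probabilities of every table with the
    observed margins whose probability does not exceed the observed table's
    (the minimum-likelihood two-sided convention). The odds ratio is the
    sample ratio n11*n22 / (n12*n21), infinite when a discordant cell is zero
    while the concordant cells are positive, NaN for 0/0.
    """
    counts = np.asarray(counts, dtype=int)
    if counts.shape != (2, 2):
        raise ValueError("need a 2x2 table")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    n11, n12 = counts[0]
    n21, n22 = counts[1]
    num, den = n11 * n22, n12 * n21
    if den > 0:
        odds = num / den
    elif num > 0:
        odds = np.inf
    else:
        odds = np.nan
    _, p = stats.fisher_exact(counts, alternative="two-sided")
    return ContingencyResult(
        counts=counts,
        n_pairs=int(counts.sum()),
        odds_ratio=float(odds),
        p_value=float(p),
    )
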