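"""PCA classification of temporal expression patterns.

Standardized day profiles (replicate-averaged log2 signal, z-scored per gene
across days) are decomposed by PCA with genes as observations and days as
variables. The first principal component separates the two large-scale
temporal archetypes; the sign of the PC1 score assigns each gene to the
*decreasing* hemisphere (high early, low late) or the *increasing* hemisphere,
with an explicit orientation anchor so the labelling is invariant to PC sign
flips.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "standardize_profiles",
    "pca_genes",
    "PcaResult",
    "classify_hemisphere",
    "average_pattern_profile",
]

logger = logging.getLogger(__name__)

DECREASING = "decreasing"
INCREASING = "increasing"


def standardize_profiles(
    gene_expr: pd.DataFrame, design: pd.DataFrame
) -> pd.DataFrame:
    """Replicate-average per day, then z-score each gene across days.

    Rows with zero standard deviation across days carry no temporal signal
    and are dropped with a warning. Sample SD (ddof=1) is used, so each
    returned row has mean 0 and SD 1.
    """
    days = sorted(design["day"].unique())
    if len(days) < 2:
        raise ValueError("need at least 2 days to standardize profiles")
    day_means = pd.DataFrame(
        {d: gene_expr[design.index[design["day"] == d]].mean(axis=1) for d in days}
    )
    sd = day_means.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.warning("dropping %d genes with constant day profiles", int(flat.sum()))
        day_means = day_means[~flat]
        sd = sd[~flat]
    z = day_means.sub(day_means.mean(axis=1), axis=0).div(sd, axis=0)
    z.columns.name = "day"
    return z


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame  # gene x PC
    loadings: pd.DataFrame  # day x PC
    variance_fractions: np.ndarray


def pca_genes(profiles: pd.DataFrame) -> PcaResult:
    """PCA of the gene x day profile matrix (genes as observations).

    Columns (days) are centered across genes, then decomposed by SVD; no
    additional scaling beyond the per-gene standardization. Each PC's sign is
    fixed so that its largest-magnitude loading is positive, which makes the
    decomposition deterministic; downstream classification applies its own
    orientation anchor on top.
    """
    if profiles.shape[0] < 2 or profiles.shape[1] < 2:
        raise ValueError("PCA needs at least 2 genes and 2 days")
    X = profiles.to_numpy(dtype=float)
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry of each PC is positive
    for k in range(len(S)):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1.0
            U[:, k] *= -1.0
    scores = U * S
    var = S**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    pcs = [f"pc{k + 1}" for k in range(len(S))]
    return PcaResult(
        scores=pd.DataFrame(scores, index=profiles.index, columns=pcs),
        loadings=pd.DataFrame(Vt.T, index=profiles.columns, columns=pcs),
        variance_fractions=frac,
    )


def classify_hemisphere(
    pca: PcaResult, profiles: pd.DataFrame
) -> pd.DataFrame:
    """Assign each gene to the decreasing or increasing temporal pattern.

    The binary label is the sign of the PC1 score, oriented so that the
    centroid profile of the *decreasing* class has a higher standardized value
    at the earliest day than at the latest day. A gene whose score is exactly
    zero is assigned by the sign of (first-day z - last-day z), ties going to
    decreasing.
    """
    pc1 = pca.scores["pc1"].to_numpy()
    z = profiles.to_numpy(dtype=float)
    first_minus_last = z[:, 0] - z[:, -1]

    neg = pc1 < 0
    pos = pc1 > 0
    # orientation anchor: which sign's centroid decreases over time?
    def _slope(mask: np.ndarray) -> float:
        if not mask.any():
            return 0.0
        centroid = z[mask].mean(axis=0)
        return float(centroid[0] - centroid[-1])

    neg_is_decreasing = _slope(neg) >= _slope(pos)
    pattern = np.where(
        pc1 == 0,
        np.where(first_minus_last >= 0, DECREASING, INCREASING),
        np.where((pc1 < 0) == neg_is_decreasing, DECREASING, INCREASING),
    )
    out = pca.scores.copy()
    out["pattern"] = pattern
    return out


def average_pattern_profile(
    assignment: pd.DataFrame, profiles: pd.DataFrame
) -> tuple[pd.DataFrame, int | float]:
    """Per-pattern mean standardized profile and the crossing day.

    Returns ``(profiles_by_pattern, crossing_day)``: the day-indexed mean
    z-profile of each class, and the day at which the two class averages are
    closest (where the temporal switch happens). With a single class the
    crossing day is the single profile's day closest to zero.
    """
    patterns = assignment.loc[profiles.index, "pattern"]
    by_pattern = profiles.groupby(patterns).mean()
    days = list(profiles.columns)
    if len(by_pattern) == 2:
        gap = np.abs(by_pattern.iloc[0].to_numpy() - by_pattern.iloc[1].to_numpy())
    else:
        gap = np.abs(by_pattern.iloc[0].to_numpy())
    crossing_day = days[int(np.argmin(gap))]
    return by_pattern, crossing_day
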