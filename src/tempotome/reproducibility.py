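"""Replicate time-profile reproducibility filtering.

Each probe set's day-ordered expression profile is measured twice (biological
replicates A and B). The Pearson correlation between the two *unlogged*
profiles (2^log2 signal) scores how reproducible the temporal profile is;
probe sets with r > 0.8 (strict) are retained, and a gene measured by several
probe sets is represented by the retained probe set with maximal r.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = [
    "replicate_profile_correlation",
    "filter_reproducible",
    "collapse_to_genes",
]

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.8


def _replicate_day_arrays(design: pd.DataFrame) -> tuple[list[int], list[str], list[str]]:
    """Days where both of the first two replicate labels are measured."""
    labels = sorted(design["replicate"].unique())
    if len(labels) < 2:
        raise ValueError("need two replicate labels to compute reproducibility")
    rep_a, rep_b = labels[0], labels[1]
    lookup = {(d, r): a for a, (d, r) in design[["day", "replicate"]].iterrows()}
    days = sorted(
        d for d in design["day"].unique() if (d, rep_a) in lookup and (d, rep_b) in lookup
    )
    arrays_a = [lookup[(d, rep_a)] for d in days]
    arrays_b = [lookup[(d, rep_b)] for d in days]
    return days, arrays_a, arrays_b


def _rowwise_pearson(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    na = np.sqrt((A * A).sum(axis=1))
    nb = np.sqrt((B * B).sum(axis=1))
    denom = na * nb
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (A * B).sum(axis=1) / denom
    r[denom == 0] = np.nan  # zero-variance profile: r undefined
    return r


def replicate_profile_correlation(
    expr: pd.DataFrame,
    design: pd.DataFrame,
    probeset_to_gene: pd.Series | None = None,
    log_scale: bool = False,
) -> pd.DataFrame:
    """Pearson r between unlogged replicate time profiles, per probe set.

    ``expr`` is the log2 probe-set x array matrix. Profiles are restricted to
    days where both replicates exist (pairwise-complete; at least 3 required).
    By default profiles are unlogged (2^x) before correlating; ``log_scale``
    correlates the log2 profiles instead (sensitivity analysis).

    Returns a table with columns gene_id, r, n_days_used, retained (False
    until :func:`filter_reproducible` is applied).
    """
    days, arrays_a, arrays_b = _replicate_day_arrays(design)
    if len(days) < 3:
        raise ValueError(f"need >= 3 days with both replicates, found {len(days)}")
    A = expr[arrays_a].to_numpy(dtype=float)
    B = expr[arrays_b].to_numpy(dtype=float)
    if not log_scale:
        A, B = np.exp2(A), np.exp2(B)
    r = _rowwise_pearson(A, B)
    n_undef = int(np.isnan(r).sum())
    if n_undef:
        logger.info("replicate correlation undefined (zero variance) for %d probe sets", n_undef)
    if probeset_to_gene is None:
        gene = pd.Series(expr.index, index=expr.index)
    else:
        gene = probeset_to_gene.reindex(expr.index)
    return pd.DataFrame(
        {
            "gene_id": gene.to_numpy(),
            "r": r,
            "n_days_used": len(days),
            "retained": False,
        },
        index=pd.Index(expr.index, name="probeset_id"),
    )


def filter_reproducible(
    table: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD
) -> pd.DataFrame:
    """Mark probe sets with r strictly greater than ``threshold`` as retained.

    Undefined r (NaN) is never retained.
    """
    if not -1.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [-1, 1], got {threshold}")
    out = table.copy()
    out["retained"] = (out["r"] > threshold).fillna(False)
    return out


def collapse_to_genes(
    table: pd.DataFrame, expr: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Collapse retained probe sets to one representative per gene.

    For genes with several retained probe sets, the probe set with maximal r
    represents the gene; ties break to the lexicographically smallest
    probeset_id so the choice is deterministic. Genes with no retained probe
    set are dropped (logged, not an error).

    Returns ``(gene_expression, gene_to_probeset)``.
    """
    retained = table[table["retained"]]
    n_genes_total = table["gene_id"].nunique()
    if retained.empty:
        logger.warning("no probe sets retained; empty gene expression matrix")
        empty = pd.DataFrame(columns=expr.columns)
        empty.index.name = "gene_id"
        return empty, pd.Series(dtype=object, name="probeset_id")
    # stable representative: sort by (gene, -r, probeset_id) and take the head
    ranked = retained.reset_index().sort_values(
        ["gene_id", "r", "probeset_id"], ascending=[True, False, True], kind="stable"
    )
    best = ranked.drop_duplicates(subset="gene_id", keep="first")
    dropped = n_genes_total - len(best)
    if dropped:
        logger.info("dropped %d genes with no retained probe set", dropped)
    gene_expr = expr.loc[best["probeset_id"]].copy()
    gene_expr.index = pd.Index(best["gene_id"].to_numpy(), name="gene_id")
    gene_expr = gene_expr.sort_index()
    mapping = pd.Series(
        best["probeset_id"].to_numpy(), index=best["gene_id"].to_numpy(), name="probeset_id"
    ).sort_index()
    return gene_expr, mapping
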