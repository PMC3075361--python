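"""Model/Results interface over the time-course analysis stages.

``TimeCourseModel`` is constructed from a log2 probe-set x array expression
matrix, a design table, and a probe-set -> gene annotation; ``fit()`` runs the
reproducibility filter, gene collapse, PCA pattern classification and the
fold-change contrasts, returning a ``TimeCourseResults`` carrying every stage
table plus a text ``summary()``.

``CrossDatasetConcordance`` fits the 2x2 direction-concordance model over a
homolog map between two fitted datasets, and ``DeltaDeltaCtModel`` fits ddCT
fold changes from a CT table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import concordance as _concordance
from . import contrasts as _contrasts
from . import patterns as _patterns
from . import qpcr as _qpcr
from .io import validate_design_arrays
from .patterns import PcaResult

__all__ = [
    "TimeCourseModel",
    "TimeCourseResults",
    "CrossDatasetConcordance",
    "DeltaDeltaCtModel",
    "DeltaDeltaCtResults",
]


class TimeCourseModel:
    """Replicated time-course expression analysis.

    Parameters
    ----------
    expression : DataFrame
        log2 probe-set (or gene) x array signals, e.g. RMA output.
    design : DataFrame
        array_id-indexed table with ``day`` and ``replicate`` columns.
    probeset_to_gene : Series, optional
        probe-set -> gene annotation; identity when omitted.
    """

    def __init__(
        self,
        expression: pd.DataFrame,
        design: pd.DataFrame,
        probeset_to_gene: pd.Series | None = None,
    ) -> None:
        validate_design_arrays(expression, design)
        self.expression = expression
        self.design = design
        self.probeset_to_gene = probeset_to_gene

    @classmethod
    def from_tsv(cls, expression_path, design_path, annotation_path=None) -> "TimeCourseModel":
        from .io import read_design, read_expression

        expr = read_expression(expression_path)
        design = read_design(design_path)
        annot = None
        if annotation_path is not None:
            df = pd.read_csv(annotation_path, sep="\t", dtype=str)
            annot = df.set_index("probeset_id")["gene_id"]
        return cls(expr, design, annot)

    def fit(
        self,
        repro_threshold: float = 0.8,
        log_scale_correlation: bool = False,
        early_days: tuple[int, ...] = (0, 1),
        late_days: tuple[int, ...] = (10, 14),
        contrast_day: int | None = 4,
        alpha: float = 0.05,
    ) -> "TimeCourseResults":
        from . import reproducibility as _repro

        table = _repro.replicate_profile_correlation(
            self.expression, self.design, self.probeset_to_gene,
            log_scale=log_scale_correlation,
        )
        table = _repro.filter_reproducible(table, threshold=repro_threshold)
        gene_expr, gene_to_probeset = _repro.collapse_to_genes(table, self.expression)

        profiles = _patterns.standardize_profiles(gene_expr, self.design)
        pca = _patterns.pca_genes(profiles)
        assignment = _patterns.classify_hemisphere(pca, profiles)
        pattern_profiles, crossing_day = _patterns.average_pattern_profile(
            assignment, profiles
        )
        fold_changes = _contrasts.fold_change_late_vs_early(
            gene_expr, self.design, early_days=early_days, late_days=late_days
        )
        day_contrast = None
        if contrast_day is not None and (self.design["day"] == contrast_day).sum() >= 2:
            day_contrast = _contrasts.day4_contrast(
                gene_expr, self.design, day=contrast_day, alpha=alpha
            )
        return TimeCourseResults(
            model=self,
            reproducibility=table,
            gene_expression=gene_expr,
            gene_to_probeset=gene_to_probeset,
            profiles=profiles,
            pca=pca,
            patterns=assignment,
            pattern_profiles=pattern_profiles,
            crossing_day=crossing_day,
            fold_changes=fold_changes,
            day_contrast=day_contrast,
            params={
                "repro_threshold": repro_threshold,
                "log_scale_correlation": log_scale_correlation,
                "early_days": tuple(early_days),
                "late_days": tuple(late_days),
                "contrast_day": contrast_day,
                "alpha": alpha,
            },
        )


@dataclass
class TimeCourseResults:
    """Fitted tables of every time-course analysis stage."""

    model: TimeCourseModel = field(repr=False)
    reproducibility: pd.DataFrame
    gene_expression: pd.DataFrame
    gene_to_probeset: pd.Series
    profiles: pd.DataFrame
    pca: PcaResult
    patterns: pd.DataFrame
    pattern_profiles: pd.DataFrame
    crossing_day: int | float
    fold_changes: pd.DataFrame
    day_contrast: pd.DataFrame | None
    params: dict

    @property
    def gene_reproducibility(self) -> pd.Series:
        """gene -> replicate-profile r of its representative probe set."""
        r = self.reproducibility.loc[self.gene_to_probeset.to_numpy(), "r"]
        return pd.Series(r.to_numpy(), index=self.gene_to_probeset.index, name="r")

    @property
    def n_retained_probesets(self) -> int:
        return int(self.reproducibility["retained"].sum())

    @property
    def n_genes(self) -> int:
        return int(len(self.gene_expression))

    def pattern_counts(self) -> pd.Series:
        return self.patterns["pattern"].value_counts()

    def summary(self) -> str:
        counts = self.pattern_counts()
        total = counts.sum()
        lines = [
            "Time-course expression analysis",
            "=" * 47,
            f"probe sets scored:        {len(self.reproducibility)}",
            f"retained (r > {self.params['repro_threshold']}):       {self.n_retained_probesets}",
            f"unique genes:             {self.n_genes}",
            f"classified genes:         {total}",
        ]
        for name in ("decreasing", "increasing"):
            n = int(counts.get(name, 0))
            pct = 100.0 * n / total if total else 0.0
            lines.append(f"  {name:<10} pattern:     {n} ({pct:.1f}%)")
        pc_var = self.pca.variance_fractions
        lines.append(f"PC1/PC2 variance:         {pc_var[0]:.3f} / {pc_var[1]:.3f}")
        lines.append(f"pattern crossing day:     {self.crossing_day}")
        e, l = self.params["early_days"], self.params["late_days"]
        lines.append(
            f"log2 FC days {l} vs {e}: median {self.fold_changes['log2_fc'].median():+.2f}"
        )
        if self.day_contrast is not None:
            up = int((self.day_contrast["direction"] == "up").sum())
            down = int((self.day_contrast["direction"] == "down").sum())
            lines.append(
                f"day-{self.params['contrast_day']} contrast (FDR {self.params['alpha']}): "
                f"{up} up, {down} down"
            )
        return "\n".join(lines)


class CrossDatasetConcordance:
    """Direction-concordance model between two fitted datasets.

    Accepts either two ``TimeCourseResults`` or raw (fold-change table,
    gene -> r) pairs, plus the homolog map (columns gene_a, gene_b).
    """

    def __init__(
        self,
        fc_a: pd.DataFrame,
        repro_a: pd.Series,
        fc_b: pd.DataFrame,
        repro_b: pd.Series,
        homolog_map: pd.DataFrame,
    ) -> None:
        self.fc_a, self.repro_a = fc_a, repro_a
        self.fc_b, self.repro_b = fc_b, repro_b
        self.homolog_map = homolog_map

    @classmethod
    def from_results(
        cls,
        results_a: TimeCourseResults,
        results_b: TimeCourseResults,
        homolog_map: pd.DataFrame,
    ) -> "CrossDatasetConcordance":
        return cls(
            results_a.fold_changes, results_a.gene_reproducibility,
            results_b.fold_changes, results_b.gene_reproducibility,
            homolog_map,
        )

    def fit(
        self,
        repro_threshold: float = 0.8,
        fold_threshold_log2: float = 1.0,
    ) -> "_concordance.ContingencyResult":
        self.pairs_ = _concordance.join_homologs(
            self.fc_a, self.repro_a, self.fc_b, self.repro_b,
            self.homolog_map, repro_threshold=repro_threshold,
        )
        counts = _concordance.concordance_table(
            self.pairs_, fold_threshold_log2=fold_threshold_log2
        )
        return _concordance.fisher_exact(counts)


class DeltaDeltaCtModel:
    """ddCT relative-quantification model for a qPCR CT table."""

    def __init__(
        self,
        ct_table: pd.DataFrame,
        reference: str = _qpcr.DEFAULT_REFERENCE,
        baseline_day: int = 0,
        efficiency: float = 2.0,
    ) -> None:
        self.ct_table = ct_table
        self.reference = reference
        self.baseline_day = baseline_day
        self.efficiency = efficiency

    def fit(self, equal_var: bool = False) -> "DeltaDeltaCtResults":
        fc = _qpcr.ddct_log2fc(
            self.ct_table, reference=self.reference,
            baseline_day=self.baseline_day, efficiency=self.efficiency,
            equal_var=equal_var,
        )
        return DeltaDeltaCtResults(model=self, fold_changes=fc)


@dataclass
class DeltaDeltaCtResults:
    model: DeltaDeltaCtModel = field(repr=False)
    fold_changes: pd.DataFrame

    def compare_with_microarray(
        self,
        gene_expr: pd.DataFrame,
        design: pd.DataFrame,
        early_days: tuple[int, ...] = (0, 1),
        late_days: tuple[int, ...] = (10, 14),
    ) -> tuple[pd.DataFrame, pd.DataFrame]:
        return _qpcr.compare_qpcr_microarray(
            self.fold_changes, gene_expr, design,
            early_days=early_days, late_days=late_days,
            baseline_day=self.model.baseline_day,
        )

    def summary(self) -> str:
        genes = self.fold_changes["gene_id"].unique()
        lines = [
            "ddCT relative quantification",
            "=" * 40,
            f"reference gene: {self.model.reference}, baseline day {self.model.baseline_day}",
        ]
        for g in genes:
            sub = self.fold_changes[self.fold_changes["gene_id"] == g]
            last = sub.iloc[-1]
            lines.append(
                f"  {g:<10} day {int(last['day']):>2}: log2 FC {last['log2_fc_vs_day0']:+.2f}"
                + (f" (p={last['p_value']:.3g})" if np.isfinite(last["p_value"]) else "")
            )
        return "\n".join(lines)
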