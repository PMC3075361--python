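"""End-to-end pipeline: simulate -> rma -> repro -> patterns -> contrasts ->
concordance -> qpcr, driven by a single declarative configuration.

Every stage reads/writes the documented TSV dialects; a manifest records each
produced file with its SHA-256 hash, row count and the stage parameters, so a
rerun with the same config and seed can be checked for bit-identical outputs.
A stage is skipped when its declared outputs are all newer than its inputs,
unless ``force`` is set.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as _io
from . import qpcr as _qpcr
from .rma import rma as _run_rma
from .simulate import SimulationConfig, generate_companion_dataset, generate_qpcr, generate_timecourse
from .timecourse import CrossDatasetConcordance, DeltaDeltaCtModel, TimeCourseModel

__all__ = ["PipelineConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths, thresholds and flags for a full pipeline run."""

    workdir: str = "."
    seed: int = 0
    n_genes: int = 500
    repro_threshold: float = 0.8
    fold_threshold_log2: float = 1.0
    alpha: float = 0.05
    early_days: tuple[int, ...] = (0, 1)
    late_days: tuple[int, ...] = (10, 14)
    contrast_day: int = 4
    companion_early_days: tuple[int, ...] = (0,)
    companion_late_days: tuple[int, ...] = (4,)
    bgcorrect: bool = True
    log_scale_correlation: bool = False
    efficiency: float = 2.0
    qpcr_genes: tuple[str, ...] = ()  # default: first six reproducible genes
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    def __post_init__(self) -> None:
        if set(self.early_days) & set(self.late_days):
            raise ValueError("early and late day sets must be disjoint")
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must be in [0, 1]")
        if not -1 <= self.repro_threshold <= 1:
            raise ValueError("repro_threshold must be in [-1, 1]")
        if self.fold_threshold_log2 < 0:
            raise ValueError("fold_threshold_log2 must be >= 0")

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            n_genes=self.n_genes, seed=self.seed, **self.simulation
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("early_days", "late_days", "companion_early_days",
                    "companion_late_days", "qpcr_genes"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _row_count(path: Path) -> int:
    with open(path, encoding="utf-8") as fh:
        return max(0, sum(1 for _ in fh) - 1)  # minus header


def _stale(outputs: list[Path], inputs: list[Path]) -> bool:
    """True when any output is missing or older than any input."""
    if not all(p.exists() for p in outputs):
        return True
    if not inputs:
        return False
    newest_in = max(p.stat().st_mtime for p in inputs)
    return any(p.stat().st_mtime < newest_in for p in outputs)


def run_pipeline(config: PipelineConfig, force: bool = False) -> dict:
    """Run every stage, returning a manifest of produced files.

    The manifest maps file name -> {sha256, n_rows} plus the stage parameters;
    rerunning with the same config and seed reproduces identical hashes.
    """
    wd = Path(config.workdir)
    wd.mkdir(parents=True, exist_ok=True)
    sim_config = config.simulation_config()
    manifest: dict = {
        "params": {**{k: v for k, v in asdict(config).items() if k != "workdir"}},
        "files": {},
        "stages": {},
    }

    paths = {
        name: wd / f"{name}.tsv"
        for name in (
            "probes", "design", "truth", "homologs", "companion_expression",
            "companion_design", "qpcr", "expression", "reproducibility",
            "gene_expression", "patterns", "pattern_profiles", "foldchange",
            "day4", "companion_reproducibility", "companion_foldchange",
            "concordance", "qpcr_fc", "qpcr_comparison",
        )
    }

    def _stage(name: str, inputs: list[Path], outputs: list[Path], fn) -> None:
        t0 = time.monotonic()
        if not force and not _stale(outputs, inputs):
            logger.info("stage %s: up to date, skipped", name)
            manifest["stages"][name] = {"skipped": True}
            return
        fn()
        dt = time.monotonic() - t0
        logger.info("stage %s: %.2fs", name, dt)
        manifest["stages"][name] = {"skipped": False}

    # -- simulate -------------------------------------------------------
    sim_outputs = [paths[n] for n in (
        "probes", "design", "truth", "homologs",
        "companion_expression", "companion_design", "qpcr",
    )]

    def _simulate() -> None:
        probes, design, truth = generate_timecourse(sim_config)
        comp_expr, comp_design, homolog_map = generate_companion_dataset(truth, sim_config)
        qpcr_genes = list(config.qpcr_genes)
        if not qpcr_genes:
            repro_genes = truth.genes.index[truth.genes["reproducible"]]
            qpcr_genes = list(repro_genes[:6])
        ct = generate_qpcr(truth, qpcr_genes, sim_config)
        _io.write_probes(probes, paths["probes"])
        _io.write_design(design, paths["design"])
        truth.to_frame().to_csv(paths["truth"], sep="\t", index=False)
        homolog_map.to_csv(paths["homologs"], sep="\t", index=False)
        _io.write_expression(comp_expr, paths["companion_expression"], index_name="gene_id")
        _io.write_design(comp_design, paths["companion_design"])
        ct.to_csv(paths["qpcr"], sep="\t", index=False)

    _stage("simulate", [], sim_outputs, _simulate)

    # -- rma ------------------------------------------------------------
    def _rma_stage() -> None:
        probes = _io.read_probes(paths["probes"])
        expr = _run_rma(probes, bgcorrect=config.bgcorrect)
        _io.write_expression(expr, paths["expression"], index_name="probeset_id")

    _stage("rma", [paths["probes"]], [paths["expression"]], _rma_stage)

    # -- primary analysis (repro + patterns + contrasts) ----------------
    primary_outputs = [paths[n] for n in (
        "reproducibility", "gene_expression", "patterns", "pattern_profiles",
        "foldchange", "day4",
    )]

    def _primary() -> None:
        expr = _io.read_expression(paths["expression"])
        design = _io.read_design(paths["design"])
        _io.validate_design_arrays(expr, design)
        truth = pd.read_csv(paths["truth"], sep="\t")
        ps2gene = _probeset_to_gene(expr.index)
        model = TimeCourseModel(expr, design, ps2gene)
        res = model.fit(
            repro_threshold=config.repro_threshold,
            log_scale_correlation=config.log_scale_correlation,
            early_days=config.early_days,
            late_days=config.late_days,
            contrast_day=config.contrast_day,
            alpha=config.alpha,
        )
        res.reproducibility.to_csv(paths["reproducibility"], sep="\t")
        _io.write_expression(res.gene_expression, paths["gene_expression"], index_name="gene_id")
        res.patterns.to_csv(paths["patterns"], sep="\t", index_label="gene_id")
        res.pattern_profiles.to_csv(paths["pattern_profiles"], sep="\t", index_label="pattern")
        res.fold_changes.to_csv(paths["foldchange"], sep="\t", index_label="gene_id")
        if res.day_contrast is not None:
            res.day_contrast.to_csv(paths["day4"], sep="\t", index_label="gene_id")
        else:
            paths["day4"].write_text("gene_id\tlog2_fc_day_vs_rest\tp_value\tadjusted_p\tdirection\n")
        _ = truth  # read for validation only

    _stage(
        "primary",
        [paths["expression"], paths["design"], paths["truth"]],
        primary_outputs,
        _primary,
    )

    # -- companion analysis ---------------------------------------------
    comp_outputs = [paths["companion_reproducibility"], paths["companion_foldchange"]]

    def _companion() -> None:
        from . import reproducibility as _repro
        from .contrasts import fold_change_late_vs_early

        expr = _io.read_expression(paths["companion_expression"])
        design = _io.read_design(paths["companion_design"])
        table = _repro.replicate_profile_correlation(expr, design)
        table = _repro.filter_reproducible(table, threshold=config.repro_threshold)
        table.to_csv(paths["companion_reproducibility"], sep="\t")
        fc = fold_change_late_vs_early(
            expr, design,
            early_days=config.companion_early_days,
            late_days=config.companion_late_days,
        )
        fc.to_csv(paths["companion_foldchange"], sep="\t", index_label="gene_id")

    _stage(
        "companion",
        [paths["companion_expression"], paths["companion_design"]],
        comp_outputs,
        _companion,
    )

    # -- concordance ----------------------------------------------------
    def _concord() -> None:
        fc_a = pd.read_csv(paths["foldchange"], sep="\t", index_col="gene_id")
        repro = pd.read_csv(paths["reproducibility"], sep="\t", index_col="probeset_id")
        gene_r = repro[repro["retained"]].groupby("gene_id")["r"].max()
        fc_b = pd.read_csv(paths["companion_foldchange"], sep="\t", index_col="gene_id")
        repro_b_table = pd.read_csv(
            paths["companion_reproducibility"], sep="\t", index_col="probeset_id"
        )
        gene_r_b = pd.Series(
            repro_b_table["r"].to_numpy(), index=repro_b_table["gene_id"].to_numpy()
        )
        homolog_map = pd.read_csv(paths["homologs"], sep="\t")
        model = CrossDatasetConcordance(fc_a, gene_r, fc_b, gene_r_b, homolog_map)
        result = model.fit(
            repro_threshold=config.repro_threshold,
            fold_threshold_log2=config.fold_threshold_log2,
        )
        c = result.counts
        pd.DataFrame(
            {
                "n11_up_up": [c[0, 0]], "n12_up_down": [c[0, 1]],
                "n21_down_up": [c[1, 0]], "n22_down_down": [c[1, 1]],
                "n_pairs": [result.n_pairs],
                "odds_ratio": [result.odds_ratio],
                "p_value": [result.p_value],
            }
        ).to_csv(paths["concordance"], sep="\t", index=False)

    _stage(
        "concordance",
        [paths["foldchange"], paths["reproducibility"],
         paths["companion_foldchange"], paths["companion_reproducibility"],
         paths["homologs"]],
        [paths["concordance"]],
        _concord,
    )

    # -- qpcr -----------------------------------------------------------
    def _qpcr_stage() -> None:
        ct = pd.read_csv(paths["qpcr"], sep="\t", dtype={"replicate": str})
        model = DeltaDeltaCtModel(ct, reference=_qpcr.DEFAULT_REFERENCE,
                                  efficiency=config.efficiency)
        res = model.fit()
        res.fold_changes.to_csv(paths["qpcr_fc"], sep="\t", index=False)
        gene_expr = _io.read_expression(paths["gene_expression"])
        design = _io.read_design(paths["design"])
        _, summary = res.compare_with_microarray(
            gene_expr, design,
            early_days=config.early_days, late_days=config.late_days,
        )
        summary.to_csv(paths["qpcr_comparison"], sep="\t", index=False)

    _stage(
        "qpcr",
        [paths["qpcr"], paths["gene_expression"], paths["design"]],
        [paths["qpcr_fc"], paths["qpcr_comparison"]],
        _qpcr_stage,
    )

    for name, path in paths.items():
        if path.exists():
            manifest["files"][path.name] = {
                "sha256": _sha256(path),
                "n_rows": _row_count(path),
            }
    with open(wd / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest


def _probeset_to_gene(probeset_ids) -> pd.Series:
    """Recover gene ids from the generator's '<gene>_ps<j>' probe-set names."""
    genes = [p.rsplit("_ps", 1)[0] if "_ps" in p else p for p in probeset_ids]
    return pd.Series(genes, index=probeset_ids, name="gene_id")
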