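"""Synthetic probe-level time-course data with known ground truth.

The generator emulates the design of a myogenic-differentiation microarray
study: six time points (days 0, 1, 4, 7, 10, 14) with biological duplicates
(A, B), two temporal archetypes — genes that *decrease* from an early plateau
and genes that *increase* to a late plateau, switching near day 4 via a
logistic transition in log2 space — a mixture of reproducible and
non-reproducible probe sets targeted so that roughly half survive an r > 0.8
replicate-correlation filter, and multiple probe sets per gene.

It also produces a paired companion dataset in a second gene namespace
(emulating a mouse C2C12 myoblast-to-myotube comparison at days 0, 1, 4) with
tunable fold-change concordance, and qPCR CT tables with a stable reference
gene (ef1a).

Optical model: probe intensity = 2^(gene log2 level + probe affinity +
N(0, noise_sd_log2)) * signal_scale + background, background ~ N(mu, sd)
truncated at zero — the same exponential-signal-plus-Gaussian-background
family the RMA background correction assumes.

All randomness flows from ``SimulationConfig.seed``; identical configs give
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import ProbeIntensityMatrix

__all__ = [
    "ConfigurationError",
    "SimulationConfig",
    "GroundTruth",
    "generate_timecourse",
    "generate_companion_dataset",
    "generate_qpcr",
    "logistic_level",
]

REFERENCE_GENE = "ef1a"
_REPLICATE_LABELS = "ABCDEFGH"


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design constants and noise levels for the generator.

    Defaults encode the emulated study design: 6 time points, duplicate
    biological measurements, a 56% decreasing / 44% increasing archetype
    split switching at day 4, an archetype contrast of 2.5 log2 units and
    0.4 log2 units of probe-level noise.
    """

    n_genes: int = 5000
    probes_per_probeset: int = 8
    #: P(gene has 1, 2, 3 probe sets)
    probesets_per_gene_probs: tuple[float, float, float] = (0.6, 0.3, 0.1)
    timepoints: tuple[int, ...] = (0, 1, 4, 7, 10, 14)
    replicates_per_timepoint: int = 2
    #: days at which the last replicate is dropped (missing-replicate policy)
    missing_replicate_days: tuple[int, ...] = ()
    frac_decreasing: float = 0.56
    frac_nonreproducible: float = 0.5
    switch_day: float = 4.0
    switch_steepness: float = 2.0  # logistic slope, per day
    effect_size_log2: float = 2.5
    noise_sd_log2: float = 0.4
    nonrepro_noise_sd_log2: float = 0.4
    base_level_log2: tuple[float, float] = (4.0, 12.0)  # uniform range
    probe_affinity_sd_log2: float = 0.5
    background_mean: float = 50.0
    background_sd: float = 10.0
    signal_scale: float = 1.0
    # companion dataset (second namespace, e.g. mouse C2C12)
    n_shared_genes: int | None = None  # default: 60% of n_genes
    concordance_rate: float = 0.9
    companion_timepoints: tuple[int, ...] = (0, 1, 4)
    companion_noise_sd_log2: float = 0.2
    companion_frac_nonreproducible: float = 0.0
    # qPCR
    qpcr_technical_replicates: int = 3
    ct_noise: float = 0.2
    ct_ref_noise: float = 0.0
    ct_intercept: float = 40.0
    ref_ct: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "probes_per_probeset": self.probes_per_probeset,
            "replicates_per_timepoint": self.replicates_per_timepoint,
            "qpcr_technical_replicates": self.qpcr_technical_replicates,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {v}")
        for name in ("frac_decreasing", "frac_nonreproducible", "concordance_rate",
                     "companion_frac_nonreproducible"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for tp_name in ("timepoints", "companion_timepoints"):
            tp = getattr(self, tp_name)
            if len(tp) < 2:
                raise ConfigurationError(f"{tp_name}: need at least 2 timepoints")
            if any(b <= a for a, b in zip(tp, tp[1:])):
                raise ConfigurationError(f"{tp_name} must be strictly increasing")
        for name in ("effect_size_log2", "noise_sd_log2", "background_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.signal_scale <= 0:
            raise ConfigurationError("signal_scale must be > 0")
        if self.background_mean < 0:
            raise ConfigurationError("background_mean must be >= 0")
        if abs(sum(self.probesets_per_gene_probs) - 1.0) > 1e-9:
            raise ConfigurationError("probesets_per_gene_probs must sum to 1")
        if self.replicates_per_timepoint > len(_REPLICATE_LABELS):
            raise ConfigurationError("too many replicates per timepoint")
        if self.shared_gene_count > self.n_genes:
            raise ConfigurationError("n_shared_genes exceeds n_genes")

    @property
    def shared_gene_count(self) -> int:
        if self.n_shared_genes is not None:
            return self.n_shared_genes
        return max(1, round(0.6 * self.n_genes))

    def replace(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """Truth labels for recovery tests.

    ``genes`` — index gene_id; columns: archetype ('decreasing'/'increasing'),
    reproducible (bool), base_level (log2), true_log2_fc (late-vs-early
    plateau contrast, first two vs last two timepoints, log2),
    n_probesets (int).
    ``probesets`` — index probeset_id; column gene_id.
    ``homologs`` — gene_a (primary namespace), gene_b (companion namespace),
    concordant (bool).
    """

    genes: pd.DataFrame
    probesets: pd.DataFrame
    homologs: pd.DataFrame
    config: SimulationConfig = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        out = self.genes.reset_index()
        out.columns = ["gene_id"] + list(self.genes.columns)
        return out


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(stream,)))


def logistic_level(
    day: np.ndarray | float,
    base: np.ndarray | float,
    effect: np.ndarray | float,
    increasing: np.ndarray | bool,
    switch_day: float,
    steepness: float,
) -> np.ndarray:
    """Noiseless gene log2 level: logistic transition centered at switch_day."""
    s = 1.0 / (1.0 + np.exp(-steepness * (np.asarray(day, dtype=float) - switch_day)))
    up = np.asarray(increasing, dtype=float)
    return np.asarray(base, dtype=float) + np.asarray(effect, dtype=float) * (
        up * s + (1.0 - up) * (1.0 - s)
    )


def _design_frame(
    timepoints: tuple[int, ...], n_reps: int, missing_days: tuple[int, ...], prefix: str = ""
) -> pd.DataFrame:
    rows = []
    for d in timepoints:
        reps = n_reps - 1 if d in missing_days else n_reps
        for r in _REPLICATE_LABELS[:max(1, reps)]:
            rows.append((f"{prefix}d{d}{r}", d, r))
    return pd.DataFrame(rows, columns=["array_id", "day", "replicate"]).set_index("array_id")


def _gene_truth(config: SimulationConfig) -> pd.DataFrame:
    rng = _rng(config, 0)
    n = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]
    decreasing = rng.random(n) < config.frac_decreasing
    reproducible = rng.random(n) >= config.frac_nonreproducible
    base = rng.uniform(*config.base_level_log2, size=n)
    n_sets = rng.choice([1, 2, 3], size=n, p=list(config.probesets_per_gene_probs))

    tp = np.asarray(config.timepoints, dtype=float)
    early, late = tp[:2], tp[-2:]
    lvl = lambda days, inc: logistic_level(
        days[None, :], base[:, None], config.effect_size_log2, inc,
        config.switch_day, config.switch_steepness,
    )
    inc = ~decreasing[:, None]
    fc = (lvl(late, inc).mean(axis=1) - lvl(early, inc).mean(axis=1))
    fc = np.where(reproducible, fc, 0.0)  # non-reproducible genes are flat
    return pd.DataFrame(
        {
            "archetype": np.where(decreasing, "decreasing", "increasing"),
            "reproducible": reproducible,
            "base_level": base,
            "true_log2_fc": fc,
            "n_probesets": n_sets,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )


def _homolog_truth(genes: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    rng = _rng(config, 1)
    shared = np.sort(rng.choice(len(genes), size=config.shared_gene_count, replace=False))
    gene_a = genes.index.to_numpy()[shared]
    concordant = rng.random(len(gene_a)) < config.concordance_rate
    return pd.DataFrame(
        {
            "gene_a": gene_a,
            "gene_b": ["m_" + g for g in gene_a],
            "concordant": concordant,
        }
    )


def _gene_levels(
    genes: pd.DataFrame, design: pd.DataFrame, config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Noiseless-plus-replicate-structure gene log2 level per (gene, array)."""
    days = design["day"].to_numpy(dtype=float)
    base = genes["base_level"].to_numpy()
    inc = (genes["archetype"] == "increasing").to_numpy()
    levels = logistic_level(
        days[None, :], base[:, None], config.effect_size_log2, inc[:, None],
        config.switch_day, config.switch_steepness,
    )
    repro = genes["reproducible"].to_numpy()
    # non-reproducible genes: flat base plus replicate-independent temporal noise,
    # large enough that the expected replicate-profile r sits at the null (< 0.8)
    flat = np.broadcast_to(base[:, None], levels.shape).copy()
    if config.nonrepro_noise_sd_log2 > 0:
        flat = flat + rng.normal(0.0, config.nonrepro_noise_sd_log2, size=levels.shape)
    return np.where(repro[:, None], levels, flat)


def generate_timecourse(
    config: SimulationConfig,
) -> tuple[ProbeIntensityMatrix, pd.DataFrame, GroundTruth]:
    """Simulate the primary probe-level time course.

    Returns ``(probes, design, truth)``: positive linear-scale probe
    intensities, the array -> (day, replicate) design, and truth labels.
    """
    config.validate()
    genes = _gene_truth(config)
    homologs = _homolog_truth(genes, config)
    design = _design_frame(
        config.timepoints, config.replicates_per_timepoint, config.missing_replicate_days
    )
    rng = _rng(config, 2)
    levels = _gene_levels(genes, design, config, rng)

    n_sets = genes["n_probesets"].to_numpy()
    gene_of_set = np.repeat(np.arange(len(genes)), n_sets)
    probeset_ids = [
        f"{genes.index[g]}_ps{j}"
        for g in range(len(genes))
        for j in range(n_sets[g])
    ]
    k = config.probes_per_probeset
    gene_of_probe = np.repeat(gene_of_set, k)
    set_of_probe = np.repeat(np.arange(len(probeset_ids)), k)
    probe_ids = [f"{probeset_ids[s]}_p{i % k}" for i, s in zip(range(len(set_of_probe)), set_of_probe)]

    affinity = rng.normal(0.0, config.probe_affinity_sd_log2, size=len(probe_ids))
    log2_vals = levels[gene_of_probe, :] + affinity[:, None]
    if config.noise_sd_log2 > 0:
        log2_vals = log2_vals + rng.normal(0.0, config.noise_sd_log2, size=log2_vals.shape)
    intensities = np.exp2(log2_vals) * config.signal_scale
    if config.background_mean > 0 or config.background_sd > 0:
        bg = rng.normal(config.background_mean, config.background_sd, size=intensities.shape)
        intensities = intensities + np.clip(bg, 0.0, None)

    probes = ProbeIntensityMatrix(
        intensities=pd.DataFrame(
            intensities, index=pd.Index(probe_ids, name="probe_id"), columns=design.index
        ),
        probeset=pd.Series(
            np.asarray(probeset_ids)[set_of_probe],
            index=pd.Index(probe_ids, name="probe_id"),
            name="probeset_id",
        ),
    )
    probesets = pd.DataFrame(
        {"gene_id": genes.index.to_numpy()[gene_of_set]},
        index=pd.Index(probeset_ids, name="probeset_id"),
    )
    truth = GroundTruth(genes=genes, probesets=probesets, homologs=homologs, config=config)
    return probes, design, truth


def generate_companion_dataset(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate the companion (second-namespace) gene-level dataset.

    Emulates a myoblast-to-myotube comparison: arrays at
    ``companion_timepoints`` with duplicate replicates. For a homolog pair
    flagged concordant, the companion fold change shares the primary gene's
    direction with at least 2-fold (1 log2) magnitude; otherwise the direction
    is flipped. Returns ``(expression, design, homolog_map)``; expression is a
    log2 gene x array matrix in the companion namespace.
    """
    config.validate()
    if len(truth.genes) != config.n_genes:
        raise ConfigurationError(
            f"truth has {len(truth.genes)} genes but config.n_genes={config.n_genes}"
        )
    missing = set(truth.homologs["gene_a"]) - set(truth.genes.index)
    if missing:
        raise ConfigurationError(f"homolog genes absent from truth: {sorted(missing)[:5]}")

    rng = _rng(config, 3)
    pairs = truth.homologs
    n = len(pairs)
    fc_a = truth.genes.loc[pairs["gene_a"], "true_log2_fc"].to_numpy()
    sign_a = np.sign(fc_a)
    sign_a[sign_a == 0] = rng.choice([-1.0, 1.0], size=int((sign_a == 0).sum()))
    magnitude = rng.uniform(1.0, 3.0, size=n)
    concordant = pairs["concordant"].to_numpy()
    fc_b = np.where(concordant, sign_a, -sign_a) * magnitude

    design = _design_frame(config.companion_timepoints, 2, (), prefix="m_")
    days = design["day"].to_numpy(dtype=float)
    d0, dmax = days.min(), days.max()
    ramp = (days - d0) / (dmax - d0)
    base = rng.uniform(*config.base_level_log2, size=n)
    levels = base[:, None] + fc_b[:, None] * ramp[None, :]

    nonrepro = rng.random(n) < config.companion_frac_nonreproducible
    if nonrepro.any():
        flat = base[:, None] + rng.normal(0.0, config.nonrepro_noise_sd_log2, size=levels.shape)
        levels = np.where(nonrepro[:, None], flat, levels)
    if config.companion_noise_sd_log2 > 0:
        levels = levels + rng.normal(0.0, config.companion_noise_sd_log2, size=levels.shape)

    expr = pd.DataFrame(
        levels, index=pd.Index(pairs["gene_b"].to_numpy(), name="gene_id"),
        columns=design.index,
    )
    homolog_map = pairs[["gene_a", "gene_b"]].copy()
    return expr, design, homolog_map


def generate_qpcr(
    truth: GroundTruth, genes: list[str], config: SimulationConfig
) -> pd.DataFrame:
    """Simulate CT tables for ``genes`` plus the ef1a reference gene.

    Target CT = ct_intercept - gene log2 level + N(0, ct_noise); the reference
    gene sits at ``ref_ct`` with N(0, ct_ref_noise), so with zero noise the
    ddCT estimate inverts to the true log2 level difference exactly.
    """
    config.validate()
    unknown = [g for g in genes if g not in truth.genes.index]
    if unknown:
        raise ConfigurationError(f"genes absent from truth: {unknown}")
    rng = _rng(config, 4)
    rows = []
    reps = [str(i + 1) for i in range(config.qpcr_technical_replicates)]
    for day in config.timepoints:
        for rep in reps:
            ref_ct = config.ref_ct + (
                rng.normal(0.0, config.ct_ref_noise) if config.ct_ref_noise > 0 else 0.0
            )
            rows.append((REFERENCE_GENE, day, rep, ref_ct))
            for g in genes:
                row = truth.genes.loc[g]
                if row["reproducible"]:
                    level = float(
                        logistic_level(
                            day, row["base_level"], config.effect_size_log2,
                            row["archetype"] == "increasing",
                            config.switch_day, config.switch_steepness,
                        )
                    )
                else:
                    level = float(row["base_level"])
                ct = config.ct_intercept - level
                if config.ct_noise > 0:
                    ct += rng.normal(0.0, config.ct_noise)
                rows.append((g, day, rep, ct))
    return pd.DataFrame(rows, columns=["gene", "day", "replicate", "ct"])
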