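"""Generator: determinism, label proportions, and noise-free limits."""

import numpy as np
import pandas as pd
import pytest

from tempotome import (
    ConfigurationError,
    SimulationConfig,
    filter_reproducible,
    generate_companion_dataset,
    generate_qpcr,
    generate_timecourse,
    replicate_profile_correlation,
)
from tempotome.simulate import REFERENCE_GENE


def test_same_seed_bit_identical():
    config = SimulationConfig(n_genes=60, seed=42)
    p1, d1, t1 = generate_timecourse(config)
    p2, d2, t2 = generate_timecourse(config)
    pd.testing.assert_frame_equal(p1.intensities, p2.intensities)
    pd.testing.assert_frame_equal(d1, d2)
    pd.testing.assert_frame_equal(t1.genes, t2.genes)
    c1 = generate_companion_dataset(t1, config)[0]
    c2 = generate_companion_dataset(t2, config)[0]
    pd.testing.assert_frame_equal(c1, c2)
    genes = list(t1.genes.index[:2])
    pd.testing.assert_frame_equal(
        generate_qpcr(t1, genes, config), generate_qpcr(t2, genes, config)
    )


def test_different_seed_differs():
    p1 = generate_timecourse(SimulationConfig(n_genes=30, seed=1))[0]
    p2 = generate_timecourse(SimulationConfig(n_genes=30, seed=2))[0]
    # seeds alter the probe-set structure draw and/or the intensities
    assert p1.intensities.shape != p2.intensities.shape or not np.allclose(
        p1.intensities.to_numpy(), p2.intensities.to_numpy()
    )


@pytest.mark.parametrize(
    "kwargs",
    [
        {"n_genes": 0},
        {"probes_per_probeset": -1},
        {"frac_decreasing": 1.2},
        {"frac_nonreproducible": -0.1},
        {"timepoints": (0,)},
        {"timepoints": (0, 4, 2)},
        {"signal_scale": 0.0},
        {"probesets_per_gene_probs": (0.5, 0.5, 0.5)},
        {"n_shared_genes": 100, "n_genes": 50},
    ],
)
def test_invalid_config_rejected(kwargs):
    with pytest.raises(ConfigurationError):
        generate_timecourse(SimulationConfig(**kwargs))


def test_archetype_fraction_matches_binomial_draw():
    config = SimulationConfig(n_genes=5000, frac_decreasing=0.56, seed=7)
    truth = generate_timecourse(config)[2]
    frac = (truth.genes["archetype"] == "decreasing").mean()
    band = 3 * np.sqrt(0.56 * 0.44 / config.n_genes)
    assert abs(frac - 0.56) < band


def test_design_emulates_study_layout():
    config = SimulationConfig(n_genes=5, seed=0)
    _, design, _ = generate_timecourse(config)
    assert sorted(design["day"].unique()) == [0, 1, 4, 7, 10, 14]
    assert set(design["replicate"]) == {"A", "B"}
    assert "d0A" in design.index and "d14B" in design.index


def test_missing_replicate_flag_drops_arrays():
    config = SimulationConfig(n_genes=5, seed=0, missing_replicate_days=(7,))
    probes, design, _ = generate_timecourse(config)
    assert "d7B" not in design.index and "d7A" in design.index
    assert list(probes.intensities.columns) == list(design.index)


def test_zero_noise_replicates_perfectly_reproducible(zero_noise_run):
    table = replicate_profile_correlation(
        zero_noise_run.expr, zero_noise_run.design
    )
    assert np.all(table["r"] > 1 - 1e-12)


def test_effect_size_recovered_from_probe_data():
    """Per-gene late-vs-early log2 FC, computed directly from the simulated
    probe intensities, averages to the configured effect size."""
    config = SimulationConfig(
        n_genes=800, seed=5, frac_nonreproducible=0.0,
        background_mean=0.0, background_sd=0.0,
    )
    probes, design, truth = generate_timecourse(config)
    log2_probe = np.log2(probes.intensities)
    early = design.index[design["day"].isin([0, 1])]
    late = design.index[design["day"].isin([10, 14])]
    per_probe_fc = log2_probe[late].mean(axis=1) - log2_probe[early].mean(axis=1)
    gene_of_probe = truth.probesets.loc[probes.probeset, "gene_id"].to_numpy()
    gene_fc = per_probe_fc.groupby(gene_of_probe).mean()
    increasing = truth.genes.index[truth.genes["archetype"] == "increasing"]
    assert gene_fc.loc[increasing].mean() == pytest.approx(2.5, abs=0.05)
    decreasing = truth.genes.index[truth.genes["archetype"] == "decreasing"]
    assert gene_fc.loc[decreasing].mean() == pytest.approx(-2.5, abs=0.05)


def test_truth_fold_change_signs_match_archetype(study_run):
    genes = study_run.truth.genes
    repro = genes[genes["reproducible"]]
    assert (repro.loc[repro["archetype"] == "increasing", "true_log2_fc"] > 0).all()
    assert (repro.loc[repro["archetype"] == "decreasing", "true_log2_fc"] < 0).all()
    assert (genes.loc[~genes["reproducible"], "true_log2_fc"] == 0).all()


def test_homolog_map_covers_configured_count():
    config = SimulationConfig(n_genes=100, n_shared_genes=37, seed=2)
    truth = generate_timecourse(config)[2]
    _, _, homolog_map = generate_companion_dataset(truth, config)
    assert len(homolog_map) == 37
    assert homolog_map["gene_a"].is_unique and homolog_map["gene_b"].is_unique
    assert set(homolog_map["gene_a"]) <= set(truth.genes.index)


def test_companion_rejects_mismatched_truth():
    config = SimulationConfig(n_genes=50, seed=2)
    truth = generate_timecourse(config)[2]
    with pytest.raises(ConfigurationError):
        generate_companion_dataset(truth, config.replace(n_genes=60))


def test_qpcr_reference_constant_and_rejects_unknown_gene():
    config = SimulationConfig(n_genes=20, seed=2, ct_noise=0.0, ct_ref_noise=0.0)
    truth = generate_timecourse(config)[2]
    ct = generate_qpcr(truth, [truth.genes.index[0]], config)
    ref = ct[ct["gene"] == REFERENCE_GENE]
    assert ref["ct"].nunique() == 1
    with pytest.raises(ConfigurationError):
        generate_qpcr(truth, ["not_a_gene"], config)


def test_roughly_half_survive_filter_at_defaults(study_run):
    """The reproducible/non-reproducible mixture is targeted so about half of
    the probe sets pass the r > 0.8 filter."""
    table = filter_reproducible(
        replicate_profile_correlation(
            study_run.expr, study_run.design, study_run.truth.probesets["gene_id"]
        )
    )
    assert 0.4 < table["retained"].mean() < 0.6
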