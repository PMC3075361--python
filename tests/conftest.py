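import logging
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from tempotome import SimulationConfig, TimeCourseModel, generate_timecourse, rma

logging.getLogger("tempotome").setLevel(logging.ERROR)


def make_design(days=(0, 1, 4, 7, 10, 14), reps=("A", "B")):
    rows = [(f"d{d}{r}", d, r) for d in days for r in reps]
    return pd.DataFrame(rows, columns=["array_id", "day", "replicate"]).set_index("array_id")


def expr_from_day_values(day_values: dict, days=(0, 1, 4, 7, 10, 14), reps=("A", "B")):
    """Build a log2 expression matrix from gene -> per-day values (both reps equal)."""
    design = make_design(days, reps)
    data = {
        a: [day_values[g][days.index(design.loc[a, "day"])] for g in day_values]
        for a in design.index
    }
    expr = pd.DataFrame(data, index=list(day_values))
    return expr, design


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def study_run():
    """One full-scale run at the study-design defaults (seed 0).

    5000 genes, effect 2.5 log2, probe noise 0.4 log2, 56% decreasing,
    half the genes non-reproducible; RMA chain plus the fitted time-course
    model. Shared across the calibration and recovery tests.
    """
    config = SimulationConfig(seed=0)
    probes, design, truth = generate_timecourse(config)
    expr = rma(probes)
    ps2gene = truth.probesets["gene_id"]
    results = TimeCourseModel(expr, design, ps2gene).fit()
    return SimpleNamespace(
        config=config, probes=probes, design=design, truth=truth,
        expr=expr, results=results,
    )


@pytest.fixture(scope="session")
def zero_noise_run():
    """Noise-free, background-free, all-reproducible dataset plus RMA output."""
    config = SimulationConfig(
        n_genes=200, seed=3, noise_sd_log2=0.0, frac_nonreproducible=0.0,
        background_mean=0.0, background_sd=0.0,
    )
    probes, design, truth = generate_timecourse(config)
    expr = rma(probes, bgcorrect=False)
    return SimpleNamespace(config=config, probes=probes, design=design, truth=truth, expr=expr)
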