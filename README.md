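# tempotome

Analysis pipeline for **replicated time-course microarray experiments**, built
around the design used to profile the in-vitro differentiation of adult
zebrafish myogenic progenitor cells: expression measured at days 0, 1, 4, 7,
10 and 14 with duplicate biological measurements (A, B) at each time point,
compared against a mouse C2C12 myoblast-to-myotube dataset and validated by
qPCR. The package is aimed at anyone re-analysing this class of Affymetrix
time-course data — or testing such an analysis end to end on synthetic data
with known ground truth.

## What it computes

1. **RMA preprocessing.** Probe intensities are modelled as
   `O = S + B`, `S ~ Exp(α)` (true signal), `B ~ N(μ, σ²)` (optical
   background); the corrected value is the posterior mean `E[S | O]`. Arrays
   are then quantile-normalized to a common distribution, and each probe set
   is summarized by Tukey median polish of the additive model
   `log2 x_ij ≈ m + probe_i + array_j`, giving log2 expression signals.
2. **Reproducibility filter.** For each probe set, the Pearson correlation
   `r` between the *unlogged* (2^signal) day-ordered profiles of replicates
   A and B; probe sets with `r > 0.8` (strict) are retained, and a gene with
   several probe sets is represented by the one with maximal `r`.
3. **Temporal patterns.** Day-mean profiles are z-scored per gene and
   decomposed by PCA (genes as observations). The sign of the PC1 score
   splits genes into the two large-scale archetypes — *decreasing* (high at
   days 0–1, falling) and *increasing* — with an orientation anchor that
   makes the labelling deterministic; the two average pattern profiles cross
   at the switch day.
4. **Contrasts.** log2 FC = mean signal(days 10–14) − mean signal(days 0–1)
   (the signals are log2, so the difference is the log2 fold change), plus a
   day-4-vs-rest differential test (pooled t, Benjamini–Hochberg FDR).
5. **Cross-dataset concordance.** Fold changes joined over a homolog map;
   among pairs reproducible in both datasets (`r > 0.8` each) and ≥2-fold
   changed in both (`|log2 FC| ≥ 1`), a 2×2 table of directions is tested
   with the two-sided Fisher exact test.
6. **qPCR validation.** ΔΔCT: `ΔCT = CT(target) − CT(ef1a)` per
   (day, replicate); `log2 FC(day N) = mean ΔCT(day 0) − mean ΔCT(day N)`,
   compared per gene against the microarray fold changes.

A synthetic-data generator (`tempotome.simulate`) emulates the full study
design — temporal archetypes switching at day 4, a reproducible /
non-reproducible probe-set mixture, multiple probe sets per gene, a paired
companion dataset with tunable concordance, and CT tables with a stable
reference gene — so every stage is testable against known truth without any
downloads.

## Worked example

```python
import pandas as pd
import tempotome as tt

config = tt.SimulationConfig(n_genes=500, seed=1)
probes, design, truth = tt.generate_timecourse(config)

expr = tt.rma(probes)                               # probe-set x array, log2
model = tt.TimeCourseModel(expr, design, truth.probesets["gene_id"])
results = model.fit()
print(results.summary())
```

```
Time-course expression analysis
===============================================
probe sets scored:        729
retained (r > 0.8):       401
unique genes:             269
classified genes:         269
  decreasing pattern:     161 (59.9%)
  increasing pattern:     108 (40.1%)
PC1/PC2 variance:         0.935 / 0.031
pattern crossing day:     4
log2 FC days (10, 14) vs (0, 1): median -0.74
day-4 contrast (FDR 0.05): 0 up, 0 down
```

About half of the 729 simulated probe sets pass the replicate-correlation
filter (the generator's default mixes reproducible and non-reproducible
probe sets in equal parts), PC1 carries ~94% of the profile variance, the
two temporal archetypes split roughly 60/40 at this small n, and their
average profiles cross at day 4 — the switch day built into the simulation.

Concordance against the paired companion dataset:

```python
comp_expr, comp_design, homologs = tt.generate_companion_dataset(truth, config)
table = tt.filter_reproducible(tt.replicate_profile_correlation(comp_expr, comp_design))
fc_b = tt.fold_change_late_vs_early(comp_expr, comp_design, (0,), (4,))
r_b = pd.Series(table["r"].to_numpy(), index=table.index)
conc = tt.CrossDatasetConcordance(
    results.fold_changes, results.gene_reproducibility, fc_b, r_b, homologs
).fit()
print(conc.summary())
```

```
Direction concordance (rows: dataset 1, cols: dataset 2)
            up    down
  up        41       4
  down      7      59
  pairs >= 2-fold in both: 111
  odds ratio: 86.39
  Fisher exact P (two-sided): 1.638e-18
```

With the generator's default 90% concordance rate, 100 of the 111
twofold-changed homolog pairs fall on the diagonal and the association is
overwhelming.

The same stages are available from the shell:

```sh
tempotome all --workdir run --seed 1 --n-genes 500
```

which writes every stage's TSV plus `manifest.json` with SHA-256 hashes
(a rerun with the same seed reproduces the hashes bit for bit).

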