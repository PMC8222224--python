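# icbnotch

Immunogenomic analysis of clinical benefit from immune checkpoint
blockade (ICB) in relapsed small cell lung cancer (SCLC), packaged as a
tested, reusable pipeline. It is aimed at translational researchers who
have bulk RNA-seq counts, clinical benefit labels, T-cell receptor (TCR)
clonotype tables and/or digital spatial profiling (DSP) / IHC readouts
for an ICB-treated cohort, and want to quantify Notch signaling,
neuroendocrine (NE) differentiation and immune activity and relate them
to benefit.

## What it computes

**Signature scores.** Single-sample gene-set enrichment (ssGSEA): per
sample, genes are ranked by expression (descending, lexicographic
tie-break) and given rank values N..1; with in-set weights
w_g = r_g^α (α = 0.25),

    ES(G) = Σ_i [ P_in(i) − P_out(i) ],
    P_in(i) = Σ_{g∈G, pos≤i} r_g^α / Σ_{g∈G} r_g^α,
    P_out(i) = #{g∉G, pos≤i} / (N − |G|).

The NE score is ES(NE-high) − ES(NE-low) over two opposing
neuroendocrine signatures; higher = more neuroendocrine.

**Normalization.** Trimmed-mean-of-M-values (TMM) composition factors
(30% M-trim, 5% A-trim, inverse-asymptotic-variance weights, factors
rescaled to geometric mean 1), CPM/RPKM, per-gene z-scores, and
cross-cohort combination by per-dataset z-scores of log2 values.

**Classification.** Notch-high status (score strictly above the
within-dataset 75th percentile), transcriptional subtype (arg-max of
within-dataset z-scored ASCL1 / NEUROD1 / POU2F3 / YAP1), and NE vs
low-NE grouping (two-group cut of a complete-linkage Euclidean
dendrogram over NE scores).

**Benefit statistics.** Two-tailed Mann-Whitney U (exact for n ≤ 20
without ties), Pearson chi-squared and two-sided Fisher exact tests on
2×2 benefit tables, Pearson correlation, and a multivariable logistic
model of benefit on z-scored Notch / immune / NE / MYC / EZH2
covariates with Benjamini-Hochberg FDR.

**TCR repertoire.** Richness, Shannon entropy, clonality
(1 − H/ln richness), Jensen-Shannon divergence (base 2, in [0, 1]),
clone expansion calls (frequency fold change > 3 with a 10-read floor
on treatment), persistently expanded clones (expanded in ≥ 80% of
on-treatment draws) and their overlap with tumor repertoires.

**DSP / IHC.** Per-protein ROI normalization by the mean of per-patient
median ROI values (negative-control and non-tumor ROIs excluded);
H-score = 1·(%1+) + 2·(%2+) + 3·(%3+); cleaved-NOTCH1 positivity at
≥ 5% positive cells.

**Synthetic cohorts.** Seeded generators produce every input with the
structure the analysis assumes — anti-correlated NE/Notch/immune
latents, benefit driven by the Notch latent, negative-binomial counts,
Zipf repertoires with planted responder expansions — plus truth
sidecars, so the whole pipeline is testable without any data download.

## Worked example

```python
from icbnotch.synthetic import SyntheticCohortConfig, simulate_expression_cohort
from icbnotch.workflows import fit_benefit_model_on_cohort, label_cohort

cohort = simulate_expression_cohort(SyntheticCohortConfig(n_samples=60, seed=1))
result = fit_benefit_model_on_cohort(cohort)   # counts -> TMM/CPM -> scores -> logit
print(result.table.round(4))
```

```
           estimate  statistic       p     fdr
covariate
Notch        1.2397     2.5937  0.0095  0.0475
Immune       0.4985     1.1618  0.2453  0.6133
NE          -0.1402    -0.2922  0.7701  0.7701
MYC          0.1714     0.5482  0.5835  0.7701
EZH2        -0.1727    -0.4947  0.6208  0.7701
```

The cohort was simulated with a Notch→benefit log-odds of 1.5 per
latent SD and no direct effect of the other covariates; the fitted
model recovers exactly that: the Notch signature has a positive per-SD
estimate (1.24), the smallest p (0.0095) and the only FDR below 0.05,
while immune, NE score, MYC and EZH2 stay non-significant.

```python
labels = label_cohort(cohort.expression, cohort.gene_sets)
print(labels.head(4))
```

```
      notch_high subtype ne_group
S000       False   ASCL1       NE
S001       False   ASCL1       NE
S002       False  POU2F3       NE
S003       False   ASCL1    lowNE
```

A command-line interface mirrors the library
(`icbnotch simulate|validate|normalize|score|classify|associate|test2x2|tcr|dsp|ihc`).

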