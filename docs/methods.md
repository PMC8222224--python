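# Methods

## Scope and model

The package operationalizes a cohort-level immunogenomic analysis of
checkpoint-blockade benefit in relapsed SCLC. Its quantitative core is
(i) rank-based single-sample enrichment scoring of Notch, immune,
antigen-presentation and neuroendocrine gene signatures, (ii)
categorical labeling of tumors (Notch-high, transcriptional subtype,
NE group), (iii) association statistics between those quantities and a
binary clinical-benefit label, and (iv) longitudinal T-cell-repertoire
and spatial-proteomic/IHC quantification. Every stage is exercised
end-to-end on seeded synthetic cohorts, so the test suite establishes
algorithmic correctness and statistical calibration without any
external data.

## ssGSEA

The enrichment score of gene set G in one sample is the summed
difference between a rank-weighted in-set ECDF and the uniform
out-of-set ECDF over the expression-ranked gene list (weights
rank^alpha, alpha = 0.25, the conventional default of the original
formulation). Ties in expression are broken by lexicographic gene id,
which makes scores platform-independent and exactly reproducible; this
matters for count data where ties are common. Scores are invariant to
any strictly monotone per-sample transform, so CPM, log-CPM or z-score
inputs give identical values. Sets are required to overlap the matrix
in at least `min_genes = 3` genes (configurable down to 1 for degenerate
demonstrations) and must not cover the whole matrix. Optional
range-normalization divides the whole score table by its global
max − min. The NE score is the difference of two opposing signatures,
ES(NE-high) − ES(NE-low); the difference form uses both directions of
the published neuroendocrine signature and makes the score antisymmetric
under swapping the two sets. A single-set NE score is available by
calling `ssgsea_score` directly.

## TMM / CPM / cross-cohort combination

TMM follows the standard reference algorithm exactly: reference sample
chosen by upper-quartile closeness to the mean upper quartile; M and A
computed on genes expressed in both samples; double trimming (30% on M,
5% on A, rank-based with average ties); inverse-asymptotic-variance
weighting; factors rescaled to geometric mean 1. The implementation
reproduces the published reference implementation's factors to ~3e-13
on a frozen composition-biased toy matrix. One numerical subtlety: with
the variance weights, factors are invariant to a pure depth rescaling
of a sample only to ~0.1%, because the weights depend on absolute
counts; the unweighted trimmed mean is exactly invariant, and a test
pins both behaviors.

Cross-cohort combination log2(x+1)-transforms each dataset, z-scores
each gene within its dataset (sample SD, n−1), and concatenates over
the gene intersection. The +1 offset handles zeros; the per-dataset
z-scoring removes platform location and scale so rank-based scores and
quantile thresholds are comparable across cohorts. The per-gene z-score
convention is sample SD (n−1) throughout the normalization module, so
the hand-checkable identity row (1,2,3) → (−1,0,1) holds exactly.

## Classification rules

Notch-high = strictly above the within-dataset 75th percentile
(linear-interpolation quantile). Strict inequality means an all-equal
dataset flags nobody, and at most ⌈n/4⌉ samples are flagged. Subtype =
arg-max of the within-dataset z-scored expression of ASCL1, NEUROD1,
POU2F3, YAP1, with exact ties resolved in that fixed priority order —
a deterministic reduction of the heatmap-based practice. NE grouping
cuts a complete-linkage Euclidean dendrogram over the 1-D NE scores at
k = 2 (scores are sorted before linkage so the assignment cannot depend
on input order); the lower-mean cluster is "lowNE". Seeded 1-D k-means
is available as an alternative. At 4σ separation between the two score
modes, aggregate recovery measures ~96%, close to the Bayes-optimal
97.7% for equal-prior Gaussians at that separation — no clustering rule
can do better than the Bayes rate, which is why the recovery assertion
sits at 95%.

## Benefit statistics

Mann-Whitney U is exact for combined n ≤ 20 without ties, otherwise
normal approximation with tie (and continuity) correction; the
switchover is fixed and documented so p-values are reproducible. The
2×2 tests are Pearson chi-squared (1 df, Yates only on request) and the
two-sided Fisher exact test under the probability-mass rule (sum of
tables no more probable than observed) — the rule that reproduces the
published positivity p-value of 0.09 and the POU2F3 row's 0.17. The
multivariable benefit model is logistic regression of CB/NCB on five
covariates (Notch, immune, NE, MYC, EZH2), z-scored across the cohort
before fitting so estimates are per-SD effects; standardization uses
the population SD so duplicating every sample leaves estimates exactly
unchanged. Wald z statistics and two-sided p-values are reported, with
Benjamini-Hochberg FDR across the five covariate p-values. An OLS
(linear probability) family is provided because reported "t values" are
ambiguous for a logistic fit. Perfect separation or non-convergence is
returned as a flagged result with NaN p-values rather than an
exception. BH-adjusted values are step-up, monotone, and never below
the raw p by construction.

## TCR repertoire

Clonality uses natural-log Shannon entropy, 1 − H/ln(richness) (the
base cancels in the ratio); a single-clone repertoire is defined as
clonality 1 by continuity. JSD uses base-2 entropies over the union of
clonotype keys so the index lies in [0, 1] with 1 for disjoint
repertoires. Expansion calls attach the 10-read floor to the
on-treatment sample (an expansion claim needs support where the clone
is claimed large; "either sample" is available) and compute the
fold change on frequencies rather than counts so depth differences
between draws cancel; clones absent pre-treatment are infinitely
expanded once they pass the floor, avoiding an arbitrary pseudocount.
Persistence uses ≥ (so 4 of 5 on-treatment draws passes the 0.8
threshold), and blood-tumor overlap is the fraction of a clone set with
nonzero tumor count. Optional seeded multinomial rarefaction supports
depth-fair richness comparisons; it is off by default because it
discards data.

## DSP and IHC

DSP normalization divides each eligible ROI value by the per-protein
mean of per-patient median ROI values, after excluding negative-control
and non-tumor-annotated ROIs; medians of even ROI counts are the mean
of the two central values. The construction forces the mean of
per-patient medians to exactly 1 per protein and is idempotent — both
are asserted. All of a patient's eligible ROIs are pooled regardless of
source sample; patients with no eligible ROI for a protein are dropped
from that protein's mean with a warning. H-score is the linear
intensity-bin combination bounded by [0, 300]; cleaved-NOTCH1
positivity is inclusive at 5% positive cells.

## Synthetic cohorts: what they emulate, and what not

The expression generator draws a standard-normal NE latent per sample;
the Notch and immune latents are each correlated −0.6 with it
(matching the sign and approximate magnitude of the inverse
NE-vs-Notch/immune relationships the analysis assumes); MYC and EZH2
latents are independent. Signature genes load on their latent with a
log2 fold change of 1 per latent SD around lognormal baselines
(median ~50 counts); counts are negative binomial with dispersion 0.3
— typical bulk RNA-seq overdispersion, and enough noise that recovery
is non-trivial. Benefit is Bernoulli with log-odds 1.5 × Notch latent;
under the null configuration the latent coefficient is 0. Lineage TFs
follow a planted subtype per sample with a 4-noise-SD shift, reflecting
the near-exclusive expression of these factors in real tumors; the
arg-max subtype call then recovers ~97% of planted labels (an arg-max
over four genes at only 2σ separation would cap near 80%, regardless of
implementation). Defaults are n = 60 samples × 1000 genes, which keeps
the 120-cohort recovery/null suite under two minutes on one CPU.

The repertoire generator uses a Zipf(1) clone distribution over 2000
clones sampled multinomially at 10^5 templates, 10-fold expansion of 50
random clones in responders, and a tumor repertoire containing 11% of
the expanded clones plus ~500 background clones.

Not emulated: gene-length effects (scores are rank-based, so RPKM vs
CPM is immaterial), batch structure beyond per-dataset location/scale,
clonal interference or timepoint autocorrelation in repertoires,
spatial correlation between DSP ROIs, and any real patient's values.
Passing recovery tests therefore demonstrates that the estimators
recover their own generative quantities under realistic noise — not
that real cohorts carry those effect sizes.

## Numerical choices and edge cases

- Quantiles: linear interpolation between order statistics everywhere.
- Constant gene rows z-score to zeros with a warning, not NaN.
- Frequencies are recomputed from counts on clonotype read so collapsed
  amino-acid keys stay consistent; on-disk frequency columns are
  ignored.
- All tabular I/O is TSV, UTF-8, "." decimal, `%.12g` floats: write →
  read round-trips are exact to 1e-12 and byte-deterministic.
- Every stochastic routine takes an explicit seed; generators are pure
  functions of their config.

## Known limitations

Real-data headline quantities (published cohort correlations,
multivariable coefficients, clonotype expansion ranges) require the
controlled-access deposits and are out of scope. The subtype call is a
deterministic arg-max reduction, not a reproduction of any particular
cohort's curated labels. The logistic model does not collapse multiple
tumors per patient by default (a per-patient mean collapse is a
one-line groupby on the covariate table). Richness comparisons without
rarefaction remain depth-confounded.
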