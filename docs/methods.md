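# Methods

This note records the models, estimators, defaults and numerical choices
behind `embryovar`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Data model

The unit of analysis is a genes × cells matrix of non-negative RPKM-like
values with two nested per-cell factors: developmental **stage** (ordered;
default `4-cell, 8-cell, morula, blastocyst`) and **embryo** of origin.
Each embryo belongs to exactly one stage; embryos are treated as biological
replicates of their stage. Matrices are stored genes × cells in double
precision regardless of on-disk layout, because every statistic is
per-gene. Stage order comes from a user-supplied list, never a lexical
sort.

All variability statistics are computed on `log2(RPKM + 1)` by default.
The raw-scale path is fully supported (`--transform raw`): on raw RPKM the
SD is dominated by the handful of highest expressors, which makes per-gene
variability comparisons nearly meaningless in practice, so the log scale is
the default and the transform tag is recorded in every output.

## Quality filter

A gene is retained when the fraction of cells with expression ≥ 0.1 RPKM is
≥ 0.75 within *every* stage (`scope=all_stages`, default) or within at
least one stage (`any_stage`). Both comparisons are closed inequalities
and fractions are compared exactly (3 of 4 cells passes 0.75). The
conjunctive default reflects that all downstream tests compare the same
gene across all stages, which requires per-stage validity everywhere. The
per-chromosome distribution check (median log2 expression per cell and
chromosome, z-scored across cells, default flag at |z| > 3) is advisory
only and never drops data.

## Variability statistics

With E embryos at a stage and embryo j contributing N_j cells:

* per-embryo SD: population form, divisor N_j (no Bessel correction);
* SDC: unweighted mean of the per-embryo SDs — every embryo counts equally
  regardless of its cell count (1/E prefactor);
* SDE: population SD (divisor E) of the per-embryo SDs around the SDC;
  undefined (NaN, never silent) for single-embryo stages;
* CV: per-embryo SD / per-embryo mean averaged over embryos (default,
  the structural analogue of the SDC), or pooled stage SD / stage mean
  (`mode="pooled"`). Any required zero mean yields an explicit undefined
  marker.

Population divisors mean the SDC is a mildly biased estimator of the
cell-level noise SD (E[SD] < σ at small N); the bias is uniform across
genes of the same design and cancels from all comparisons the pipeline
makes. The test suite checks convergence of SDC to the generating σ within
5% at 1,000 cells per embryo.

## Statistical tests

Levene's test is the one-way fixed-effects F test applied to absolute
deviations from the group centre; `center="mean"` (Levene's original form,
the default) or `"median"` (Brown–Forsythe). Groups are stages;
observations are individual cells pooled across a stage's embryos — the
only grouping that gives every stage ≥ 2 observations in small designs.
P-values are adjusted with Benjamini–Hochberg step-up across all tested
genes; the centring and adjustment are recorded in outputs.

**Calibration caveat.** At study-like sample sizes (k = 4 stages of 8
cells) the mean-centred Levene test is measurably liberal: 10,000-run null
simulations give a type-I rate of ≈ 0.070 at nominal 0.05 (scipy's
implementation agrees to 1e-12), while the median-centred variant is
conservative at ≈ 0.030. This is an inherent small-sample property of the
test, not an implementation artefact; `scripts/acceptance.py` reports both
rates. Users wanting strict type-I control at small n should prefer the
median variant and interpret marginal p-values cautiously.

The Fisher exact test computes the two-sided p by summing hypergeometric
probabilities of all tables (margins fixed) no more probable than the
observed one, with a 1e-7 relative slack so floating-point ties are
included; the odds ratio reported is the sample estimate ad/bc (infinite
when bc = 0, undefined for 0/0), and enrichment vs depletion is read off
OR ≷ 1. Fisher calibration is checked by simulation: random catalogues
reject at ≈ 4.6% at nominal 5% (slightly conservative, as expected for a
discrete exact test).

## Mixture modelling

1-D Gaussian mixtures are fit by EM. Initial means are data quantiles plus
seeded Gaussian jitter (0.25 SD); ten restarts run a 40-iteration
vectorised burn-in and the best restart is polished to convergence
(relative log-likelihood change < 1e-8, cap 500 iterations). Component
variances are floored at 1e-6 · var(x). BIC = −2·loglik + p·log n with
p = (K−1) + K + (1 or K) for the equal-/free-variance family. `select_k`
fits K = 1..9 in both families by default and returns the minimum-BIC fit,
ties broken toward smaller K; the chosen family, seed and restart count are
serialised with every fit. Mode/state boundaries between adjacent
components are the points of equal posterior probability, found by root
bisection between the component means (falling back to the midpoint if the
weighted densities do not cross there).

Hierarchical clustering (stable-gene grouping) is standard agglomerative
linkage — complete linkage, Euclidean distance by default — cut at k
clusters, via scipy.

## Stable genes, expression modes, markers, control states

* Stable genes: Levene BH-adjusted p > 0.05 (strictly greater, so
  "non-significant" is exact) → per-stage SDC profiles clustered into
  k = 3 groups → the cluster with lowest mean SDC. Hierarchical clustering
  is the primary method; a mixture-model variant on the per-gene mean SDC
  is available behind a flag, and outputs record which was used.
* Expression modes: per stage, a 3-component mixture on stage-mean log
  expression of the stable genes, components labelled low/medium/high by
  ascending mean; a degenerate stage-mean distribution falls back to
  BIC-selected K with a warning. Mode-overlap summaries report both
  plausible denominators (genes with the mode in ≥ 1 stage; mean per-stage
  count), since either normalisation is defensible.
* Markers of stage X: SDC strictly minimal at X, stage mean strictly
  maximal at X, and adjusted Levene p < 0.05. Exact ties disqualify
  (deterministic; ties are measure-zero on real data). The Levene family
  is the same transcriptome-wide BH family used for stable genes. The
  ANOVA cross-comparison BH-adjusts over the marker set only, matching the
  question "of the markers found, which would a mean-based screen flag?".
* Control states: `select_k` (K = 1..9) on a stage's per-gene SDC vector;
  states numbered 1 (lowest variability) upward.

## Subsampling heterogeneity

All C(n, r) combinations of r cells (default r = 4) are enumerated per
stage, cells pooled across embryos (per-embryo enumeration available).
Each combination's profile is the Gaussian KDE (Silverman bandwidth) of the
per-gene population SDs across the selected cells, evaluated on a shared
512-point grid spanning [0, 1.1 · max SD]; kernel mass below zero is
reflected and the density renormalised to exactly unit mass on the grid.
Profile diversity is the matrix of pairwise L1 distances (trapezoid rule);
the **heterogeneity index** is the mean pairwise L1 distance, and a
single-linkage cut gives a descriptive grouping of combinations — no
formal test is attached. For stages where C(n, r) exceeds a cap (default
50,000) a seeded uniform subsample of combinations is profiled.

## Synthetic data

The generator emulates the replication design the analysis assumes:
log2-scale expression `mu_gs + b_gj + eps` with embryo random effect
`b_gj ~ N(0, 0.15²)` and cell noise `eps ~ N(0, sigma_gs²)`, back-transformed
to an RPKM-like scale (2^v − 1, floored at 0). The default design is 4
stages, (3, 3, 2, 3) embryos, (4, 8, 8, 10) cells per embryo; ~8,000 genes.
Planted classes partition the genes:

* stable genes (12%): constant σ = 0.3 across stages; low/medium/high
  expression modes at log-means 0.5/4/9 (proportions 0.30/0.55/0.15);
* markers (10 per stage): a stage-varying baseline σ ~ U(0.8, 1.6) — as for
  any real gene — with the marker stage at 0.5 × the minimum of the other
  stages and its log-mean at 2 × the maximum of the others;
* variability-state genes (background): per-stage σ drawn from
  stage-specific mixtures of 4/3/3/2 components whose lowest component
  (σ ≈ 0.3) is shared with the stable class and whose upper tail widens
  over development;
* zero-inflated genes (5%): low expression (log-mean 1.5) with per-cell
  Bernoulli dropout at p = 0.3.

Stage means of background genes are positively coupled to their stage
sigmas (2 log2 units per σ unit): a gene upregulated at a stage is also
more variable there, reflecting noisy transcriptional activation. This
coupling is what makes the marker pattern (high mean *with* low
variability at the same stage) rare among non-markers, as it is in real
data; with independent means, a quarter of all differentially variable
genes would mimic markers by coincidence.

What the generator does **not** model: read counts and RPKM normalisation
mechanics, depth-dependent dropout curves, gene–gene correlation, and
non-Gaussian noise. Passing recovery tests therefore demonstrate that the
pipeline's inference is correct under its own assumptions at realistic
sample sizes — not that those assumptions hold for any particular real
dataset.

Two findings from the generator are worth flagging as limitations of the
method itself: (i) zero-inflated genes mimic markers, because dropout
simultaneously lowers the mean and raises the SD, so stages with fewer
dropouts look both higher-expressed and more precise — marker lists from
dropout-prone data should be screened for expression level; (ii) with only
12 cells at a stage (3 embryos × 4 cells), SDC sampling noise makes marker
detection at that stage unreliable in both directions, which is consistent
with variability markers being reported only for the better-sampled stages
in this kind of design.

## Problem sizes and reproducibility

Recovery simulations run at deliberately desk-scale sizes, chosen once:
1,000 genes for the stable-gene (300 stable + 700 shift), marker and
control-state configurations, with 8 cells per embryo (8/8/8/10 for
control states) — inside the study's 4–10-cell band; 1,500 genes for the
SD-vs-CV benchmark; 500 genes × 12 cells for the heterogeneity pair; 10
seeds per quantity. The control-state recovery summary is the median
selected K over seeds: at several thousand genes BIC begins to resolve the
chi-distribution skew of SD estimates and occasionally splits the widest
planted component, so the median is the stable summary of what the
procedure recovers. All randomness flows from one master seed through a
documented splitting scheme; repeated runs are bit-identical.

## SD-vs-CV benchmark

Genes are planted at three cell-level noise SDs (0.2/0.8/1.6) at a common
log-mean of 6; under zero-inflation, a third of genes are low-expression
(log-mean 2) with dropout probability 0.3. Each statistic (SDC, CV) is
clustered by BIC-selected mixtures (K ≤ 5) and scored by adjusted Rand
index against the planted levels; genes with undefined CV form their own
predicted cluster. Without zero-inflation both statistics recover the
three levels (ARI > 0.9); with it, the CV conflates low expression with
high variability and its ARI falls below the SDC's (means ≈ 0.46 vs 0.55
over 10 seeds).
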