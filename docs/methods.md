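# Methods

This note documents the statistical procedures implemented in `tocopls`,
the assumptions behind the synthetic cohort generator, the numerical
choices that matter, and the limitations of what the test battery can and
cannot show.

## Phenotype model and replicate processing

The phenotype is the adipose-tissue α-tocopherol concentration of one
participant, in nmol/g protein. Measurements arrive as 2–6 technical
replicates laid out on a meal × time grid (three test meals; fasting and
8 h post-meal). Adipose α-TOC turns over on a scale of weeks to years, so
neither the meal nor the 8-hour window is expected to shift it; the
package verifies this with two-sided paired *t* contrasts (per meal,
fasting vs 8 h; per meal pair at matched time) and then treats the
replicates as exchangeable. A full linear mixed model with AIC-selected
covariance structure would test the same thing; it is deliberately not
re-implemented because the downstream pipeline only consumes the
"no effect → average the replicates" conclusion.

Each participant's replicate set is screened once with a two-tailed Grubbs
test (G = max|xᵢ − x̄|/s against
G_crit = ((n−1)/√n)·√(t²/(n−2+t²)), t the upper α/(2n) Student quantile on
n−2 df), removing at most one outlier — the single-outlier variant, since
replicate sets have at most six values. Sets smaller than three skip the
screen; a set reduced below two values is flagged low-confidence but still
averaged.

Dispersion is summarized as percent CV (100·SD/mean, sample SD). Equality
of two CVs is tested with Forkman's F-statistic based on McKay's
approximation,
F = [ĉ₁²/(1+ĉ₁²(n₁−1)/n₁)] / [ĉ₂²/(1+ĉ₂²(n₂−1)/n₂)] on (n₁−1, n₂−1) df,
two-sided. The test assumes independent samples; applying it to plasma and
adipose values from the same participants (as the source analysis did) is
a statistical caveat, not corrected here. McKay's approximation is
accurate for CVs below roughly 0.7 — adequate for the 0.25–0.61 range this
package targets.

Pearson correlations are reported with Fisher-z 95% CIs
(z ± z_{α/2}/√(n−3), back-transformed) and a t test on n−2 df. The
covariate screen retains a covariate exactly when its CI excludes zero;
at n = 42 this is mildly liberal (measured ≈ 6% inclusion under the null).

## Genotype QC

Dosages count minor alleles (0/1/2, NA missing). The cascade runs
call-rate ≥ 0.95 → HWE → tag-SNP selection → perfect-pair dedup, in that
order (the source does not state whether call rate and HWE were applied
jointly; call-rate-first is the package's choice). The HWE test is the
plain Pearson χ² with 1 df, no continuity correction, with the allele
frequency estimated from the counts; monomorphic SNPs are flagged, not
excluded. LD is the squared Pearson correlation of dosages on
pairwise-complete observations ("composite" genotype correlation), computed
from the cohort itself rather than an external reference panel — a
documented divergence that keeps the pipeline self-contained. Tag
selection is greedy most-connected-first (Carlson-style) within gene
groups, ties broken by input order; perfect-pair dedup keeps one seeded-
random survivor per r² = 1 component. Surviving column order always
preserves input order, and re-running the cascade on its own output
excludes nothing.

## Univariate screen

Each SNP is tested under additive and dominant codings by simple least
squares with a Wald statistic B/SE referred to Student's t on n−2 df — the
conservative small-sample reading of an asymptotic Wald test at n = 42. A
coding is only tested when each of its genotype classes holds ≥ 5
observations (all three dosage classes for additive; both collapsed
classes for dominant) — which makes the additive model systematically the
more restrictive one. The screen runs on the unadjusted phenotype;
covariates enter the multivariate step as predictors instead. Note that
with the ≥5-per-class rule active, the additive coding requires dosage-2
carriers, so retained additive and dominant codings of one SNP are never
identical vectors; the additive-preference dedup rule exists for smaller
`min_group` settings.

## PLS engine

PLS1 is implemented from scratch by NIPALS on autoscaled data (all
variables, including the response, scaled to mean 0, SD 1 with the n−1
denominator; whether the source software also scaled y is unstated — this
package does, and reports coefficients back-transformed to phenotype
units, where the choice cancels). Missing predictor values are mean-imputed
after QC, before scaling. Standardized coefficients are reconstructed as
b = W(PᵀW)⁻¹q; back-transformation uses bⱼ·sd_y/sd_{xj} with intercept
ȳ − Σbⱼx̄ⱼ, and the two prediction pathways agree to 1e−10. Full-component
PLS reproduces ordinary least squares to ≤ 1e−8 relative error (tested
against the normal equations on 200 random instances, and against
scikit-learn's PLSRegression during development).

VIP_j = √(p·Σₐ sₐ(w_{ja}/‖wₐ‖)² / Σₐ sₐ) with sₐ = qₐ²·tₐᵀtₐ; mean squared
VIP is 1 by construction.

Cross-validation uses venetian-blind folds (position mod K after a seeded
shuffle, K = 7 by default); fold models are recentred on their training
rows. Q² = 1 − PRESS/SS_y. The component count is grown while one more
component improves cumulative Q² by more than 0.01 (a tunable), with at
least one component always kept.

## Model selection

The sweep refits the model along an increasing VIP-threshold grid
(default 0.8 to 1.5 in steps of 0.05, a choice — the source says only
"increasing VIP threshold values"). VIPs are re-ranked after every refit
(dynamic mode, switchable to static filtering on the full model's VIPs);
retained sets are therefore nested. Entries with n − k − 1 < 1 carry no
adjusted R² (the statistic is undefined; such fits are positively biased)
and cannot be selected. Among entries with CV-ANOVA p < 0.05 the maximal
adjusted R² wins, ties toward fewer variables. Finally, selected SNPs in
mutual LD (r² > 0.80; connected components) are pruned to the highest-VIP
member (ties by entry order), the model is refitted and CV-ANOVA is
re-verified — a model losing significance after pruning is reported as
such.

## Validation battery

* **CV-ANOVA**: F = [(SS_y − PRESS)/A] / [PRESS/(n − A − 1)] on
  F(A, n − A − 1), sharing PRESS bit-for-bit with Q². The df convention is
  a transparent ANOVA decomposition; the commercial implementation's exact
  convention is unpublished. This statistic is *conservative*: PRESS
  exceeds the in-sample residual sum of squares in expectation, so the
  null rejection rate is measurably below the nominal level (≈ 1.4% at
  α = 5% in a 500-replicate null simulation). Its p-values rank models
  usefully but are not uniformly distributed under the null.
* **Permutations**: the response is shuffled (default 100 times), the model
  refitted with a re-chosen component count, and R²/Q² regressed on the
  absolute correlation between permuted and original response, anchored by
  the real model at |corr| = 1. Pass criteria Q²-intercept < 0.05 and
  R²-intercept < 0.4 follow standard chemometrics guidance.
* **Leave-k-out**: Q² recomputed with seeded folds of size k, default
  k ∈ {1, 3, 7} (the exact k values used by the source are unknown).
* **Coefficient stability**: refits on each fold complement; per-variable
  spread, delete-group jackknife interval, and sign-consistency against
  the full fit.

A caution that the package makes explicit: because the univariate screen
and the sweep both consult the same response, end-to-end significance is
inflated relative to the nominal level — cohorts with *no* genetic signal
still produce a "significant" final model in a substantial fraction of
runs. The validation battery (especially the permutation intercepts)
exists precisely because the selection path invalidates naive p-values;
the pipeline reports, but cannot repair, this property of the two-step
design.

## Genetic score

The exported score is affine: intercept plus one coefficient per SNP,
dominant entries counting dosage 2 as 1. Export/score round-trips
reproduce the fitted model's predictions exactly; covariates that survive
selection are exported separately and the genetic score is flagged as
partial. Missing genotypes fail loudly by default (a clinical-style
predictor should not impute silently); an explicit cohort-mean fallback
exists. The published 10-SNP model ships as packaged JSON with intercept
35.7 nmol/g protein; note its published source table reports positive PLS
coefficients for two SNPs whose univariate coefficients are negative — the
fixture encodes the PLS table as printed, without resolving the
discrepancy.

## Synthetic cohort generator

The generator is the package's substitute for the unavailable cohort data
and defines the conditions under which the pipeline is exercised:

* **Genotypes**: dosages are sums of two Bernoulli(p) allele indicators —
  exact HWE proportions. LD pairs are generated by allele copying: each
  partner allele copies the source allele with probability 1 − f and is
  redrawn from its own marginal otherwise, with f calibrated (closed form
  for equal frequencies, numerically otherwise) so the allele correlation
  equals √r²_target; dosage r² then matches the target in expectation and
  f = 0 reproduces the exact-copy r² = 1 case. No haplotypes, population
  structure or genotyping error are modelled.
* **Phenotype**: latent concentration = 35.7 + Σ effects (the packaged
  published coefficients by default; dominant coding collapses dosage 2
  to 1) + N(0, σ²_residual) between participants; replicates add
  N(0, σ²_technical) and are laid out on the meal × time grid (fixed 6, or
  uniform 2–6 in "vary" mode, matching the study's replicate counts).
  Concentrations are clipped at zero.
* **Noise split**: the source reports no residual/technical decomposition.
  Defaults are assumptions, chosen once: σ_residual solves analytically
  for a between-participant CV of 61% given the genetic variance of the
  architecture (≈ 67 nmol/g protein for the default panel), and
  σ_technical = 18 (≈ 15% of the expected mean) as plausible assay noise.
* **Covariates**: age, BMI, blood lipids and plasma α-TOC are drawn with
  the study's published means and SEM-derived SDs; total cholesterol and
  plasma α-TOC are coupled to the standardized latent phenotype through a
  Gaussian construction targeting Pearson r = 0.36 and 0.24.

What passing tests on these cohorts show — and what they do not: the
generator produces *independent* SNPs (unless LD pairs are configured)
with exactly linear, homoscedastic genetics. Real candidate-gene panels
are correlated within genes, and the published univariate effect sizes
(2–3× the PLS coefficients) suggest exactly such correlation. Under the
stated generating conditions (printed coefficients + CV-61% noise), the
per-SNP univariate Wald t at n = 42 is ≈ 1, so the screen-gated pipeline
recovers only ~1–2 of the 10 causal SNPs per run; recovering most of the
architecture requires larger cohorts or lower noise (both exercised in the
tests). Parameter-recovery results on these cohorts therefore validate the
machinery, not the attainability of the original study's model size at
n = 42.

## Problem sizes used by the test battery

Worked examples run on printed summary statistics (instant). Oracle
equivalences use 200 random instances (PLS vs least squares), 12-sample
leave-one-out refits, and all genotype-count triples with n ≤ 50 (HWE).
Calibration checks use 500 null replicates per test at n = 42.
Parameter-recovery runs 20 seeded end-to-end pipelines at n = 42 with 100
permutations each, plus 5 cohorts at n = 420 in a low-noise regime
(σ_residual = 20, σ_technical = 10) for intercept recovery. The whole
suite completes in a few minutes on one CPU.
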