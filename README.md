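# tocopls

Candidate-gene SNP association analysis of adipose-tissue α-tocopherol
(vitamin E) concentration, built as a tested, reusable Python pipeline.

## The problem

α-Tocopherol (α-TOC) is mainly stored in white adipose tissue, and its
concentration there varies widely between healthy people (between-participant
CV around 60%) while correlating only weakly with fasting plasma α-TOC.
Part of that variability is genetic. `tocopls` implements the full analysis
chain used to find SNP combinations associated with such a phenotype in a
small candidate-gene cohort (n ≈ 42, thousands of candidate SNPs):

1. **Genotype QC** — call-rate filter (< 95% dropped), Hardy–Weinberg
   equilibrium exclusion (Pearson χ², 1 df, p < 0.05), greedy tag-SNP
   pruning of high-LD SNPs (squared dosage correlation r² > 0.80) within
   gene groups, and seeded de-duplication of perfectly correlated pairs.
2. **Phenotype processing** — replicate adipose α-TOC measurements (meal ×
   time design, 2–6 per participant) are screened with a two-tailed Grubbs
   test and averaged into one phenotype per participant; paired *t*
   contrasts verify that neither meal nor sampling time shifts the
   concentration; CVs are compared with Forkman's F-type test; Pearson
   correlations carry Fisher-z 95% CIs.
3. **Univariate screen** — every SNP is tested under additive
   (per-minor-allele) and dominant (carrier) codings by least squares with
   a Wald *t* test; genotype groups with fewer than 5 observations exclude
   a coding; p < 0.05 retains a candidate. Covariates are retained when
   their correlation CI excludes zero.
4. **PLS regression with VIP selection** — a from-scratch PLS1 (NIPALS)
   engine on autoscaled data; models are refitted along an increasing
   VIP-threshold ladder, and the model maximizing

       adjusted R² = 1 − (1 − R²)(n − 1)/(n − k − 1)

   with a significant cross-validation ANOVA is selected; selected SNPs in
   mutual LD are pruned to the highest-VIP member.
5. **Validation battery** — CV-ANOVA, 100 y-permutations (R²/Q² intercepts),
   leave-k-out cross-validation, and fold-wise coefficient-stability checks.
6. **Genetic score** — the final model is exported as an affine predictor,
   concentration = b₀ + Σᵢ rᵢ·cᵢ, with cᵢ the minor-allele count (additive)
   or carrier indicator (dominant). The published 10-SNP score (intercept
   35.7 nmol/g protein, SNPs in *PPARG*, *ABCA1*, *BUD13*, *CD36*, *MGLL*)
   ships as a packaged fixture.

Because cohorts like this are not publicly downloadable, the package
includes a first-class synthetic cohort generator (`tocopls.simulate`) that
emulates the study design — HWE genotypes at the published allele
frequencies, optional LD, the published effect sizes, replicate structure
and correlated blood-lipid covariates — so every stage is testable end to
end.

## Worked example

```python
from tocopls import PipelineConfig, run_pipeline, score, published_score_model
from tocopls.simulate import simulate_cohort, study_config

config = study_config(n_participants=120, seed=42, residual_sd=22.0,
                      technical_sd=10.0, vary_replicates=False)
genotypes, cohort = simulate_cohort(config)
result = run_pipeline(genotypes, cohort.measurements, cohort.covariates,
                      PipelineConfig(seed=7, n_perm=100))
print(result.status)
print(result.coefficient_table().round(3).to_string(index=False))
```

prints

```
ok
 gene    snp_id   coding   vip  coefficient
 CD36 rs3211958 additive 1.012       13.641
BUD13 rs1648364 dominant 1.113       25.599
ABCA1 rs1561166 dominant 1.083       29.213
ABCA1 rs4743764 dominant 1.062       22.181
ABCA1 rs2275542 dominant 0.860       16.985
```

a low-noise 120-participant cohort generated from the published 10-SNP
architecture, in which the pipeline recovers five of the causal SNPs (the
final model here: R² = 0.62, adjusted R² = 0.60, Q² = 0.58, CV-ANOVA
p ≈ 1e−23, permutation Q²-intercept −0.12). Each coefficient is the mean
change in adipose α-TOC concentration (nmol/g protein) per minor-allele
copy (additive) or in carriers (dominant).

Applying the packaged published score:

```python
model = published_score_model()
row = {snp: 0.0 for snp in model.snp_ids}
score(row, model)                # -> 35.7 (intercept: zero minor alleles)
row["rs709158"] = 2.0            # additive: 2 x 16.8
row["rs1561166"] = 1.0           # dominant carrier: +36.4
score(row, model)                # -> 105.7 nmol/g protein
```

The same steps are available as a CLI
(`tocopls simulate|qc|phenotype|screen|fit|select|validate|score|run`),
with exit code 0 on success, 2 when no significant model exists, 1 on
error.

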