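# Methods

This note documents the statistical model behind each component, the
defaults and why they were chosen, and what the synthetic cohort does and
does not emulate.

## Score construction

A trait's genetic risk score is the raw weighted allele count
`GRS_it = Σ_m w_mt d_im` over that trait's markers (one lead SNP per
gene/locus). No normalization by marker count and no centering is applied:
the score stays in trait units (mg/dL per allele copy summed; log-mg/dL
for TG), so cohort-level score means and SDs are directly interpretable.
A marker may carry weights for several traits; trait marker sets are
allowed to overlap.

Dosages are expected effect-allele counts in [0, 2]. Harmonization aligns
each genotype column with the weight table's effect allele: matching
orientation is kept, the opposite orientation of the same allele pair is
recoded `d → 2 − d` (missing stays missing), an incompatible pair drops the
marker, and a weight marker absent from the genotype data is dropped with
the score computed from the remaining markers. Strand-ambiguous (A/T, C/G)
pairs are matched by the labels as given and logged; no frequency-based
strand inference is attempted, because silent inference can corrupt scores
undetectably. Harmonization is an involution fixed point: applying it twice
equals applying it once.

Missing cells are filled with the marker's cohort-wide mean observed dosage
(a per-marker expected allelic dosage). The fill is deliberately not
population-specific: one score per individual, computed the same way for
everyone.

## Quality control

Marker filters use strict inequalities: missingness > 0.05, minor allele
frequency < 0.005 (computed from mean dosage / 2, folded), and exact
Hardy–Weinberg p < 0.0005. The HWE test is the exact conditional test
(probabilities of heterozygote counts no more probable than observed, given
the allele counts), chosen over the chi-square approximation because the
0.0005 threshold bites exactly where the approximation is worst — rare
alleles and small expected cell counts. HWE applies only to non-imputed
markers, on dosages rounded to integers: fractional imputed dosages are not
genotype counts and HWE belongs to the pre-imputation data. Monomorphic
markers return p = 1. Individuals on lipid-lowering medication are excluded
before analysis when a medication flag is present.

## Regression evaluation

All models share the covariate set {age, age², sex} (sex coded female = 0,
male = 1; the sign of the sex coefficient depends on this coding). TG is
analyzed as its natural logarithm. Complete-case analysis per model; no
phenotype imputation, no outlier trimming. Continuous axes of ancestry
(genotype principal components) are deliberately excluded from all models:
they are collinear with the population factor, and the whole point is
inference *about* population groups. R² is unadjusted throughout, since
ΔR² between nested OLS fits is the quantity of interest.

- **ΔR²**: R²(covariates + score) − R²(covariates), p from the 1-df nested
  F-test (identical to the squared-t test of the score coefficient). The
  confidence interval is a case-resampling percentile bootstrap (default
  1,000 resamples, seeded): rows are resampled, both models refit, and the
  2.5/97.5 percentiles of the ΔR² replicates taken. A percentile bootstrap
  was chosen because it is distribution-free and the sampling distribution
  of ΔR̂² is skewed near zero.
- **Moderation**: F-test of {covariates + population + score +
  population×score} against the model without interactions, df1 = K − 1.
- **Joint non-corresponding test**: F-test of {covariates + all four
  scores} against {covariates + the trait's own score}, df1 = 3, with the
  full-model per-score coefficient table. Covariates stay in both models;
  a `include_covariates=False` flag reproduces the bare two-score-model
  comparison.
- **Clinical outcomes**: the four scores jointly against covariates-only;
  linear outcomes by 4-df F-test and ΔR², binary outcomes by 4-df
  likelihood-ratio test and ΔNagelkerke-R², where
  `R²_N = [1 − exp(2(ll₀ − ll₁)/n)] / [1 − exp(2·ll₀/n)]` referenced to the
  intercept-only likelihood. A population where a binary outcome has one
  observed class yields an undefined cell, not an error.

Linear fits use OLS (statsmodels for coefficient tables; an internal
Cholesky normal-equations path with an SVD fallback for bootstrap and
simulation loops — the fallback also yields the correct residual sum of
squares for rank-deficient designs, so a score that is an exact linear
combination of the covariates gives ΔR² = 0 rather than an error).
Logistic fits are maximum likelihood; separation or non-convergence raises
a flagged error. Perfect collinearity raises an error naming the aliased
column.

## Population-structure statistics

Per-population effect-allele frequency is `Σd / (2n)` over non-missing
dosages. The across-population contrast is a one-way ANOVA on per-individual
dosage treated as continuous (dosage, not rounded genotype — imputed values
carry information). Zero within-group variance with a between-group
difference is reported as p = 0 with a degeneracy flag. PCA standardizes
each marker to zero mean and unit variance (standard genotype-PCA
practice; makes components scale-free), drops zero-variance markers, and
fixes component signs by forcing the largest-magnitude loading positive so
outputs are reproducible. Pairwise individual correlation is Pearson's r
between dosage vectors; individuals with constant vectors are flagged NaN
rather than silently zeroed. A multi-marker moment estimator of Fst
(across-population variance of frequencies over p̄(1−p̄), with the binomial
sampling contribution subtracted) is provided for checking simulated
differentiation.

## The synthetic cohort

The generator's defaults define the study conditions:

- **Populations**: AfricanAmerican n=1355, AsianAmerican n=666, Caucasian
  n=2063, Hispanic n=1256 (published analysis sizes), with Balding–Nichols
  Fst to a shared ancestral pool of 0.14 / 0.11 / 0.06 / 0.08. The Fst
  values are this package's choice of plausible continental-ancestry
  differentiation (African-descent and East-Asian groups most diverged from
  a pooled ancestral frequency, European-descent least); no published
  per-group values exist to copy.
- **Markers**: 46/37/52/32 per trait drawn from a shared pool of 101
  distinct markers, ancestral frequencies uniform on [0.05, 0.95].
- **Weights**: zero-mean normal, per-trait SDs 0.075/0.082/0.070/0.078,
  chosen so simulated score SDs land at the published cohort magnitude
  (~0.2–0.3) while leaving enough variance headroom for the frequency
  calibration below to be feasible.
- **Phenotypes**: `y = b0 + b_age·age + b_age²·age² + b_sex·sex +
  γ_k·GRS + ε` with age uniform on [45, 84] and male fraction 0.47. The
  per-population noise variance is solved analytically from
  `target = var(γ_k GRS) / (var(cov) + var(γ_k GRS) + var(ε))` so the
  expected ΔR² equals the configured target — a deterministic calibration
  rather than trial and error. Default targets 0.05 / 0.04 / 0.035 / 0.01
  (Caucasian / Hispanic / Asian / African-American) with slope multipliers
  1.0 / 1.0 / 0.9 / 0.45 encode the cross-population generalization gap the
  evaluation is designed to detect. An unattainable target (score variance
  too small) raises an error rather than silently missing it. TG is
  generated on the log scale and exponentiated. The far Gaussian tail of
  HDL/LDL/TC is floored at 1 mg/dL to stay on the physical scale (<0.1% of
  draws at the defaults).
- **Dosage realism**: 84% of markers flagged imputed (published cohorts
  genotyped only a small minority of score markers directly) with truncated
  Gaussian jitter (SD 0.1) to emulate fractional dosages; 1% of cells
  masked missing; medication flags at a configurable rate (default 0 — the
  flag exists to exercise the sample filter).
- **Clinical outcomes**: binary outcomes from a logistic model on the four
  scores (e.g. metabolic syndrome loaded negatively on the HDL score and
  positively on the TG score, T2D negatively on the TG score); continuous
  risk indices as linear combinations with Gaussian noise.

A separate calibration utility solves, per population, the nearest
frequency vector (constrained least squares, frequencies bounded in
[0.02, 0.98]) whose implied score mean `Σ2p_m w_m` and variance
`Σ2p_m(1−p_m)w_m²` match published cohort-level summaries; sampling
binomial genotypes from the calibrated frequencies then recovers those
summaries within Monte-Carlo error.

**What the simulator does not emulate**: linkage disequilibrium between
markers (scores use one lead SNP per gene, so markers are independent by
construction), admixture tracts and within-group ancestry gradients,
genotyping batch artifacts, differential imputation quality across groups,
and gene–environment interaction beyond population-specific slopes.
Passing tests therefore demonstrate that the *statistical machinery* is
correct under the assumed generative model, not that any particular real
cohort satisfies that model.

## Problem sizes and numerical choices

Calibration suites run at desk scale chosen by this package: moderation
type-I error over 1,000 null datasets (n = 500/group) and power over 200
datasets (n = 1,000/group, 5:1 slope ratio); ΔR² recovery over 200 datasets
at n = 2,000/population; bootstrap coverage over 500 datasets (n = 400,
300 resamples). Dosages outside [0, 2] beyond 1e-6 are errors; within
tolerance they are clipped. Nested-F numerators are floored at zero against
floating-point cancellation. All tables are written with a fixed float
format (`%.10g`) so identical runs are byte-identical.

## Known limitations

- The exact HWE test enumerates all heterozygote counts per marker; for
  extremely large cohorts a mid-p or chi-square screen would be faster.
- The bootstrap refits both nested models per replicate without
  acceleration (no BCa correction); percentile intervals for ΔR̂² can
  undercover slightly at small n because ΔR̂² is positively biased.
- VCF parsing handles biallelic records only; multi-allelic records are
  skipped with a warning rather than decomposed.
- The pipeline's pairwise-correlation table is O(n²) and disabled by
  default for large cohorts.
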