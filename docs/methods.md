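# Methods

This note documents the statistical model, the estimation algorithms, the
synthetic-data generator, and the numerical and design choices behind
`longreml`.

## Two-stage trajectory model

Repeated measurements of trait *k* on subject *i* at period *j* are modelled
as

    y_ijk = β_ik0 + β_ik1 (age_ij − mean(age_i)) + ε_ijk

with `mean(age_i)` the unweighted mean of the subject's *observed* ages.
Centring at the subject's own mean age makes the intercept B0 the expected
trait value at that age (not an extrapolation to age 0) and — crucial for
heritability of change — de-correlates the intercept and slope estimates, so
B1 is not contaminated by the subject's baseline level.

Periods differ in residual variance, so stage 1 estimates a weight
w_jk per (period, trait): the residual variance of a cross-sectional
regression of the trait on intercept + sex + age + top-10 genetic PCs across
the subjects observed in that period. Stage 2 then fits each subject's line
by weighted least squares with observation weight 1/w_jk: the standard
heteroscedasticity correction that down-weights noisier periods. Two points
deserve emphasis:

- **Weight direction.** A literal reading of the variance specification
  Var(ε_ijk) = (1/w_jk)·σ²_ik with w_jk called a "residual variance" would
  give *noisier* periods *more* weight. The default is the statistically
  correct direction (weight ∝ 1/w_jk); the literal reading is available via
  `weight_mode="literal"` so the ambiguity is surfaced rather than hidden.
- **What w_jk contains.** Because stage 1 is cross-sectional, w_jk includes
  between-subject variance of both the level and the slope contribution
  (β_ik1 times the age deviation), not just measurement noise. At extreme
  periods the slope term dominates, giving a U-shaped weight profile over
  periods. This costs some efficiency for slope estimation relative to an
  oracle that knew the pure noise variances, but it is what a two-stage
  procedure can estimate without fitting a joint mixed model, and the
  estimates remain unbiased (the induced B1 measurement-error variance is
  small: ~1.5% of slope variance at the default design).

Inclusion rules applied before fitting, all with strict inequalities:
natural-log transform for traits flagged skewed (non-positive values become
missing with a warning); whole (trait, period) cells dropped when their
missing rate exceeds 0.5; subjects retained per trait only with ≥ 3
non-missing measurements. Subjects without two distinct observation ages are
dropped (slope undefined). The per-subject weighted residual variance σ²_ik
is carried in the output but unused downstream by default.

Stage-1 "age" is the raw visit age (not centred); this affects only the
stage-1 intercept, not the residual variance that defines w_jk.

## Genetic relationship matrix

The GRM uses the realized-relationship estimator with standardized dosages
and the distinct diagonal form (see `grm.py` for both formulas). The diagonal
choice matters: it changes REML variance estimates relative to the plain
cross-product, and it makes A slightly indefinite in small samples — a fact
the REML implementation must survive (below). Allele frequencies are
estimated in-sample after QC; missing genotypes are handled by pairwise
deletion with per-pair SNP counts (mean-imputation is available via
`missing="mean"`). Monomorphic SNPs are excluded with a warning. The
estimator is exactly invariant to allele-label swaps, and the SNP-count-
weighted average of per-chromosome GRMs reproduces the genome-wide GRM
exactly when no calls are missing.

With frequencies estimated in-sample, standardized scores sum to ~0 across
subjects, forcing the mean off-diagonal toward −1/(n−1) rather than 0; tests
account for this.

PCs are the top-k eigenvectors of the GRM scaled by the square root of their
eigenvalues, with each component's sign fixed by making its largest-magnitude
loading positive, so covariate files are byte-reproducible.

## GREML

Variance components for y ∈ {B0, B1} (covariates: intercept, subject mean
age, sex) are estimated by restricted maximum likelihood:

    l_R = −½ [ log|V| + log|XᵀV⁻¹X| + yᵀPy ],  V = Σ_c A_c σ²_g,c + I σ²_e

maximized by average-information REML: one EM burn-in step, then Newton
steps using the AI matrix, with components constrained to a floor of
1e-6 × phenotypic variance (proposals below it are clamped). The Newton step
uses an **active set**: components pinned at the floor whose gradient points
further down are frozen and the AI system re-solved for the free components —
without this, a clamped component corrupts the step for the others. Each step
is backtracked (halved) until the likelihood does not decrease; candidate
points where V loses positive definiteness are rejected the same way.
Convergence requires successive log-likelihood change < 1e-4 and relative
component change < 1e-8 (defaults; `max_iter=100`).

Two pathologies get explicit treatment:

- **Flat likelihood.** If a GRM is indistinguishable from the identity, total
  variance is identifiable but its split is not; the AI matrix is singular.
  The fit detects this (condition number > 1e9) and returns
  `status="flat"` rather than an arbitrary interior point.
- **Near-singular ridge.** Because the GRM diagonal makes A slightly
  indefinite at small n, the REML optimum can sit on a ridge where V is close
  to singular and AI steps stall just short of the optimum. An opt-in
  `polish=True` runs a bounded derivative-free refinement (Nelder–Mead on
  log-variances, rejecting non-PD points); precision tests use it, production
  defaults do not need it.

Initialization gives every component an equal share of the phenotypic
variance. A GRM so far from PSD that even the initial V fails Cholesky gets a
1e-6 diagonal ridge with a warning. Standard errors come from the inverse AI
matrix at the optimum, with the delta method for h². The null model
(residual only) has the closed form σ²_e = RSS/(n−p), evaluated under the
same likelihood-constant convention.

**Testing against the boundary null.** The LRT statistic 2(l₁ − l₀) is
referred to a 50:50 mixture of a point mass at zero and χ²₁ (the null value
σ²_g = 0 lies on the parameter boundary): p = 0.5 · P(χ²₁ > LRT), so an
observed statistic of 0 gives p = 0.5. FDR across the trait panel uses
Benjamini–Hochberg within each response (B0, B1).

**Chromosome partition.** The default is one joint REML fit with 22 genetic
components plus residual (per-chromosome fits are available via
`joint=False`; the two differ when chromosomes compete for the same
variance). Per-chromosome h²_c = σ²_g,c / total variance; the
chromosome-size correlation is a Pearson correlation of h²_c against SNP
counts (physical lengths accepted), with a two-sided t-test.

## Trajectory GWAS

Per SNP: OLS of the response on intercept + additive dosage + covariates
(mean age, sex, 10 PCs), two-sided t-test on the dosage coefficient,
subjects with missing dosage dropped per SNP (no imputation), monomorphic
SNPs reported as NA rows with a reason. P-values from numerically perfect
fits are floored at the smallest positive double rather than 0. Thresholds
are strict: genome-wide p < 1e-7, suggestive p < 1e-5. Genomic-control λ is
the median test χ² over 0.4549. The BH routine propagates NAs without
counting them toward the number of tests.

## Synthetic-data generator

The generator mirrors the model the pipeline assumes, with known truth:

- Genotypes: allele frequencies uniform on `maf_range` (default 0.05–0.5),
  dosages Binomial(2, p) per subject (HWE), chromosome labels in 22
  near-equal blocks. No LD, no population structure, no genotyping error —
  deliberate non-goals.
- Subject effects: true intercept b0 and slope b1 are each polygenic value +
  environmental residual. SNP effects are i.i.d. Gaussian across all SNPs
  (infinitesimal model) and rescaled so the realized genetic variance equals
  h²·var exactly in-sample; this makes parameter-recovery tests sharp at
  moderate n. The environmental parts are drawn at their nominal variances
  (so realized total h² varies by ordinary sampling error), independent
  between intercept and slope by default with correlation configurable — the
  trajectory model itself does not constrain their joint distribution.
  The same in-sample philosophy drives `simulate_snp_response`, which makes a
  single SNP explain an exact variance fraction for power checks.
- Design: baseline age uniform on 40–69 years, follow-ups at exact 2-year
  spacing (6 periods); visit-level noise N(0, w_j) with the default
  heteroscedastic profile (0.30, 0.36, 0.42, 0.48, 0.54, 0.60) — modest
  measurement noise growing over follow-up, in units of the subject-level
  trait variance (var_B0 = var_B1 = 1 by default). Fixed effects default to
  sex_effect = 0.5, age_effect = 0 (a nonzero age effect only shifts all
  slopes, leaving variances untouched).
- Missingness: visits dropped independently with `missing_visit_prob`
  (rows kept with missing values), plus a separate `drop_periods` knob that
  blanks whole periods to exercise the >0.5 missing-rate exclusion.
- All randomness flows through seed sequences derived from `seed` (separate
  streams for genotypes and each named trait), so a configuration is fully
  reproducible and traits are mutually independent given the genotypes.

What passing tests on these data do **not** show: robustness to LD between
causal and tagged variants, to population stratification beyond what PCs
remove, to informative (non-random) dropout, or to model misspecification of
the linear age trend. They do show that the estimators are correct and
calibrated when their assumptions hold.

## Problem sizes used in tests and the acceptance script

Chosen as the smallest scales at which the targeted behaviour is clearly
measurable: optimizer-equivalence at n=40/m=200 (10 instances); parameter
recovery at n=1000/m=5000 (10 replicates; per-replicate sampling SE of ĥ² is
≈ √(2m)/n ≈ 0.1); null calibration with 200 replicates at n=300; chromosome
localization at n=500 with 100 SNPs/chromosome; the acceptance script's
pipeline run at n=500/m=2000 and recovery means at n=800/m=3000 over 5
replicates. The analysis walkthrough uses a 400-subject, 1500-SNP, 16-trait
cohort; at that scale a true slope h² of 0.17 is detectable as the top-ranked
trait but not reliably FDR-significant — a deliberate illustration that
longitudinal-change heritability demands large cohorts.

## Known limitations

- Two-stage estimation is statistically less efficient than a joint mixed
  model (a non-goal here); its simplicity is the point.
- Dense-matrix REML is O(n³) per iteration; fine for n up to a few thousand,
  not for biobank n.
- The HWE chi-square test is anti-conservative at very small expected
  genotype counts; the exact test (`method="exact"`) is preferable there and
  the two can disagree about a sharp threshold in that regime.
- Sample QC covers genotype missingness only; sex-consistency checks would
  require X-chromosome data, and genotype imputation is out of scope.
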