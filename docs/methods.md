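# Methods

`renometh` implements a blood-methylation analysis of kidney function in
type 2 diabetes: per-CpG association testing, sparse multisite panel
selection, longitudinal modelling of eGFR decline, 5-year end-stage
kidney disease (ESKD) projection, and functional enrichment of selected
sites. Everything is exercised on synthetic cohorts so the full pipeline
is testable without protected patient data.

## Models and procedures

### Methylation scales

A CpG's methylation is a beta value in [0, 1] (methylated signal
fraction) or an M value, `M = log2(beta / (1 - beta))`. The two are a
monotone bijection; M is variance-stabilised and is the scale on which
the simulator works. The M transform clips betas into
`[1e-6, 1 - 1e-6]` by default (configurable, or disabled to make
boundary values an error) because boundary betas map to infinite M.

### Probe quality filters

Filters run in a fixed order — SNP-overlap, detection-failure fraction
(probes then samples), non-CpG context, sex chromosomes, any-missing —
and each probe is charged to the first rule that removes it, so the
`FilterReport` counts are disjoint and conserve the input count. The
detection-failure cutoff (`unreliable_fraction_threshold`, default 0.05)
is the knob most likely to differ between studies and is surfaced
explicitly. Manifest coordinates are 1-based (array convention); the BED
reader is the single place where 0-based half-open coordinates are
converted.

### Single-site EWAS

For each probe, the trait (baseline eGFR or eGFR slope) is regressed by
OLS on methylation plus covariates (sex, age, smoking, diabetes
duration, HbA1c, systolic and diastolic blood pressure, batch, cell
fractions as supplied); the methylation coefficient is tested with a
two-sided t test. The implementation residualizes the trait and all
probes on the covariate design once (Frisch–Waugh) and then fits each
probe as a simple regression; this is algebraically identical to the
per-probe full OLS (verified against `statsmodels` in the tests) and
costs one matrix pass. Bonferroni adjustment is `min(m*p, 1)`;
Benjamini–Hochberg FDR flags use the step-up rule with an inclusive
boundary (`p <= q*k/m`). The genomic inflation factor is
`lambda = median(qchisq(1 - p, 1)) / qchisq(0.5, 1)`; zero p-values are
mapped to the smallest positive float first.

### Multisite selection

The core procedure builds a sparse linear predictor from many CpGs:

1. A 10% test split is excised once and never touched until the final
   evaluation.
2. Repeated nested cross-validation (default 10 repeats x 10 outer
   folds) on the training split. Per outer fold the LASSO penalty is
   chosen by inner 5-fold CV as the **largest** grid alpha whose mean
   inner R² is within one SD of the best, the SD taken across grid
   values — large alphas are preferred so each fold model keeps only the
   strongest CpGs. The fold model's selected set and its outer-test
   Pearson correlation are recorded.
3. Each probe is weighted by the sum of the outer-test correlations of
   the fold models that selected it (signed, as the formula reads;
   negative fold correlations are not clipped). Ranking is by descending
   weight with ties broken by ascending probe ID.
4. Model sizes n are scanned over the ranked list (every n up to the
   number of positive-weight probes, capped at `max_size`, default 200).
   For each n a LASSO is refit on the whole training split with alpha
   re-selected by inner CV on the restricted design, and its BIC
   computed as `N ln(RSS/N) + k ln(N)` with k = active coefficients plus
   intercept (the standard LASSO degrees-of-freedom estimator). The
   chosen n* is the **largest** n whose BIC is within `0.1 * SD(BIC)` of
   the minimum — more sites are kept for robustness as long as fit
   barely degrades.
5. The final LASSO on the top-n* probes keeps zero coefficients in the
   model record (they are part of the candidate panel), stores the
   standardization parameters, and serializes to JSON exactly.

The alpha grid is 50 log-spaced values (configurable) from `alpha_max`
(the smallest penalty zeroing all coefficients) down to
`1e-4 * alpha_max`. Covariates, when included, are standardized and
penalized alongside the probes; an unpenalized-covariate variant was
considered and rejected to keep a single code path — the simplest
reading of "LASSO on sites plus covariates".

If no probe is ever selected across all fold models (typical of null
cohorts), the pipeline returns an intercept-only model rather than
failing; constant predictions are reported with correlation 0, since a
constant ranks nothing.

Cross-cohort transfer supports two modes: retraining on the probe
intersection of the two cohorts, or applying the original model directly
with absent probes' standardized values set to zero (which changes
nothing when the absent probes carried zero coefficients — a contract the
tests check).

### eGFR trajectories

Longitudinal kidney function follows a linear mixed model on the log
scale: `log(eGFR_ij) = b0 + b1*t_ij + u0i + u1i*t_ij + e_ij`, with an
unstructured 2x2 random-effects covariance, fitted by REML
(`statsmodels.MixedLM`). A subject's slope is `c_i = b1 + u1i` (BLUP),
reported as annual percent change `100*(exp(c_i) - 1)`; the inverse map
is `c = log(pct/100 + 1)`. Projection: `eGFR(t) = eGFR(0) * exp(t*c_i)`,
with ESKD at a horizon defined as projected eGFR < 15 ml/min/1.73 m².
Numerical choices:

- When every subject's trajectory is exactly linear (residuals below
  1e-10), the mixed model is singular (zero residual variance) and the
  fit switches to the exact solution: per-subject OLS, fixed effects as
  the means of the subject lines, random effects as the deviations.
- A singular estimated random-effects covariance triggers a refit with
  independent (diagonal) random effects and a logged warning.
- Single-visit subjects are dropped with a logged count (their slope is
  unidentifiable); subjects with exactly two visits are kept, pooled by
  the model.
- Per-subject OLS slopes (`ols_subject_slopes`) are provided separately
  for replication-style cohorts where each subject is fit independently;
  the mixed model remains the default for the primary analysis.

### Cell-type deconvolution

Whole-blood beta values at discriminating probes are modelled as
`x = R w` with R the reference panel. Per sample, w solves nonnegative
least squares and is renormalized to sum to one; the simplex is enforced
by renormalization rather than constrained optimisation, which matches
reference-based practice and guarantees valid covariates. Fewer panel
probes than cell types is an error (underdetermined), as is an all-zero
solution.

### ESKD risk evaluation

The "actual" 5-year label applies the projection to the mixed-model
slope estimated from all follow-up measurements. The methylation risk
score applies the same projection to a slope inferred by the multisite
model under 5-fold cross-validation (trained on 4/5, scored on the held
1/5); the score is the negated projected eGFR. AUROC and AUPR are
computed on the pooled left-out predictions (not per-fold averages), with
ties counting one half in the ROC area, and additionally on the subgroup
with baseline eGFR >= 30. Subjects already below 15 at baseline project
below 15 under any plausible slope and are therefore labelled positive.
Clinical comparator equations are pluggable score columns, not
implemented here.

### Enrichment

Query CpGs link to every gene whose interval lies within 1 kb of the
probe position (distance to the nearest interval point; 0 inside).
Unmapped probes are reported, not dropped. Two nulls are provided, used
for two different questions: an exact upper-tail hypergeometric test
against the full gene background, and an empirical null resampling
equally sized gene sets from the CpG-proximal universe with the add-one
correction `p = (1 + #{null >= obs}) / (reps + 1)`. Support is counted
at both levels: a site counts as supported if at least one linked gene
carries at least one evidence flag; the gene-level fraction counts
distinct linked genes directly.

## The synthetic-data generator

The generator emulates the statistical structure the analyses assume:

- **Methylation.** Latent M values per probe: a trimodal probe-mean
  distribution (unmethylated / methylated / intermediate), AR(1)
  correlation (`block_rho`, default 0.6) inside contiguous blocks of
  `block_size` probes (default 10) mimicking the spatial dependency of
  neighbouring CpGs, Gaussian probe noise, per-(batch, probe) offsets,
  and cell-composition loadings on a random probe subset driven by
  Dirichlet-distributed fractions. Betas are the logistic image of M and
  lie strictly inside (0, 1).
- **Causal structure.** Disjoint causal probe sets for baseline eGFR and
  slope. Effects have random signs and magnitudes uniform in
  `[0.5, 1.5] * effect_size_sd`, so every planted probe genuinely
  carries signal of the configured scale — a Gaussian effect draw would
  routinely plant near-zero "causal" probes that no method could find,
  which makes recovery rates uninterpretable. QC flags (SNP, non-CpG,
  sex chromosome) and missingness are never placed on causal probes:
  signal removed by quality control is unobservable by construction and
  teaches nothing about the analysis.
- **Phenotypes.** Baseline eGFR is linear in the standardized causal M
  values plus covariate effects (age, HbA1c, diabetes duration, systolic
  BP) and noise, centred at 90 ml/min/1.73 m². Covariates mirror a
  diabetes registry: sex (Bernoulli), age (normal), smoking (3-level
  categorical), diabetes duration (gamma), HbA1c, systolic/diastolic BP
  (normal), batch (categorical).
- **Longitudinal eGFR.** Generated exactly from the random-slope model;
  the default fixed slope is -0.02 log units/year (about -2%/year, the
  decline regime of a diabetic cohort), random-slope SD 0.03, residual
  SD 0.1, follow-up 10 years, 10–40 visits per subject (a registry with
  a median of a few dozen measures), baseline visit always at t=0.
- **Reference panel.** Six leukocyte types (CD4 T, CD8 T, NK, B,
  monocytes, granulocytes) with 10 discriminating probes each,
  near-unmethylated everywhere except the marked type.
- **Determinism.** One global seed fans out to per-component child
  streams via `numpy.random.SeedSequence.spawn`, so adding a generator
  does not perturb the others and identical seeds give bit-identical
  cohorts.

What the generator does **not** emulate: array chemistry and detection
noise, creatinine measurement (eGFR is emitted directly), population
structure, non-linear methylation-phenotype links, informative visit
schedules or dropout. Passing tests therefore show the procedures are
correct and well-calibrated under the assumed generative model, not that
the effect sizes seen on real cohorts will transfer.

## Problem sizes in tests and the acceptance script

Simulation checks run scaled down to single-CPU sizes chosen to keep the
sample-to-feature regime of the analysis: end-to-end recovery uses 500
samples x 2000 probes with 10 planted CpGs and a 10-point alpha grid;
the paired random-probe comparison uses 20 cohorts of 200 x 600; the
acceptance script's primary cohort is 400 x 1500 with 5 repeats of
10-fold nested CV. The ESKD benchmark uses a progressive-decline cohort
(fixed slope -0.25 log units/year, random-slope SD 0.05) so both 5-year
outcomes occur and the methylation signal carries most of the slope
variance. The Bonferroni FWER check regenerates 500 independent null
traits over one 100 x 200 cohort; the inflation-factor check averages
ten draws of 10^5 uniform p-values so it measures calibration of the
statistic rather than Monte-Carlo noise of a single draw.

## Known limitations

- The one-SD alpha rule is aggressive by design; on weak-signal cohorts
  the fold models can be empty and the pipeline degenerates to the
  intercept-only model (reported, not an error).
- BIC for LASSO uses the active-set df estimator, which undercounts
  slightly under heavy correlation; the 0.1-SD tolerance absorbs this in
  practice.
- The mixed model's BLUPs shrink extreme subjects toward the population
  slope; with very short follow-up the per-subject OLS slopes and the
  BLUPs can differ materially, and which to use is a study-design choice
  exposed to the caller.
- Deconvolution assumes the reference panel matches the tissue; panel
  construction from purified cells is out of scope (the panel is an
  input).
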