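# Methods

## Problem

Case–control studies of bipolar disorder (BD) commonly measure, per
subject, (a) a multiplex immunoassay panel of plasma cytokines, chemokines
and growth factors, and (b) proton-MRS metabolite concentrations from a
single anterior-cingulate voxel (glutamate Glu, Glx, N-acetylaspartate NAA,
glutathione GSH, myo-inositol mI).  The scientific question is which
analytes predict which metabolite concentrations after adjusting for
clinical covariates, in a setting with n ≈ 63 patients, ~23 usable
correlated predictors, and no valid p-values from penalized regression.

`cytomet` implements the full analysis chain as reusable components:
analyte limit-of-detection (LOD) QC, MRS partial-volume correction and
reliability filtering, covariate-adjusted univariate statistics with FDR,
bootstrap-stabilized elastic-net variable selection with variable inclusion
probabilities (VIP), and confirmatory Gaussian GLM fits — plus a seeded
synthetic-cohort generator for calibration and parameter-recovery testing.

## MRS post-processing (`cytomet.mrs`)

Tissue segmentation yields voxel percentages of gray matter, white matter
and CSF.  Because CSF carries essentially no metabolite signal, apparent
concentrations are diluted by the CSF fraction

    fCSF = %CSF / (%GM + %WM + %CSF),      corrected = raw / (1 − fCSF).

Only the CSF correction is applied (no GM/WM partial-volume model).
Quantifications are flagged unreliable when the Cramér–Rao lower bound is
**not strictly below 20%** (`crlb < threshold`, threshold configurable);
unreliable rows are retained in files but excluded from statistics.  Tissue
inputs are accepted as percentages (sum ≈ 100) or fractions (sum ≈ 1),
auto-detected from the median sum — the fraction is scale-invariant so the
two conventions are numerically identical.

## Analyte QC (`cytomet.stats`)

An analyte is excluded when its non-detected fraction strictly exceeds the
threshold (default 0.20).  Non-detects of retained analytes are imputed at
LOD/2 (factor configurable); the convention is the standard single-value
substitution for lightly censored assay data.  Non-detects are represented
as an explicit mask plus per-analyte LOD, never as sentinel values, so
downstream stages can revisit the decision.

## Univariate layer

Group comparisons use the pooled-variance (Student) two-sample t —
chosen because it reproduces the reference cohort table's printed t values
within rounding, which Welch's variant does not — and Pearson chi-square
without continuity correction for the 2×2 sex table (again matching the
printed statistic exactly).  Covariate adjustment is an OLS ANCOVA; the
group effect is reported as the partial F with 1 numerator df (the squared
t of the group coefficient).  Correlations are Pearson r with the t-based
two-sided p.  Multiplicity is handled by Benjamini–Hochberg step-up
q-values, one family for the group-comparison table and a separate family
for the correlation screen, mirroring the two reporting blocks of the
motivating study.

## Stability selection (`cytomet.enet`, `cytomet.stability`)

### Solver

The elastic net minimizes

    (1/2n) Σᵢ (yᵢ − β₀ − xᵢᵀβ)² + λ Σⱼ pfⱼ (α|βⱼ| + ((1−α)/2) βⱼ²)

by cyclic coordinate descent with soft-threshold updates (α = `l1_ratio`,
default 0.5; the L1/L2 mix was not stated by the motivating study and 0.5
is the neutral equal-mix reading).  Per-feature penalty factors `pfⱼ` allow
nuisance covariates to enter unpenalized (`pf = 0`): they join every model,
are never shrunk, and never compete for selection.  Implementation notes:

- data are centered internally (intercept unpenalized by construction);
- unpenalized columns are profiled out exactly before iteration
  (Frisch–Waugh), which keeps the iteration well-conditioned when a
  bootstrap resample makes a covariate nearly constant;
- convergence is judged on the fit scale — the largest squared per-sweep
  coefficient change on the standardized-predictor scale relative to the
  outcome variance must fall below `tol` (default 1e-7, the glmnet
  criterion and default).  An absolute coefficient-change criterion stalls
  on near-singular bootstrap training folds where coefficients wander in a
  null space without changing the fit;
- `λ_max = maxⱼ |x̃ⱼᵀ r| / (n α pfⱼ)` over penalized features, where `r`
  is the OLS residual of y on the intercept plus unpenalized features
  (with none, `r = y − ȳ`); at `λ ≥ λ_max` all penalized coefficients are
  exactly zero;
- the grid is geometric, 100 points from `λ_max` down to `1e-4·λ_max`,
  solved warm-started;
- a pure-Python mirror of the update (`debug=True`) asserts the penalized
  objective is non-increasing after every sweep.

### Cross-validation

Per dataset (or per bootstrap resample) the penalty is chosen by 5-fold CV
minimizing the held-out Gaussian deviance — squared error pooled over all
held-out observations ("expected deviance"); exact ties resolve toward the
larger, more parsimonious λ.  Inside a bootstrap resample the folds are
**group-aware**: all copies of a duplicated subject stay in one fold.
Without this, duplicates leak between training and held-out folds,
minimum-deviance CV systematically picks overfit penalties on pure noise,
and the null calibration of the whole procedure breaks (measured: 12/20
null runs produce a false selection with naive folds, 2/20 with grouped
folds at B = 200).

### Bootstrap and VIP

B resamples with replacement (published procedure: B = 5,000; desk-scale
runs use B = 200–500).  Each resample re-runs CV and refits at its own λ*.
Within each resample, predictor columns are standardized before
penalization (the glmnet / MATLAB-lasso default; it makes the penalty
scale-equivariant and is required to reproduce the null calibration of the
canonical implementations), and coefficients are mapped back to the input
scale for reporting; `standardize=False` disables this.
A predictor's VIP is the fraction of resamples with |β| > 1e-8 (coordinate
descent produces exact zeros; the epsilon is a cheap guard).  Selection
threshold: VIP ≥ 0.75, boundary inclusive.  Coefficient summaries are the
bootstrap mean and the percentile interval at 95% — percentile rather than
BCa, the minimal reading of an unqualified "95% confidence interval".  The
percentile interval need not bracket the mean and no such invariant is
asserted.  A resample in which a penalized column is constant pins that
coefficient at zero (counted as non-inclusion) and is logged.

Everything is driven by one `numpy` generator seeded from `random_state`;
the same seed and configuration reproduce results bit-exactly.

### Normalization

Min–max normalization (x → (x−min)/(max−min), per column; constant columns
are an error naming the column) is fitted once on the full analysis sample
before resampling — following the stated order of the emulated procedure
("before performing the analyses") — and applied to predictors and
covariates; the outcome stays on its original scale.  The resulting mild
leakage into bootstrap resamples is acknowledged and a warning is emitted
once per pipeline run; per-resample refitting would be the choice if
out-of-sample generalization estimates were the goal (they are not — the
bootstrap here measures selection stability).

## GLM confirmation (`cytomet.glm`)

Selected predictors are re-estimated on their raw (unnormalized) scale in
a Gaussian identity-link GLM together with **all** nuisance covariates.
Per term: coefficient b, standard error, Wald = (b/se)², two-sided p from
χ²₁ (consistent with the "Wald" naming; at n ≈ 63 the difference from the
t reference is negligible).  The a-priori model of glutamate on IL-9 and
TNF-α (`step1_glu_model`) is a pure delegation to the same fit and includes
the same covariates as the confirmation stage.

## Pipeline (`cytomet.pipeline`, `cytomet` CLI)

`run_pipeline` executes: ND exclusion → CRLB filter + CSF correction →
group/ANCOVA/correlation tables with FDR → step-1 GLM (Glu) → one
stability run per outcome metabolite (mI, GSH, NAA) → GLM confirmation of
each outcome's survivors.  Selection and confirmation run on the patient
group only: the nuisance covariates (onset, episode count, lithium level)
exist only for patients.  Sex is coded M=0/F=1 (logged); "number of
episodes" is depressive + manic counts.  An empty survivor set is reported,
not an error.  Outputs are plain CSVs plus a YAML manifest (config echo,
seed, package versions, per-stage row counts); reruns with one seed and
config are byte-identical, and the manifest suffices to reproduce a run.

## Synthetic cohort generator (`cytomet.simulate`)

The generator emulates the structure the analysis assumes, with defaults
mirroring the motivating study where values were published and stipulated
otherwise (the paper published no analyte distribution parameters):

- **Groups**: 63 BD / 49 HC.  Ages N(46.8, 11.9²) vs N(33.7, 11.1²)
  truncated to 18–65 (BD older in every seeded run); sex Bernoulli with
  female rates 46/63 vs 21/49 — the study's age/sex confound, so the
  covariate adjustment is genuinely exercised.
- **Analytes**: the standard 27-plex panel (16 cytokines, 6 chemokines,
  5 growth factors), multivariate log-normal; log-medians set to plausible
  plasma magnitudes (e.g. CCL5 ~2·10⁴ pg/mL, IL-1β ~2 pg/mL — this scale
  spread is why confirmatory slopes for CCL5 are ~10⁻⁵), log-SD 0.6,
  correlation 0.6 within family blocks and 0.3 between.
- **Censoring**: LOD = the stated quantile of each analyte's marginal
  (default 0.05; 0.35 for IL-10, IL-15, GM-CSF and VEGF so that exactly
  those four fail the >20% ND rule, as in the motivating cohort).
- **Metabolites**: corrected-scale concentration = group baseline + sparse
  analyte effects + covariate effects + Gaussian noise.  Default true
  effects mirror the reported associations (IL-9→Glu, IL-1β/IL-4/bFGF→mI,
  TNF-α/CCL4→GSH, CCL5→NAA) with standardized strengths 0.5–0.8 noise-SD
  per analyte-SD; age→mI slope 0.03/yr mirrors the reported age–mI
  correlation.  Baselines are back-computed so group means land near the
  published table.  Raw (file) concentrations are corrected × (1 − fCSF),
  so the CSF correction recovers the generated value.
- **MRS metadata**: tissue percentages ~ scaled Dirichlet around
  (21, 77.5, 1.5) with concentration 60 (fCSF ≈ 0.015, SD ≈ 1.5%, matching
  the published magnitudes); CRLB uniform in (3, 18)% — all reliable by
  default, as in the motivating cohort ("no subject excluded"), with the
  filter exercised by tests at other ranges.

What the generator does **not** emulate: assay plate effects, longitudinal
or mood-state dynamics, non-lognormal analyte tails, spectral artifacts,
linewidth/SNR group differences.  A green recovery test therefore
establishes that the machinery identifies sparse linear analyte effects of
the stated size under LOD censoring and realistic confounding — not that
the procedure is robust to assay or acquisition pathologies.

## Numerical choices and degenerate inputs

- CRLB threshold comparisons are strict (`<`); VIP threshold is inclusive
  (`≥`), both per the published wording.
- `λ` ties in CV resolve to the larger λ; the λ_max computation carries a
  (1 + 1e-10) round-off guard so the null model is exact at the top of the
  path.
- Constant predictor columns: error at normalization time (named); pinned
  to zero inside a bootstrap resample (logged).
- Missing CRLB ⇒ unreliable (logged); all-zero tissue vector ⇒ error;
  fCSF ≥ 1 ⇒ error.
- Rank-deficient designs raise errors listing the collinear columns.

## Known limitations

- The normalization leakage described above (a property of the emulated
  procedure, not a bug).
- At B = 200 the binomial Monte-Carlo noise of a VIP is ±0.03–0.04; near
  the 0.75 threshold, selections can flip between bootstrap seeds.  B =
  5,000 (the published setting) shrinks this to ±0.006.
- Minimum-deviance CV (as published) is more permissive than the 1-SE
  rule; on pure noise a spurious predictor survives the VIP threshold in
  roughly 5–10% of datasets at n = 63, p = 22, B = 200 — a property of the
  procedure confirmed against an independent glmnet-based implementation,
  not of this package.
- The univariate layer assumes two groups and complete covariates after
  filtering; general k-group designs are out of scope.
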