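# cytomet

Bootstrap-stabilized elastic-net analysis linking peripheral immune markers
(cytokines, chemokines, growth factors) to proton-MRS brain metabolite
concentrations in case–control psychiatry cohorts.

## Who this is for

Groups running combined immunoassay + single-voxel ¹H-MRS studies (e.g.
bipolar-disorder cohorts with an anterior-cingulate voxel) who need the full
statistical chain as tested, reproducible components rather than ad-hoc
scripts: analyte limit-of-detection QC, CSF partial-volume correction with
CRLB reliability filtering, covariate-adjusted group statistics with FDR,
penalized variable selection with honest stability guarantees, and
confirmatory regression — plus a synthetic cohort generator to calibrate
the whole pipeline before touching real data.

## The core method

With n subjects, p correlated analyte predictors X (min–max normalized),
outcome y (a metabolite concentration), and unpenalized nuisance covariates
Z (age, sex, onset, episode count, BMI, lithium), the elastic net

    min over (β₀, β, γ):  (1/2n) ‖y − β₀ − Xβ − Zγ‖² +
                          λ Σⱼ pfⱼ ( α|βⱼ| + ((1−α)/2) βⱼ² )

is solved by cyclic coordinate descent (soft-threshold updates, warm-started
geometric λ path from λ_max = maxⱼ |x̃ⱼᵀr| / (nα pfⱼ)).  Penalized
regression yields no valid p-values, so inference is by stability under
resampling: for b = 1…B bootstrap resamples, λ*_b is chosen by 5-fold
cross-validation (minimum held-out deviance, folds grouped by subject so
duplicates never straddle a split) and the model refit; the **variable
inclusion probability** of predictor j is

    VIPⱼ = #{b : β̂ⱼ,b ≠ 0} / B,

with selection at VIP ≥ 0.75, bootstrap-mean coefficients and 95%
percentile intervals.  Selected predictors are then re-estimated on their
raw scale in a Gaussian GLM with all covariates, reporting b, SE,
Wald = (b/SE)² and its χ²₁ p-value.

The MRS side applies the CSF partial-volume correction
`corrected = raw / (1 − fCSF)` with `fCSF = %CSF/(%GM+%WM+%CSF)` and keeps
only quantifications with Cramér–Rao lower bound < 20%.

See `docs/methods.md` for assumptions, parameter defaults, numerical
choices and limitations.

## Worked example

```python
from cytomet import PipelineConfig, make_demo, run_pipeline

make_demo(seed=1, directory="demo")          # synthetic cohort: 63 BD + 49 HC
config = PipelineConfig(input_dir="demo", output_dir="results",
                        n_bootstrap=300, seed=1)
results = run_pipeline(config)

stab = results["stability_results"]
print(stab[stab["selected"]][["outcome", "predictor", "vip", "boot_mean_coef"]]
      .round(3).to_string(index=False))
```

prints

```
outcome predictor   vip  boot_mean_coef
     mI     IL-1b 0.980           0.866
     mI      IL-2 0.860           0.597
     mI      IL-4 0.927           0.832
     mI      IL-5 0.803           0.477
     mI      CCL2 0.817          -0.794
     mI      bFGF 0.973           1.974
    GSH     TNF-a 0.910           0.231
    GSH     G-CSF 0.750           0.093
    NAA      CCL5 1.000           0.919
```

The demo cohort plants true effects of IL-1β, IL-4 and bFGF on
myo-inositol, TNF-α and CCL4 on glutathione, CCL5 on NAA, and IL-9 on
glutamate.  All strong planted effects are recovered (VIP ≈ 1); correlated
neighbours of true predictors (IL-2, IL-5, CCL2, G-CSF) can ride along near
the 0.75 threshold — exactly the behaviour stability selection is meant to
expose.  Coefficients are per min–max-normalized predictor range.  The
confirmation stage then reports raw-scale effects, e.g.

```
outcome  term       b     se    wald       p
     mI IL-1b  0.2497 0.0776 10.3517  0.0013
    NAA  CCL5 1.4e-05  2e-06 81.2893 2.0e-19
```

(the tiny CCL5 slope is real: plasma CCL5 is measured in tens of thousands
of pg/mL), and the a-priori glutamate model finds IL-9 (Wald = 27.9,
p < 1e-6) but not TNF-α (p = 0.43).

The same run from the shell:

```sh
cytomet simulate --out demo --seed 1
cytomet run-all --input demo --out results --seed 1 -B 300
```

Outputs: `group_stats.csv` (per-variable group means/SDs, t or χ²
statistic, raw p, BH q), `ancova_stats.csv` (age/sex-adjusted partial F per
metabolite), `correlations.csv`, `stability_results.csv` (VIP table above),
`lambda_trace.csv` (per-bootstrap selected penalty), `glm_results.csv`,
`metabolites_processed.csv` (fCSF, corrected concentrations, reliability
flags) and `manifest.yaml` (config echo, seed, versions, per-stage row
counts).  Reruns with the same seed and config are byte-identical.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the demo cohort from the given seed and runs the entire
pipeline end to end (QC → correction → univariate layer → stability
selection at B = 300 → GLM confirmation), leaving the full result bundle
in `results/pipeline_outputs/` next to the report JSON.
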