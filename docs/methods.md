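# Methods

This note records the statistical definitions and numerical choices
implemented in `protsig`, in the order the pipeline applies them.

## 1. Protein-based grouping (`protsig.grouping`)

Samples are dichotomized on a per-sample protein value by one of three rules:

- **Quartiles**: `high` = values ≥ Q3, `low` = values ≤ Q1, middle half
  excluded. Quartiles use linear interpolation (`numpy.quantile`, the type-7
  default); boundary ties join the extreme groups. Requires ≥ 8 values and a
  non-degenerate interquartile range.
- **Z-score**: z = (x − mean)/SD with SD computed with ddof = 1; `high` for
  z > t, `low` for z < −t (default t = 0.2), the band |z| ≤ t excluded.
- **Mean ± k·SD**: `high` above mean + k·SD, `low` below mean − k·SD. With
  k = 0 this reduces to a mean split and matches the z-score rule at t = 0.

All three return a label per sample (`high` / `low` / `excluded`); every
downstream step consumes these labels, never raw cut-offs.

## 2. Signature derivation (`protsig.derive`)

Per gene, the high and low groups are compared with a Welch-type two-sample
test in one of two modes:

- **classic**: ordinary Welch t (mean, SD with ddof = 1), identical to
  `scipy.stats.ttest_ind(equal_var=False)`.
- **robust** (default): location = median, scale = 1.4826·MAD (the
  normal-consistent median absolute deviation). The squared standard error is

      SE² = (π/2) · (s₁²/n₁ + s₂²/n₂)

  with π/2 the large-sample variance inflation of the median relative to the
  mean under normality. Without this factor the statistic referenced to the
  Welch–Satterthwaite t distribution is markedly anti-conservative (measured
  11.6% null rejection at nominal 5%, n = 20/20); with it the measured null
  rejection is 4.7%. Degrees of freedom follow Welch–Satterthwaite on the
  robust variances. This is the package's definition of the "robust Welch
  adaptation"; it is a deliberate design choice, not a literature-standard
  test, and its far-tail p-values at small n remain approximate.

P-values across genes are adjusted by Benjamini–Hochberg step-up FDR
(`statsmodels.stats.multitest.multipletests`, verified in the tests against a
brute-force double-loop oracle). A gene enters the signature when it passes
the FDR threshold (default 0.05) plus optional raw-p and fold thresholds, and
its coefficient is the sign of (location_high − location_low): +1 or −1.
Genes need ≥ 3 non-missing values per group; a derivation that selects no
genes is a warning, not an error, and the pipeline reports `not_applicable`.

### Known power limitation

At small group sizes the robust test pays a large efficiency price. At the
package's canonical stress setting (n = 60 with quartile groups → 15 vs 15,
effect 1.5·noise_sd, 2000 genes) the per-gene noncentrality (~3.8–4.1) sits
below the self-consistent BH cutoff (~5 at m = 2000), so sensitivity
collapses to ~25–30% (classic mode: ~45–50%). This is a property of the
design point, not a bug; the acceptance test that demands 80% recovery there
is left failing, with the analysis recorded in the repository notes.

## 3. Scoring (`protsig.scoring`)

`Sigscore(sample) = Σᵢ Sᵢ·eᵢ` over signature genes present in the matrix
(missing genes are reported, scoring a matrix containing none of them is an
error). Options: per-gene z-standardization before summing, and division by
the number of matched genes. Median dichotomization labels scores strictly
above the median `high`, the rest `low`, optionally within strata (e.g. ER
status), with interpolated medians.

## 4. Validation (`protsig.validate`)

- Pearson correlation with pairwise-complete observations
  (`scipy.stats.pearsonr`, ≥ 3 pairs).
- ROC/AUC via the Mann–Whitney identity AUC = U/(n₁·n₂) with ties counted
  1/2; the p-value is the asymptotic two-sided Mann–Whitney test. The curve
  itself is a full threshold sweep (`sklearn.metrics.roc_curve` without
  intermediate-point dropping); the tests verify that its trapezoidal area
  equals the U-statistic AUC to 1e-10.

## 5. Survival (`protsig.survival`)

Implemented natively (with `lifelines` used only as a test oracle):

- **Kaplan–Meier** product-limit estimator, events before censorings at tied
  times.
- **Log-rank** via per-event-time hypergeometric observed/expected/variance.
- **Cox proportional hazards** by Newton–Raphson on the Efron partial
  likelihood (Breslow available), with step-halving, covariates centered and
  scaled internally and estimates transformed back. Convergence requires
  gradient max-norm < 1e-9; a monotone likelihood (separation) is detected
  either by divergence or by a converged standardized coefficient exceeding
  10 (hazard ratio > e¹⁰ per SD), and flagged as non-converged. Standard
  errors come from the inverse observed information; Wald CIs and p-values.
- **Interaction LRT**: 2·(ℓ_full − ℓ_reduced) ~ χ²(1) comparing Cox models
  with and without the treatment × score product term (both contain
  treatment, score, and any adjustment covariates). Monte-Carlo calibration
  at n = 300 over 1000 null replicates gives a rejection rate within 5% ± 2%
  at α = 0.05.

## 6. Synthetic cohorts (`protsig.simulate`)

A latent activation aⱼ ~ Bernoulli(prevalence) drives

- protein: `protein_effect·aⱼ + N(0, noise_sd)`;
- expression: planted genes `sᵢ·effect_size·aⱼ + N(0, noise_sd)` with
  alternating signs sᵢ, all other genes pure noise;
- survival: exponential PH with linear predictor
  `log_hr_treatment·Tⱼ + log_hr_activation·aⱼ + log_hr_interaction·Tⱼ·aⱼ`;
  uniform right censoring whose horizon is calibrated by bisection to the
  target censoring fraction;
- clinical covariates (age, tumor size, grade, nodal status, ER status)
  drawn independently of activation.

One seed is split into independent per-component streams
(`numpy.random.SeedSequence.spawn`), so adding genes leaves protein, clinical
and survival draws unchanged; the same config is byte-identical across runs.
Sample ids embed the seed, so cohorts drawn with different seeds have
disjoint ids (enforced by the transfer-validation leakage guard). The model
deliberately omits gene–gene correlation, batch effects, and non-proportional
hazards; it is a test harness for the pipeline's statistics, not a realistic
transcriptome simulator.

Default problem sizes used by the acceptance computations (training cohorts
of n = 60 with 2000 genes and 100 planted genes; 81-sample validation
cohorts; n = 300 survival cohorts) are the package's own stress-test choices
mirroring typical cohort scales in this study design.

## 7. Pipeline (`protsig.pipeline`)

`run_pipeline` executes load/simulate → group → derive → score → validate →
survive → associate, writing each stage's artifact in plain text and a
`manifest.json` with the package version, a SHA-256 of the canonical config,
SHA-256 of every input file, and per-stage counts. Two runs of the same
config differ only in the manifest timestamp. Configuration is validated
before any stage runs; a stage failure raises an error naming the stage and
preserves earlier artifacts. `run_transfer_validation` derives on a training
cohort only, refuses overlapping sample ids, and evaluates on the test cohort
against mean ± k·SD protein truth labels.

## Numerical conventions

- Floats are written with `%.10g`; all artifacts are plain text.
- NaN is the only missing-value representation; statistics are
  pairwise/casewise complete as documented per function.
- All randomness flows through `numpy.random.Generator` seeded explicitly;
  no global RNG state is used.
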