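# Methods

This note records the statistical model behind each stage of `methsev`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions a maintainer would
otherwise have to reverse-engineer.

## Severity score

The composite clinical score is additive over features with a floor of 2:
one point per affected bone beyond the first (capped at 5), two points
each for fracture through pagetic bone and orthopaedic surgery, 0–3 points
for deformity grade, one point each for hearing-aid use (which requires
skull involvement), prior bisphosphonate therapy, osteosarcoma history,
and disease onset before 55 years (age at onset banded inversely: earlier
onset is more severe). The attainable range is 2–18. The exact published
weighting lives in prior clinical literature and is not restated here, so
the rubric is a documented default constrained to reproduce the known
range and mean (≈ 6.6) and is fully overridable (`SeverityRubric`,
rubric YAML in the CLI). Osteosarcoma can be excluded via
`include_osteosarcoma=False` since its contribution to the published total
is uncertain. Dichotomization labels a sample *high* iff score ≥ threshold
(cohort median by default, the clinical convention being < 7 vs ≥ 7).

## Synthetic cohorts

The generator is additive on the M-value scale, because all inference in
the pipeline operates on M-values:

```
M_ij = baseline_i + Σ_g γ_ig z_gj + effect_i (S_j − S̄) + ε_ij
```

* `baseline_i`: islands hypomethylated (N(−2.5, 0.8)), other probes
  bimodal — reproduces the qualitative M-value landscape of blood arrays.
* Confounders: per-site coefficients γ on standardized age, sex, three
  batch factors, cell proportions (8 Houseman blood cell types from a
  neutrophil-dominant Dirichlet) and `n_latent = 3` unmeasured factors.
  Coefficient scales are the `confounder_effects` map (defaults 0.10–0.30
  M-units per covariate SD — free parameters of the simulator, not
  estimates from any cohort).
* Island coherence: within an island, both the noise and the confounder
  coefficients mix an island-level draw with a site-level draw in
  proportion √ρ/√(1−ρ), so the within-island correlation of the full
  residual structure equals `island_correlation` (default 0.6). Measured
  within-island correlation ≈ 0.59 vs ≈ 0 between islands.
* Severity: `S_j ~ Poisson(λ_j)` with
  `log λ_j = log μ − v/2 + Σ β_c z_cj + w L_j`, `L_j ~ N(0,1)` the
  liability shared with methylation, `v` the total coefficient variance so
  E[λ] = μ (default 6.6). Scores are floored at 2 (the observed clinical
  minimum) and capped at 18 (the rubric ceiling — required for the
  clinical-features round trip; P(Poisson(6.6) > 18) ≈ 1e−4 so the mean is
  unaffected).
* Causal coupling: `frac_causal_sites` (default 1%) of probes receive
  `effect_i = ±causal_effect_size` (default 0.05 M-units **per point of
  observed severity**). About half of the causal sites are planted as
  whole islands of ≥ 4 sites (so region-level power is measurable), the
  rest scattered over non-island probes. Planting the effect on the
  observed score — rather than on the latent liability — makes the planted
  coefficient exactly the estimand of the site-level regression, so
  effect-recovery bias is well defined; the liability in the Poisson rate
  still makes the coupling visible to the reversed region model.
* Clinical features are sampled as a randomized exact inverse of the
  default rubric, so `composite_severity_score(simulate_clinical_features(s))
  == s` for every attainable score.
* Seeds: one master seed; each operation draws from a fixed child stream
  (`SeedSequence((seed, op_code))`), so adding an operation never perturbs
  the draws of an existing one, and identical configs are bit-identical.

What the generator does **not** emulate: raw array chemistry (dye bias,
probe types, detection failures), genetic effects on methylation (mQTL),
missing values, age-dependent methylation drift, and any real genomic
annotation — probe ids, positions and gene labels are synthetic. Passing
tests therefore demonstrate the statistical machinery (calibration, power,
no leakage) under a known truth, not performance on real cohorts.

Two canonical configurations (`methsev.presets`) define the study
conditions used by the test suite and the reproduction script:

* `null_config` — no causal sites **and** `liability_weight = 0`. The
  liability exists solely to couple methylation to severity; with no
  causal sites it would only over-disperse the Poisson score (var/mean
  ≈ 1.46 at the default weight), which is signal-free model misfit rather
  than a null. 20,000 sites × 232 samples.
* `planted_config` — generator defaults at 232 samples; 4,000 sites by
  default for replicate studies (chosen so ten-replicate power and
  predictor studies complete in minutes on one CPU; the full pipeline at
  20,000 sites runs in ~30 s and is exercised by the orchestration tests).

## Preprocessing

* M-values: `log2((meth+1)/(unmeth+1))`, exact elementwise.
* Sample QC: a sample is dropped iff the median of log2(intensity+1) in
  either channel is **strictly** below 11.0. The threshold is interpreted
  on the log2 scale — raw-scale medians of real arrays are in the
  thousands, so a threshold of 11.0 is only meaningful after the log
  transform; it is configurable.
* Site filtering removes the union of four blacklists (cross-reactive,
  SNP-overlapping, sex-chromosome, smoking-associated probes — all
  user-supplied, one id per line) plus manifest X/Y probes; per-reason
  counts deduplicate in that fixed order.
* Cell composition: the reference-based (Houseman-style) estimator is
  realized as least squares constrained to the probability simplex
  (w ≥ 0, Σw = 1; SLSQP with analytic gradient, ftol 1e−14) — the same
  feasible set as the original constrained projection, testable by
  construction (exact mixtures are recovered to 1e−6; noisy mixtures to
  < 0.05 absolute).
* Surrogate variables: the site-loading basis of the unmeasured structure
  is the top-k left singular vectors of the matrix residualized on
  severity + known confounders (the phenotype is protected during
  estimation); the per-sample scores are then the projection of the
  **original** matrix onto that basis, centered and orthonormalized.
  Projecting the original data is essential: scores taken directly from
  the residual SVD are orthogonal to severity by construction, so
  adjusting for them removes latent variance while leaving the
  chance-correlated latent component — measured λ ≈ 7.8 on a synthetic
  null versus 2.1 with no adjustment and 1.03 with this estimator. Default
  k = 10 surrogate variables.

## Site-level EWAS

Shared-design OLS across all sites via one QR decomposition; the severity
coefficient is reported in M-units per severity point. Aliased design
columns (constant batches, the redundant eighth cell proportion) are
dropped with a warning — small simulated cohorts produce them routinely —
and severity must survive aliasing or the fit errors.

Variance moderation follows the standard empirical-Bayes scaled-F moment
estimator on log s²: d₀ from the trigamma-inverse of the excess variance
of log s² (Newton iteration), s₀² from its mean; posterior variances
s̃² = (d₀s₀² + d·s²)/(d₀+d); moderated t with d + d₀ df (normal when
d₀ = ∞). Two-sided p-values. λ uses the 1−p → χ²₁ upper-tail quantile
convention, reported to 2 decimals. Ties in the ranked output break by
site id for determinism. BH q-values are computed by the step-up rule and
verified against statsmodels.

## Region-level test

Regions partition the retained probes: islands by manifest island id;
non-island TSS200/TSS1500 probes per gene as promoters; non-island
Body/5'UTR/3'UTR probes per gene as gene bodies. Non-island probes with
no gene label cannot be assigned and are excluded (counted in the log).

The Poisson GLM is fitted by IRLS (log link, deviance convergence at
relative 1e−8, max 50 iterations, linear predictor clipped at ±30);
coefficients and deviances match statsmodels/BFGS oracles to ≤ 1e−6.
χ² = D(step1) − D(step2) ≥ 0 by nesting (asserted); df is the rank of the
site block after projection against the confounders (SVD, relative cutoff
1e−10), which equals the site count for full-rank blocks and handles the
strong within-island collinearity otherwise. Regions with more sites than
n − rank(confounders) − 10 are skipped (`df_guard`, configurable);
non-convergent fits mark the region untested rather than erroring.
Multiple testing is per region-type family (islands, promoters, gene
bodies), both Bonferroni and BH.

**Known limitation**: the asymptotic χ²_df reference runs slightly liberal
for large site blocks at n = 232 — with known confounders and exact
Poisson severity, type-I error at α = 0.05 is ≈ 0.053 for 4-site regions
but ≈ 0.066 for 10-site blocks. Calibration checks therefore use the
three-site design, and each replicate redraws the severity score: with a
single draw shared across thousands of regions, the rejection fraction
converges to the type-I error conditional on that draw's realized
dispersion (SD ≈ √(2/n)), not to the marginal level
(`methsev.diagnostics.region_null_calibration`).

## Enrichment

One-sided (over-representation) Fisher's exact p-values — the
hypergeometric upper tail, verified against full enumeration with exact
binomial coefficients to 1e−12 — with a two-sided flag. Odds ratios use
the Haldane 0.5 correction when any cell is zero. Category enrichment
uses gene-level universes (the genes on the manifest); window enrichment
uses site-level universes with 1-based inclusive membership. BED input is
converted from 0-based half-open on read, and exports convert back. The
packaged window fixtures carry the published linkage-region and GWAS-SNP
coordinates verbatim (GRCh37).

## Predictor

The latent-component regressor is standard PLS (scikit-learn NIPALS) on
features centered/scaled with discovery statistics; for single-response
regression its predictive subspace coincides with the orthogonalized
variant the field also uses, so plain PLS is the default and reproducible
choice. The component count (not fixed by any external source) defaults
to "auto": 5-fold discovery cross-validation, capped at 10. The sparse
subset is elastic-net (l1_ratio 0.5) over a 50-point geometric penalty
path with the 1-SE rule on 5-fold discovery CV. The frozen
`PredictorModel` stores feature ids, center/scale, loadings and collapsed
coefficients; predictions depend only on stored fields, and a leakage
audit (corrupting validation labels, asserting bit-identical discovery
artifacts) is part of the test suite. ROC analysis uses the rank/trapezoid
AUC with half credit for ties; the operating point maximizes Youden's J
(a documented choice — no external rule is specified for it), with *high*
predicted at score ≥ threshold.

## Pipeline and formats

Stages run preprocess → severity → site EWAS → region EWAS → enrichment →
predictor; any stage failure halts with the stage named, and partial
outputs remain. Every output directory receives the verbatim config YAML
and a run manifest (package version, config hash, seeds); reruns are
bit-identical. Reports use the manifest's 1-based inclusive GRCh37-style
coordinates; BED exports are 0-based half-open. Matrices are TSV/CSV with
site ids in the first column; values are written with 12 significant
digits. Missing values are unsupported (inputs must be complete), and no
IDAT/raw-chemistry handling is included — inputs are assumed normalized
upstream.
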