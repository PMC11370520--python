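# Methods

## The meta-scoring model

A polygenic risk score (PRS) for sample *s* is the weighted sum
`PRS_s = Σ_i w_i d_is` of per-variant effect weights `w_i` over effect-allele
dosages `d_is ∈ [0, 2]`.  A *meta-PRS* linearly combines K component PRSs —
each derived from one GWAS-like source for the disease or one of its risk
factors — and is collapsed back into a single per-SNP weight table so it can
be deployed like any ordinary scoring file.

Construction has two stages:

1. **Candidate selection.**  Each source provides several candidate weight
   vectors (here: marginal effect estimates thresholded at a p-value grid,
   standing in for a shrinkage-hyperparameter grid).  For each source the
   candidate whose PC-adjusted, standardized score maximizes the AUC of a
   logistic regression for combined prevalent + incident case status
   (adjusting for age and sex) is retained.  Ties break toward the earlier
   candidate, making selection deterministic.

2. **Elasticnet combination.**  The K selected component scores are
   PC-adjusted, standardized, and entered with age and sex into an
   elasticnet-penalized logistic regression.  Mixing parameters α ∈
   {0, 0.1, 0.25, 0.5, 0.75, 0.9, 1} are scanned; for each α a 100-point
   log-spaced λ path from λ_max down to λ_max·10⁻⁴ is solved with warm
   starts, and 10-fold cross-validation records the mean out-of-fold AUC of
   the full linear predictor per (α, λ).  The arg-max pair is refit on all
   training samples.  Ties break toward the larger λ (the sparser model).
   Covariates and the intercept are never penalized; no class reweighting is
   applied.

The solver is a glmnet-style IRLS coordinate descent with per-feature
penalty factors, written here because the stack's penalized logistic
implementations cannot leave covariates unpenalized.  It uses
covariance-form updates (all inner-loop quantities reduce to cached weighted
moments, O(p) per coordinate), internal predictor centering (penalty-
invariant; the intercept is adjusted back on exit), the glmnet α = 0 proxy
(λ_max computed as if α = 10⁻³), and convergence tolerance 1e-8 on the
maximum coefficient change.  The test suite pins it against
`sklearn` SAGA on the all-penalized case and against unpenalized
maximum-likelihood fits in the λ → 0 limit.

**Collapse.**  With `γ_{i,j}` component j's weight for variant i, `β_j` the
elasticnet coefficient (on the standardized-score scale) and `σ_j` the
training-cohort SD of component j's PC-adjusted score, the collapsed weight
is

    w_i = Σ_j (β_j / σ_j) γ_{i,j}

over the union of supports (absent entries contribute 0).  The division by
σ_j is deliberate: the elasticnet consumed standardized scores, so applying
β_j to raw γ weights would mis-weight components by their raw SDs.  A
`literal` mode (`--literal-collapse`) reproduces the plain weighted sum
Σ_j β_j γ_{i,j} for comparison, since deposited meta-scores in the wild do
not always document which convention they used.  Covariate coefficients and
the intercept are cohort-level terms and are dropped at collapse.

PC residualization cannot be expressed in per-SNP weights, so the collapsed
score is defined up to the PC-spanned component; downstream evaluation
re-applies PC adjustment in each target cohort.  The exact algebraic
identity — collapsed-table score equals Σ_j β_j z_j plus a constant, to
1e-8 — therefore holds (and is tested) with PC adjustment disabled.

## Scoring engine conventions

* Positions are 1-based (VCF convention); genome build is metadata only.
* Harmonization matches on variant id first, then chr:pos with an identical
  allele set; duplicated ids are an error.  Swapped effect/other alleles
  score the complementary dosage `2 − d`.  Strand-ambiguous variants (A/T,
  C/G) are dropped by default (`keep` available) because orientation cannot
  be resolved from alleles alone.
* Missing dosages are mean-imputed as twice the effect-allele frequency
  (standard PRS practice); an `exclude` policy propagates NaN instead.
* Standardization uses the sample SD (ddof = 1) and stores (mean, SD) so a
  training-cohort transform replays exactly on held-out samples.

## Synthetic cohort generator

The generator emulates the data structure the pipeline consumes, not any
particular population:

* **Genotypes** are Binomial(2, p) dosages with per-variant MAF uniform on
  `maf_range`, split into two equal subpopulations whose allele frequencies
  drift apart by ±`pc_confounding_sd`·√(p(1−p)), so leading PCs separate
  subpopulations when the drift SD is positive.  Optional equicorrelated LD
  blocks are available; the default is linkage equilibrium, since no check
  here depends on realistic LD.
* **Causal architecture**: `n_causal` variants receive N(0,1) effects
  rescaled analytically so the Hardy–Weinberg genetic variance equals the
  liability heritability exactly; the liability variance decomposition
  (genetic + covariate + residual = 1) holds by construction.
* **Candidate weights**: each source draws `effect_hat ~ N(true, se)` with
  the GWAS standard error `se = se_scale/√(2 N p(1−p))` and emits one
  candidate per entry of the p-value grid {5e-8, 1e-5, 1e-3, 1} (an
  arbitrary stand-in for a shrinkage-hyperparameter grid, which is out of
  scope).  Risk-factor sources draw true effects correlated ρ with the
  disease architecture on the same causal support.
* **Prevalent disease** follows a liability-threshold model: liability =
  genetic + covariate + residual components with unit total variance;
  samples above the Φ⁻¹(1 − prevalence) quantile are prevalent at baseline.
* **Incident disease** among the non-prevalent follows an exponential
  proportional-hazards model, hazard = `baseline_hazard`·exp(β·liability)
  with β the log HR per SD.  The exponential baseline (not Weibull) keeps
  closed-form checks available; the recovery benchmarks concern the
  coefficient, not hazard-shape realism.  Censoring is the minimum of an
  exponential censoring time and administrative truncation at
  `max_follow_up`.  Event onset is dated by the *midpoint convention*:
  halfway between the observed event time and the previous disease-free
  record on a record grid (default spacing 1 year; a zero grid reduces to
  baseline-only, i.e. onset = t/2).
* **Pseudo-clinical score**: a noisy view of the covariate component whose
  squared correlation with it equals `clinical_signal_fraction`, pushed
  through the same hazard form to a 10-year probability.  A dysglycemia-like
  biomarker column (correlation 0.75 with liability) lets evaluation emulate
  the jump from a questionnaire-only clinical model to a biomarker-informed
  one.

Default study conditions: prevalence 7.9%, incident log HR per SD log(1.8),
~12 years of maximum follow-up, 44 sources of which 34 are risk-factor
sources, heritability 0.35 (a common-variant liability-scale figure, i.e.
what a SNP score could in principle capture, deliberately below twin-study
estimates), covariate variance 0.15, baseline hazard 0.005/year.  The
baseline hazard is set so the cohort's mean predicted 10-year risk (~6%)
straddles the UK guideline thresholds (5.6%, 10%, 14.3%) the screening
analysis exercises — with a perfectly calibrated risk score, a cohort whose
mean risk sat far below 5.6% would make two-stage screening degenerate.

What the generator does *not* emulate: realistic human LD panels, ancestry-
specific allele-frequency spectra, hospital-coding noise, diagnostic
misclassification, or the healthy-volunteer selection of real biobanks.
Passing benchmarks therefore demonstrate the correctness and statistical
behaviour of the pipeline's machinery under its stated model, not expected
performance on any real cohort.

All randomness derives from one root seed through documented child streams
(`default_rng([seed, stage_id])` in the simulator; `seed + k` offsets for
the pipeline's stochastic consumers), making every artifact bit-reproducible.

## Evaluation statistics

* **Logistic association**: OR per SD with Wald 95% CI; AUC of the fitted
  linear predictor with a case/control-stratified bootstrap SE (resampling
  within outcome classes, 2,000 replicates by default) and a normal-
  approximation CI.  Separation is flagged, never silently swallowed.
* **Cox association**: per-SD HR from the Efron partial likelihood
  (`lifelines`), time-in-study scale, prevalent cases excluded.  Harrell's C
  of the linear predictor is attached with an infinitesimal-jackknife SE.
* **Harrell's C**: pairs are comparable when the member with the smaller
  time has an event; predictor ties count ½.  The IJ variance sums squared
  per-sample influences `U_i = (c_i − C·a_i)/D` of the ratio C = N/D with
  respect to a case weight on sample i, where `c_i`/`a_i` are the sample's
  concordance/comparability sums and D the number of comparable pairs.  The
  estimator is validated against a bootstrap SE on fixtures.
* **ΔC-index**: both Cox models are refit on every bootstrap resample
  (sample-level resampling with replacement, preserving each sample's
  (time, event) pair — the resampling scheme appropriate for right-censored
  data); the SE of the bootstrapped deltas gives a first-order normal CI
  and two-sided p around the full-data estimate (1,000 resamples default).
  Resamples without events are redrawn with a logged, capped retry.
  Bootstrap-loop fits use an internal vectorized Newton solver for the
  Efron partial likelihood (validated against `lifelines` to 1e-6,
  including tied times), because a full `lifelines` fit per resample is two
  orders of magnitude slower.
* **Absolute 10-year risk**: `risk = 1 − S₀(10)^exp(lp − l̄p)` with a
  Breslow-type baseline cumulative hazard at the mean-lp reference.  A PRS
  is integrated by refitting a two-predictor Cox model on
  [logit(clinical risk), standardized PRS] and recomputing absolute risk;
  pinning the PRS coefficient at zero yields the recalibrated-clinical null
  used in consistency checks.  This refit-with-logit-offset recipe is a
  documented stand-in where the published integration formula is not
  available; the interface isolates it so an alternative drops in.
* **Categorical NRI** at one threshold, computed separately in cases and
  non-cases; case NRI% = 100(up − down)/n_cases.  Outcome at the horizon
  uses the simple-count convention (censored-before-horizon non-events are
  non-cases); a Kaplan–Meier-weighted variant is available behind a flag.
  High-risk classification uses strict `>` at the NRI threshold.
* **Two-stage screening**: stage 1 selects strictly above its threshold
  (matching the guideline's ">5.6%"); stage 2 classifies high risk at `>=`
  its threshold within the screened set (the guideline text does not fix
  the comparison there; both are configurable).  NNS = screened /
  cases-among-screened and NNT = high-risk / cases-among-high-risk are
  exact integer ratios.  Protocol comparisons bootstrap ΔNNS/ΔNNT with
  normal-approximation CIs.

Prevalent and incident outcomes are analysed separately throughout
evaluation; only the meta-training outcome pools them, mirroring how such
scores are trained in practice.

## Numerical choices and degenerate inputs

Wald (not profile-likelihood) CIs for OR/HR; Efron tie handling in Cox;
strict arg-max CV selection with no one-standard-error rule; rank-deficient
PC matrices fall back to a minimum-norm least-squares solve with a logged
warning; zero-variance scores, all-censored outcomes, empty harmonization
intersections, and constant outcomes raise typed errors rather than
propagating NaN.

## Benchmark problem sizes

The packaged benchmarks run at: HR recovery — 500 replicates of n = 5,000
(150 variants); noise specificity — n = 10,000 with 5 informative + 15 noise
components; dominance — 50 replicates of n = 10,000 (800 variants, 5
sources with per-source GWAS n = 2,000, so single sources are individually
noisy and combination has headroom), 25-point λ paths; null calibration —
200 replicates of n = 2,000 plus one n = 10,000 AUC check; collapse
identity — K = 6 over 1,000 variants.  The published screening arithmetic
runs on vectors reconstructed exactly from the printed integer counts
(190,293 participants, 4,064 cases).

## Known limitations

The elasticnet CV shares one λ path per α across folds (glmnet behaviour);
fold assignment is stratified by outcome.  The IJ variance for C is a
first-order influence approximation and can differ from the bootstrap SE by
O(10%) at moderate n.  The collapse identity is exact only without PC
adjustment (see above).  The NRI bootstrap resamples outcome labels jointly
with risks, which is correct for the reported components but does not
propagate uncertainty in the underlying risk-model fits.
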