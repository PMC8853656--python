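# Methods

This note documents the models implemented in `methylpace`, the defaults
and why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions that matter for reproducibility.

## Pace of Aging composite

**Standardization.** Each biomarker is z-scored against the mean and SD of
its *baseline* (earliest observed) visit, then multiplied by its
orientation (+1 if an increase indicates deterioration, −1 otherwise).
Anchoring at baseline rather than pooled visits keeps slope units stable
as follow-up extends and matches the "decline from a young-adult
baseline" framing of multi-system aging studies. A zero baseline SD is a
hard error naming the biomarker. Standardization is idempotent after the
first pass.

**Growth models.** For each biomarker we fit, by full maximum likelihood,

    value ~ 1 + centered_age,  random intercept + random slope | subject

with age centered at the mean observed visit age (numerical conditioning;
the intercept is not used downstream). The random intercept and slope are
modeled as *independent*: the slope enters as a variance component rather
than a correlated random effect. With centered ages this is the natural
parameterization (centering decorrelates the two by design), and it makes
the slope BLUP take the closed shrinkage form

    BLUP_i = lambda * OLS_i + (1 - lambda) * fixed_slope,
    lambda = tau^2 / (tau^2 + sigma^2 / Sxx)

exactly in balanced designs — a property the tests exploit as an oracle.
Estimation uses statsmodels' linear mixed models (Powell optimization,
which converges reliably at these problem sizes). Two degenerate regimes
bypass the likelihood machinery: exactly linear trajectories (pooled
per-subject residual variance below 1e-12, where the ML problem is
singular) and optimizer non-convergence both fall back to a two-stage
estimator — per-subject OLS slopes, moment variance components, the same
closed-form shrinkage — and the fit object records `method="twostage"`
and the convergence flag. The two-stage path is also exposed directly
(`method="twostage"`) and is the recommended estimator for large
simulation sweeps: on balanced four-visit designs its BLUPs are
numerically indistinguishable from the ML ones at a tiny fraction of the
cost, so the end-to-end tests and the acceptance script use it for the
compositing stage.

**Compositing.** The raw composite is the sum of slope BLUPs over
biomarkers. Slopes missing for a biomarker are imputed with that
biomarker's cohort mean slope and counted; subjects missing more than half
the biomarkers are excluded and flagged. The composite is divided by its
cohort mean, so the published convention "cohort mean = 1" holds exactly
and ratios between subjects are preserved (a pace of 2 means twice the
average annual decline). A non-positive cohort mean raises a scaling
error rather than silently flipping signs — it almost always means
mis-configured orientations. Division (rather than an affine map) was a
genuinely open choice; it was picked because the phenotype is read as a
*rate ratio*, and it is surfaced as a parameter-free convention rather
than hidden rescaling.

## Probe reliability

Technical replicates are interchangeable aliquots, so the ICC is the
one-way random-effects, single-measurement (absolute agreement) form,
estimated by ANOVA moments: ICC = σ²_b/(σ²_b + σ²_w), with the
mean-replicate-count correction k₀ for unbalanced designs and Searle's
F-based 95% interval. Negative moment estimates are truncated to 0 and
flagged, preserving the [0, 1] semantics of the downstream filter. The
reliability filter is *strict* (ICC > threshold, default 0.4); boundary
behavior is unit-tested. Whether the original mixed-effects ICCs behind
published probe-reliability tables used ANOVA moments or (restricted) ML
is not specified there; the ANOVA estimator is used here and the
reliable-probe set is treated as an input, never a constant.

## Elastic-net training

Predictors are restricted to the reliable probe set, standardized
internally with training-set mean/SD, and fitted by coordinate descent
(scikit-learn) at mixing parameter α = 0.5. The penalty λ is chosen at
minimum mean cross-validated squared error over a log-spaced grid (40
points, spanning a 100-fold range below the data-driven λ_max — the
glmnet convention for n < p), with fold assignment deterministic given
the seed. The minimum-CV rule (not the 1-SE rule) is the default because
the target workflow reports a single selected λ; the grid and rule are
configurable. Coefficients are back-transformed to the raw beta scale so
the deployable artifact needs no stored scale parameters; only nonzero
weights are kept. Training uses raw betas while scoring uses
reference-normalized values — an asymmetry inherited from the deployment
design (the training cohort *defines* the reference distribution, so its
own values are already on the reference scale in distribution).

## Reference panel and scoring

The panel is frozen once, at training time: all algorithm probes plus
background probes drawn without replacement from the remaining universe,
stratified across deciles of training-set mean beta so the panel
represents the underlying beta distribution (simple random draw available
by flag; at panel size 20,000 the two differ negligibly, which the
background-draw robustness test quantifies). Each panel probe stores its
training-set mean beta; the sorted vector of these means is the
quantile-normalization target. Storing means rather than full quantile
vectors keeps the model artifact a pair of small CSVs.

Scoring a new matrix: align to the panel (missing probes become missing
rows), refuse samples with fewer than 80% of algorithm probes or 80% of
panel probes present (configurable; cross-array application makes probe
dropout routine), impute remaining missing values with reference means
*before* normalization (so each sample's rank vector is complete), then
per sample independently replace each value by the target value at its
within-sample rank. Ties receive the mean of the tied target positions —
computed by grouped summation over the sorted target, so untied values map
to target entries exactly, bit for bit. No jitter is added and no
randomness exists at scoring time; determinism outranks distributional
smoothness. Scores are not re-centered in the target cohort: the score
inherits the training scale, since normalization is *to the reference*,
not to the target cohort. The headline consequence, verified at
deployment scale (20,000 probes × 200 samples), is that any strictly
increasing per-sample transform of the input leaves scores bit-identical.

Model files round-trip losslessly: floats are written as `repr` decimal
strings and parsed with round-trip precision; loading validates that every
weighted probe is present in the panel and that the format version
matches.

## Physiology-based comparators

All comparators are panel-agnostic; references are fitted to whatever
training table is supplied (synthetic or user data). The classical
8-biomarker panel (albumin, log alkaline phosphatase, blood urea
nitrogen, log creatinine, log CRP, HbA1c, systolic blood pressure, FEV₁)
ships as named metadata with log-transform flags.

- **Klemera–Doubal biological age**: per-marker OLS of marker on age in
  the reference population gives (qⱼ, kⱼ, sⱼ); BA is the precision-
  weighted combination Σ(xⱼ−qⱼ)kⱼ/sⱼ² / Σkⱼ²/sⱼ². The non-augmented
  estimator is the default; the chronological-age-augmented variant
  (age as an extra term with variance s_BA²) is available by flag, since
  published implementations differ on this point. Residual SDs are floored
  at 1e-8 so exactly collinear synthetic markers cannot produce infinite
  precision weights.
- **Phenotypic Age**: a configured linear predictor over markers (and
  optionally age) is pushed through a Gompertz mortality CDF over a fixed
  horizon and inverted through an age-only Gompertz model back to years.
  Constants are configuration data, never hard-coded; the map is strictly
  increasing in the linear predictor, and risks numerically at 0 or 1 are
  clamped and flagged. When the two Gompertz shapes coincide, the age-a
  linear predictor is an exact fixed point (PhenoAge = a), which the tests
  use as the calibration oracle.
- **Homeostatic dysregulation**: log(1 + Mahalanobis distance) of a
  marker profile from the healthy-reference centroid under the healthy
  covariance. The healthy subset defaults to the youngest age tertile of
  the training table (configurable), since the originating literature does
  not pin the subset rule. The measure is invariant to affine marker
  rescaling when the reference is refit, and a numerically singular
  covariance is rejected with a suggestion to remove collinear markers.
- **Age acceleration** is the OLS residual of a measure on chronological
  age; **Cohen's d** uses the pooled SD with a normal-approximation CI;
  **Pearson r** uses the Fisher-z interval.

## Synthetic data: what it emulates, and what it does not

The cohort generator emulates a single-year birth cohort measured at four
visit ages (26, 32, 38, 45) on 19 biomarkers. A latent pace factor with
mean exactly 1 (by centering) and SD 0.29 drives subject-specific slopes:
biomarker B's slope for subject i is mean_slope_B + loading_B·(pace_i−1)
plus an idiosyncratic deviation. Mean slopes are drawn from 0.03–0.08
baseline-SD/year (≈ one baseline SD of deterioration over the two-decade
follow-up), loadings are proportional to the mean slope (0.5–1.5×),
visit-level noise is 0.3 baseline SDs, and the subject-biomarker slope
deviation is 0.01 SD/year. The single-latent-factor structure is a
modeling choice for testability — it makes the pace composite a
well-defined estimand — not a claim about the joint slope distribution in
any real cohort.

The methylation generator plants a sparse causal probe subset (50 of
2,000 by default) whose logit-scale values are linear in the latent pace,
with effect magnitudes ~0.3 (random sign, ±50% spread) and probe-level
noise SD 0.04, squashed through the logistic function so betas stay
strictly inside (0, 1). These two scales were calibrated once, jointly,
so that the generator supports the full invariant set the test-suite
asserts: ridgeless OLS on the causal probes alone recovers the latent
pace at r ≥ 0.9 (the oracle ceiling), the cross-validated elastic net
recovers ≥ 60% of causal probes with ≤ 5% null-effect false discoveries
on 10-seed averages, and held-out scoring recovers pace at r ≥ 0.6.
Passing an earlier run's `SimTruth` as `architecture` reuses the probe
universe, baselines and effects, which is how held-out samples share the
training generative model.

The replicate generator adds per-probe technical noise sized so the
between/total variance ratio equals a planted ICC, clips to [0, 1], and
*errors* if more than 1% of values clip — silent clipping would corrupt
the planted variance ratios. The distortion generator applies per-sample
strictly increasing maps (affine compression, logit shift, power) to
exercise the scorer's rank invariance.

None of the generators simulate probe-level genomic annotation, cell-type
composition, array chemistry (Type I/II designs), nonlinear trajectories,
time-varying covariates, or informative dropout. Passing tests therefore
demonstrate correctness of the estimators and the deployment contract
under the stated generative model, not performance on real arrays.

## Problem sizes and numerical conventions

Test-suite and acceptance-script simulations use cohorts of 40–500
subjects, 150–2,000-probe training matrices, and one deployment-scale
scoring check at 20,000 probes × 200 samples; end-to-end recovery is
averaged over 5 seeds in the acceptance script and 10 in the test suite.
All randomness flows from explicit seeds through numpy Generators; CLI
runs derive module-level substreams from a single `--seed`. Comparisons
asserted exactly (quantile-normalization oracle, rank invariance,
mean-one scaling at 1e-10 or better) are engineered to be exact, not
merely close: grouped summation in the normalization, division-based
scaling, and repr/round-trip float serialization.

## Known limitations

- The composite's SD is a cohort property; the generator's pace SD of
  0.29 propagates only partially through slope estimation noise, so the
  *scaled* composite SD in simulations (~0.12 at default noise) is not a
  target quantity.
- The mixed-model path assumes independent random intercepts and slopes;
  strongly unbalanced designs with intercept-slope correlation would need
  the correlated parameterization, which the two-stage fallback does not
  provide either.
- The elastic net's minimum-CV λ slightly over-selects at low
  signal-to-noise; the 1-SE rule is not implemented, only a configurable
  grid and rule hook.
- Scoring handles missing probes by reference-mean imputation, which
  biases refused-sample diagnostics conservative; no cross-array bias
  correction beyond the panel normalization itself is attempted.
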