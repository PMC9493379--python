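# Methods

## Model and prediction

An NTCP model is a logistic regression on the log-odds scale: linear
predictor `S = b0 + Σ b_j x_j`, risk `p = expit(S)`. The packaged dysphagia
model uses six predictors — four organ-at-risk mean doses in Gy (oral
cavity; superior, middle, inferior pharyngeal constrictor muscle) and two
binary indicators. Indicator coding is documented in the model spec
(`coding` field): tumour location 1 = pharynx / 0 = larynx, baseline
dysphagia 1 = grade ≥ 2. The protocol source prints single unit
coefficients for both indicators without stating reference levels, so the
coding is a declared, configurable convention rather than an inference.

Probabilities are clipped to `[1e-12, 1 − 1e-12]` inside likelihood
evaluation only, so a wildly mis-specified model (|S| ≈ 40) still yields a
finite log-likelihood; stored predictions are never clipped. Doses above a
configurable 80 Gy plausibility ceiling raise a warning, not an error —
they are implausible for mean doses to these organs but not impossible.

## The update hierarchy and the closed testing procedure

Four nested models are fitted on the validation cohort:

| level | free params | estimated |
|---|---|---|
| original | 0 | nothing (published model as-is) |
| intercept update | 1 | `alpha`, with `S` as fixed offset (slope ≡ 1) |
| logistic recalibration | 2 | `alpha`, `beta_cal` on `S` |
| revision | k+1 = 7 | intercept + all coefficients |

All fits are binomial GLMs (statsmodels IRLS, tolerance 1e-8 on the
deviance change, max 100 iterations). Non-convergence, perfect separation
(detected by statsmodels or by runaway coefficients |b| > 10³) and rank
deficiency (QR check, offending columns named) are explicit
`FitFailureError`s, never silent. Log-likelihoods of all four levels are
computed with the same clipped Bernoulli formula, which guarantees the
nesting chain `ℓ_original ≤ ℓ_intercept ≤ ℓ_recal ≤ ℓ_revision` up to
optimizer slack (1e-6).

The closed testing procedure tests, in order, original vs revision
(df = 7), intercept update vs revision (df = 6), logistic recalibration vs
revision (df = 5), each by a likelihood-ratio test `X² = 2(ℓ_c − ℓ_s)`
(floored at 0 with a warning when optimizer noise makes it marginally
negative). The walk stops at the first non-significant test
(default `alpha_sig = 0.05`) and selects that simpler level; if all three
reject, the revision is selected. Anchoring every test at the revision is
what makes the procedure *closed* — the original model survives only if it
is not rejected against the most flexible alternative, which controls the
family-wise type-I error of "updating when no update is needed" at
`alpha_sig`. A `stepwise` ordering (each level against the next) is
available as a config option for comparison with sequential-testing
practice; the default is the closed tree. All three tests are always
computed and reported; tests past the stopping point are flagged
`used: false`.

The Monte-Carlo harness (`ctp_selection_frequencies`) verifies the two key
operating characteristics: under the null (data generated from the
evaluated model) the original is retained in ≈ 95% of replicates, and each
departure class (intercept shift / slope shrinkage / coefficient change)
drives selection to its minimal sufficient level with probability growing
in n.

## Performance metrics

**AUC** is the Mann–Whitney concordance `P(p_event > p_nonevent) + ½P(tie)`,
computed via midranks (exactly the exhaustive-pair value). The default
confidence interval is DeLong's asymptotic-variance Wald interval,
truncated to [0, 1]; a seeded stratified bootstrap (2000 resamples,
percentile) is available. **Sensitivity/specificity** classify
`p ≥ threshold`; no universal threshold convention exists for this metric
in external validation, so the default is 0.5 with a Youden-optimal option,
and the threshold used is always reported.

**Brier score** is `mean((p − y)²)`. The **Hosmer–Lemeshow** statistic
sorts patients by predicted risk into `g = 10` near-equal groups and
compares observed with expected event counts;
`X² = Σ (O−E)²/E + (O−E)²/(n−E)` per group, groups with degenerate
expected counts merged into a neighbour with a warning. The reference
distribution is chi-square with `g − 2` df by default — the convention the
field reports — but note that `g − 2` is strictly the *in-sample fitting*
calibration; for externally fixed predictions the correct null df is `g`,
and the df is configurable. The test suite checks null p-value uniformity
at df = g.

The **flexible calibration curve** is a lowess (locally weighted linear)
regression of outcome on predicted probability, span 0.75, evaluated on a
101-point grid over the observed prediction range and truncated to [0, 1].
Robustness iterations are disabled: Bernoulli residuals are not
outlier-contaminated, and down-weighting them would bias the curve.
Fewer than 20 observations or constant predictions are refused (no stable
smoother exists there). The **E-statistics** are per-patient absolute
differences `d_i = |p_i − ĉ(p_i)|` with `ĉ` linearly interpolated from the
curve grid: Emax = max, Eavg = mean, E90 = 90th percentile
(linear-interpolation quantile). Because lowess is locally *linear* and a
calibrated model has the linear relation `E[y|p] = p`, the smoother is
essentially unbiased under the null and the E-statistics converge to 0.

`validation_report` assembles, per update level, the discrimination
summary, calibration summary, calibration curve and (downsampled) ROC
polyline into one JSON document that embeds the resolved configuration and
seed; plots are derived from the report JSON alone, never the other way
round. The report is byte-deterministic given cohort, model and config.

## Synthetic cohort generator

The generator emulates the structure of a 277-patient head-and-neck
validation cohort; its defaults are the study conditions, not tuning knobs:

* modality mix 204/59/14 (photon / photon+chemo / proton) out of 277;
* dose marginals per arm (mean, SD in Gy): photon — oral cavity 33.2/15.4,
  PCM superior 55.5/17.7, PCM medium 50.2/17.4, PCM inferior 38.2/19.9;
  proton — 24.1/11.9, 35.1/8.3, 41.2/12.6, 37.5/17.9 (the photon+chemo arm
  shares the photon marginals — no separate marginals are published);
* pharynx prevalence 0.68; baseline-dysphagia prevalence 0.15 (the
  development-cohort value 0.25 is available as
  `DEVELOPMENT_BASELINE_PREVALENCE` to emulate the case-mix shift between
  development and validation populations);
* truth model defaulting to the packaged NIPP model, distorted by a
  `MiscalibrationSpec`: outcome probability `expit(γ·S + δ)` after
  coefficient overrides — δ is what re-calibration in the large corrects,
  γ what logistic recalibration corrects, overrides what only a revision
  corrects.

Doses are drawn from a **Gaussian copula**: an equicorrelated latent
standard normal vector (common ρ, default 0.4 — only marginals are
published, but anatomy makes neighbouring-organ doses positively
correlated, which is exactly what stresses a revision fit realistically) is
mapped through Φ to uniforms and then through the inverse CDF of each arm's
normal distribution truncated to [0, 80] Gy. This construction is chosen
over accept–reject truncation deliberately: the marginals are *exactly*
truncated normals (so moment checks have a closed-form scipy oracle and no
resampling loop or clipping fallback exists), doses can never be negative,
and the only approximation is a small attenuation of the Pearson
correlation through the monotone marginal transform (verified < 0.05 at
n = 100 000 for ρ ≤ 0.8). With the default (mild) truncation the realised
dose means sit up to ≈ 3 Gy below the nominal normal means for the
highest-dose organ; the truncated-normal moments are the generator's
declared targets.

Draw order is fixed and documented (modality, latent dose normals, tumour
location, baseline dysphagia, outcome), PRNG is numpy's default PCG64, so
a recipe (including its seed) determines the cohort byte-for-byte across
platforms. Monte-Carlo replicates derive per-rep seeds from the master
seed via `SeedSequence.generate_state` (counter-based): replicates are
independent and individually reproducible.

With the default recipe and the packaged model as truth, the implied event
rate is ≈ 44% (self-consistency of the generative law is tested at 3 MC
standard errors). The real validation cohort's 31% event rate is
reproducible by recipe adjustment (e.g. an intercept offset in the truth
model); the default keeps the published model *exactly* calibrated on the
synthetic population, which is the null the closed-testing properties are
defined against.

What the generator does **not** emulate: dependence of doses on tumour
location or stage, baseline-by-location dependence, inter-observer
variability in toxicity scoring, longitudinal trajectories, and
dose-volume-histogram structure beyond the mean dose. Passing tests
therefore demonstrate the statistical machinery under a plausible joint
law, not transportability to any real cohort.

## Problem sizes and numerical choices

The Monte-Carlo studies use n = 1000 × 300 reps (null error control) and
n = 3000 × 200 reps per departure class; parameter-recovery checks use
100 replicates at n = 50 000 and 25 at n ∈ {500, 5000}; generator moment
checks use n = 100 000. These sizes put Monte-Carlo standard errors well
inside the asserted margins (e.g. binomial SE ≈ 1.3% at 300 reps against a
3-point margin) while keeping a full run in the minutes range on one CPU.

Ties in AUC are handled by midranks; the E90 quantile uses linear
interpolation between order statistics; Hosmer–Lemeshow group boundaries
use a stable argsort so tied predictions split deterministically. The
degenerate all-ties DeLong variance is 0 and the interval collapses to the
point estimate by construction.

## Known limitations

* The revision fit is unpenalised maximum likelihood; with few events it
  will overfit, and the package deliberately does not implement shrinkage
  or model extension with new predictors.
* The closed tree controls the error of *unnecessary updating*; it does not
  quantify the optimism of the selected revision, which requires a further
  independent validation.
* Multi-level (grade-specific) outcomes, time-to-event structure, missing
  data handling and DICOM dose extraction are out of scope; cohorts are
  complete-case by contract.
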