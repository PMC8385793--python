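# Methods

## The estimand and model chain

The pipeline estimates sex-stratified adjusted relative risks (aRR) of
screened neurodevelopmental delay per 1 SD of conditional growth. The
stages, in order:

1. **Timeline alignment.** Checkup measurements are taken near, not at,
   the nominal ages, so raw length/weight are carried to target ages
   (defaults birth = 0, 122, 213, 304 days; 4/7/10 months at 30.4375
   days/month, rounded) by piecewise-linear interpolation between the two
   flanking observations, or linear extrapolation from the nearest two
   when the target lies outside the observed range. A value is produced
   only if the nearest observation is within a window of the target
   (default 92 days, configurable); a lone observation passes through
   only within ±1 day. Interpolation runs on raw cm/g *before* z-scoring:
   over spans of ≤ 3 months linearity is the standard assumption, and it
   makes the affine-exactness property testable. Note that with the
   92-day default, a child with 4- and 10-month checkups has both flanks
   within the window of the 7-month target, so the 7-month value is
   interpolable even without a 7-month checkup; model samples are
   consequently nested (see "model variants").

2. **LMS z-scoring.** z = ((x/M)^L − 1)/(L·S), with the log-limit form
   for |L| < 1e-7; the implementation uses `expm1`/`log1p` so the forward
   and inverse transforms round-trip to 1e-10 across L ∈ [−2, 2].
   Reference rows are keyed by sex, measure and age; birth rows are
   additionally stratified by parity and completed gestational week
   (floor of gestational age — the convention of such newborn tables).
   Age lookup takes the nearest tabulated row within ±15 days, otherwise
   interpolates L, M, S linearly between flanking rows. The published
   national standards are not redistributable, so the package generates a
   **synthetic** reference table: median curves M(t) = a + b(1 − e^(−t/τ))
   with birth ≈ 49 cm/3.05 kg (boys) rising to ≈ 71 cm/8.8 kg at 10
   months, CV declining with age (length ≈ 0.040 → 0.034, weight
   ≈ 0.118 → 0.105), fixed powers L = 1 (length) and 0.35 (weight), and
   birth medians shifted ≈ 0.9 %/week (length) and 5.5 %/week (weight) of
   gestation plus a small parity effect. Any user table in the same CSV
   schema is accepted.

3. **Conditional variables.** OLS with intercept, fit per sex stratum on
   the complete cases of a model variant; residuals standardized to unit
   sample variance so each aRR is per 1 SD (the underlying method uses
   standardized conditionals; standardization also makes the variables
   scale-invariant). Rank-deficient designs and too-small samples raise;
   a perfect fit degenerates to all-zero residuals with a warning.

4. **ASQ-3 scoring.** Items score yes = 10 / sometimes = 5 / not yet = 0;
   domain = item sum (0–60). Cutoff per domain and outcome age =
   reference-sample mean − 2·SD (n−1 denominator, no flooring, pooled
   across sexes, derived from all children with a score at that age).
   Delay = any domain **at or below** its cutoff. A domain with any
   unanswered item is treated as absent by default (no prorating; a
   `prorate=True` flag provides the instrument-manual mean×6 adjustment).
   A child with all five domains absent has an absent delay outcome.

5. **Risk models.** Log-link Poisson-family GLM on the binary outcome
   (IRLS, relative tolerance 1e-10, max 100 iterations); point estimates
   equal Poisson ML; standard errors scaled by √(Pearson χ²/df)
   (quasi-Poisson); 95 % Wald intervals with z = 1.96. Covariates:
   maternal age (linear, in years), maternal smoking, maternal and
   paternal education (reference junior high), family income (reference
   low), home speech stimulation. Complete-case per model; dropped-row
   counts are retained. With a single binary regressor the fit reproduces
   the closed-form risk ratio exactly; near-separated cells yield huge
   SEs and an honest infinite upper CI bound plus a warning.

### Model variants

Which checkups a child's data resolve determines the exposure set:

| variant  | timepoints (months) | note |
|----------|---------------------|------|
| `birth4` | 0, 4                | used for all 6-month outcome models |
| 1        | 0, 4, 7, 10         | complete first-year trajectory |
| 2        | 0, 4, 7             | 10-month data not required |
| 3        | 0, 4, 10            | 7-month not required; 10-month conditionals regress on birth + 4 months only |

Each variant is fit on its own complete-case sample, so the samples are
nested supersets (variant 2 ⊇ variant 1, etc.), and variant 3's 10-month
conditionals are *different variables* from variant 1's even on shared
children. `run_model_grid` produces 2 sexes × 4 tables × (total + 5
domains), with per-column events/n.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not any real cohort's joint distribution. One integer seed drives a fixed
`SeedSequence` split (one stream per stage), so equal seeds give
byte-identical cohorts. Defaults (the generator's standard conditions):

* n = 86,805 children; 51.0 % boys; gestational age truncated-normal
  39.4 (SD 1.1) on [37, 42) weeks; multipara 51.7 %; smoking 14.5 %;
  education/income/speech-stimulation marginals as in a large Japanese
  term-birth cohort's complete-data column; maternal age 31.4 (SD 4.8).
* Latent z-score trajectories: 8-dimensional multivariate normal over
  {length, weight} × {0, 4, 7, 10 mo} with a documented plausible
  correlation matrix (post-natal autocorrelations 0.80–0.85,
  length–weight ≈ 0.55–0.72 at the same visit, birth–infancy 0.30–0.55).
  No cohort reports this matrix; it is a default, not an estimate.
* Raw measurements: latent z inverted through the synthetic LMS table at
  the child's actual (jittered, ±10 days uniform) checkup age, rounded to
  0.1 cm / 1 g.
* Delay: generated on the **log-risk scale**, p = baseline ×
  exp(Σ log RR_v · c_v), where c_v are the *population* conditional
  variables (computed exactly from the correlation matrix, unit
  variance), so the quasi-Poisson estimand equals the configured RR with
  no link mismatch. Baselines: boys/girls 8.9/8.5 % at 6 months and
  16.9/12.6 % at 12 months. Probabilities outside (0, 1) raise a
  configuration error naming the offending age/sex.
* Questionnaire items are sampled *backwards* from the drawn delay flag:
  unimpaired domain scores are 60 − 5·Bin(4, 0.35) (support 40–60), a
  delayed child's randomly chosen domain is forced to 5·Bin(2, 0.30)
  (support 0–10). Because the derived cutoff (mean − 2 SD) lands in the
  (10, 40) gap at any realistic prevalence, the scored any-domain flag
  equals the drawn indicator exactly for every complete questionnaire —
  regardless of which subsample the cutoffs are derived from.
* Missingness last, missing-at-random given covariates: per-checkup
  marginal rates 16.1/63.3/42.1 % (4/7/10 mo), questionnaire 4.4/9.0 %
  (6/12 mo), with log-odds tilts toward multiparity (+0.40), smoking
  (+0.30), low education (+0.25) and low income (+0.15); the intercept is
  calibrated by bisection on the generated sample so the marginal rate is
  hit exactly. Small MCAR covariate and item-level missingness; 0.3 %
  missing basic birth data; 1.0 % multiple births and 3.5 % malformation
  flags feed the eligibility cascade.

What the generator does **not** emulate: regional/center structure, true
joint covariate dependence beyond the missingness tilt, questionnaire
item psychometrics (items within a domain are decomposed from the domain
score by a fixed pattern), measurement error in the anthropometry beyond
rounding and checkup-age jitter, or informative (outcome-dependent)
missingness. Passing tests therefore demonstrate the *estimator chain* is
correct and calibrated under these conditions — not that any real
cohort's printed effect estimates are reproduced, which restricted data
make impossible at desk scale.

## Problem sizes used in tests

Recovery and null-calibration checks run the full pipeline on 20 seeded
cohorts of n = 50,000 each (the scale at which the configured RR 0.85 is
comfortably inside its own CI), with the boys' 6-month model as the
testbed; correlation-convergence uses one n = 100,000 draw; the remaining
unit tests use cohorts of ≤ 8,000.

## Numerical and design choices

* Wald CIs (z = 1.96), not profile likelihood — standard quasi-Poisson
  practice.
* Cutoff SD uses the n−1 denominator (immaterial at reference-sample
  sizes, declared for reproducibility).
* Pearson χ² without continuity correction for phi/Cramér's V, and the
  pooled-variance (classic Student) t behind the point-biserial r; both
  reproduce published two-decimal balance effect sizes exactly. Reported
  values are rounded half-up to 2 decimals.
* Conditional variables could in principle be left unstandardized; the
  per-SD scale was chosen so aRRs are comparable across variables.
* Residualization per sex stratum, consistent with fully sex-stratified
  outcome models.
* Coverage checks: per-exposure CI-coverage demands (≥ 18/20 at nominal
  95 %) fail by binomial chance ≈ 7.5 % per exposure, so the null check
  asserts the headline exposure per-term and ≥ 90 % pooled across the
  four exposures; empirical estimate spread matches the Wald SEs.

## Known limitations

* The two-point linear timeline is deliberately simple (no splines, no
  growth-curve models); curvature between birth and 4 months interacts
  with checkup-age jitter to add a little noise to the 4-month z-score,
  a mild attenuation absorbed well within the recovery tolerances.
* The synthetic LMS table is a stand-in: z-scores computed with it are
  internally consistent but not comparable to published standards.
* Quasi-Poisson on binary outcomes yields dispersion < 1 (≈ 1 − p̄);
  alternatives (log-binomial, robust-sandwich Poisson) are out of scope.
* No imputation anywhere: every model is complete-case, so estimates are
  consistent under missing-at-random given the modelled covariates only.
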