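# Methods

This note records the statistical model, the generator that stands in for
unshareable EHR data, and the design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Study design being emulated

A retrospective matched cohort: adults (18+) registered with a GP for at
least 90 days before the study start (1 November 2020) are eligible. People
with a first long COVID diagnosis code define the exposed group; their
diagnosis date is the index date. Each exposed person is matched without
replacement to up to five comparators with identical integer age, sex and
region who are registered, alive and undiagnosed at the index date, which
they inherit. Follow-up runs from the index date to the earliest of death,
deregistration, a resolved-condition code (exposed), the comparator's own
later diagnosis, the administrative end (31 January 2023) and index + 365
days; intervals are half-open and day counts are `end − start`. The
historical comparison uses the fixed pre-pandemic year
[2019-03-01, 2020-03-01) for members registered since before that window.

Outcomes per person-period: per-care-type visit counts with same-day
deduplication *within* care type (several prescriptions on one day are one
visit; a GP visit and an A&E visit on the same day are two), admissions
counting only when discharge is after admission; and costs assembled as
GP visits × £41, prescriptions at raw (non-deduplicated) chapter frequency
× chapter unit cost, and recorded per-event secondary-care costs. The two
frequency conventions — deduplicated visits but raw prescription counts for
costing — are both implemented exactly as stated in the source convention
they follow, although they differ.

## Two-part model

Counts and costs are zero-inflated and right-skewed, so each outcome is
modelled in two parts:

- **Part 1**: logistic regression of `1(outcome > 0)` on exposure plus the
  adjustment set (age band, sex, ethnicity, IMD quintile, region, asthma,
  mental health, comorbidity level, prior COVID hospitalisation, vaccine
  doses). No person-time offset enters this part: an offset on the logit
  scale has no person-time interpretation. Missing ethnicity/IMD/BMI are an
  explicit `missing` category by default (complete-case analysis would
  discard a double-digit percentage of rows for ethnicity alone).
- **Part 2 (counts)**: zero-truncated NB2 regression, log link, offset
  `log(person-years)`, fitted on the rows with a positive outcome. The
  family is chosen by the ratio of residual deviance to residual degrees of
  freedom from a Poisson GLM on the same rows: above 1.0 (configurable) the
  NB2 is used, otherwise the truncated Poisson. NB2 rather than NB1 because
  it is the conventional "negative binomial regression" in the health-
  utilisation literature. α is estimated jointly on the log scale; the MLE
  uses BFGS with the analytic score, a gradient-norm tolerance of 1e-8
  (falling back to a Nelder-Mead polish and accepting 1e-4 when line
  searches stall on flat likelihoods), initialisation from an untruncated
  Poisson fit with a moment estimate of α, and covariance from the observed
  information (numerical Hessian at the optimum). An α estimate below 1e-4
  is treated as the Poisson boundary: a warning is emitted and the model is
  refitted as truncated Poisson. The log-pmf is written through `log1p`
  throughout and switches to a summed `log1p` representation for α < 1e-5,
  where the `gammaln(y + 1/α) − gammaln(1/α)` form cancels catastrophically.
- **Part 2 (costs)**: log-link Gamma GLM with the same offset on rows with
  positive cost; the dispersion is estimated by Pearson χ², and the shape
  is its reciprocal.

A categorical level present in the cohort but absent from the positive
rows a part-2 fit conditions on has no identifiable coefficient; such
dummy columns are collapsed into the reference level for that fit, with a
warning, rather than aborting.

Wald intervals on the log scale throughout. Standard errors do not account
for matched-set clustering in the coefficient tables (the generator draws
person-periods independently given covariates, so they are correct under
the simulated conditions); absolute-scale uncertainty uses the cluster
bootstrap below, which does respect the design.

## Predictions and DID

Predicted averages use marginal standardisation: exposure (and period, in
DID fits) is set counterfactually for every person, part 1's probability is
multiplied by part 2's conditional mean at a one person-year offset —
μ/(1 − f(0; μ, α)) for truncated counts, the fitted mean for Gamma — and
the product is averaged over the cohort's covariate distribution.
Percentile CIs come from a cluster bootstrap that resamples matched sets
with replacement and refits both parts; the CI method for predicted means
was not prescribed by the design being emulated, so the percentile cluster
bootstrap is this package's choice, as is reporting predictions per
person-year. The bootstrap raises if more than 5% of replicates fail.

The DID fit adds period and group×period terms to both parts and reports
(a) the interaction coefficients and (b) the absolute-scale contrast of the
four standardised predicted means; the headline DID estimate is (b). The
common-trend assumption is probed descriptively by binning pre-period
visits per person-year by calendar time and group.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the package's
study conditions and were fixed once:

- Cohort structure: `n_exposed` = 2000 by default with a 10× undiagnosed
  pool, exact-age matching leaving most sets complete (just under five
  comparators per exposed on average, mirroring the near-complete 1:5
  pattern of the emulated study). Covariate marginals default to the
  published cohort's counts (`COHORT_REFERENCE_COUNTS`), drawn
  independently per factor — only marginals are published, so no joint
  structure is modelled. BMI marginals are internally inconsistent as
  printed in the source table and are replaced by a generic adult
  distribution; BMI is excluded from worked-example checks.
- Utilisation: one person-level hurdle per observation window
  (p = 0.95 exposed / 0.70 comparator, an any-use odds ratio of ≈ 8.1,
  the magnitude reported for the emulated cohort), then a zero-truncated
  NB2 *total* count with α = 0.8 and a comparator latent rate of 16
  visits/person-year (base_rate 3.2 per care type × 5 types), multiplied by
  exp(covariate effects), by the persistent rate ratio 1.49 for exposed
  windows, and by exp(0.357) for exposed contemporary windows (the DID
  shift, log of the published 20.48 → 29.28 increase). The total is
  allocated multinomially across care types (GP 35%, prescriptions 40%,
  outpatient 20%, A&E 3%, admission 2%) and dates scattered uniformly.
  The hurdle-on-the-total form keeps the two-part estimator correctly
  specified, so recovery tests have exact closed-form truths
  (`GroundTruth.implied_estimands`); a sum of independent per-type hurdle
  draws would not be hurdle-distributed in total. The published
  supplementary material quantifies neither the empirical dispersion nor
  the zero fraction, so α and the hurdle probabilities are realistic free
  choices, not calibrated claims.
- Costs: secondary-care events carry Gamma(shape 2) costs with comparator
  means £160 (A&E), £2,600 (admission), £140 (outpatient), multiplied by
  1.44 for exposed events; 2% of secondary costs are blanked (the reported
  missingness scale). GP and prescription costs are assembled downstream
  from unit costs, so the *conditional total-cost ratio* implied by the
  generator is a composite (≈ per-visit cost ratio × conditional count
  ratio), which `implied_estimands` computes exactly.
- Roles and windows: about 0.2–6% of comparators (depending on pool size)
  are people diagnosed later; their comparator spell is censored at their
  own diagnosis. Event streams are generated per analysis window with
  role-specific rates — a pre-diagnosis comparator spell uses comparator
  rates, the same person's own follow-up uses exposed rates — except for
  the shared historical window, where the latent (ever-diagnosed) rate is
  used; this contaminates comparator historical rows by a few percent of
  members, a small, realistic bias that recovery tests absorb within their
  Monte-Carlo tolerance.

What the generator does **not** emulate: coding-practice variation,
calendar epidemic waves, seasonal utilisation, joint covariate structure,
within-person correlation of the hurdle across periods, or time-varying
vaccine status (index-date values are reused in both DID periods). Passing
recovery tests therefore show that the estimator chain is correct under
its own assumptions, not that those assumptions hold in real EHR data.

## Numerical and procedural choices

- Date intervals half-open; all randomness flows from explicit seeds
  (simulation, matching tie-breaks, bootstraps), so identical
  configuration reproduces byte-identical outputs.
- Matching processes exposed people in ascending index-date order with
  seeded uniform tie-breaking among eligible candidates; sets with 1–4
  comparators are retained; exposed with no candidate are dropped and
  counted. Censoring-date ties resolve by the precedence death >
  deregistration > resolved code > comparator diagnosed > administrative
  end > window end.
- Descriptives: chi-square without continuity correction, Welch t-test for
  age (pooled optional); percentages are column percentages recomputed
  from counts at one decimal.
- Missing-cost imputation uses the care-type-specific mean of observed
  per-event costs ("mean cost per visit" read as the per-event mean,
  computed across people, not within person).
- Stratified analyses fit group×stratum interactions; stratum effects are
  linear combinations of coefficients, and effect modification is tested
  with a likelihood-ratio test per part, df = levels − 1.
- The deviance-based family check sits exactly at threshold 1.0 by
  default; equidispersed data therefore select NB2 roughly half the time
  with a near-zero α, which the boundary fallback turns back into the
  truncated Poisson.

## Problem sizes used in the test suite

Recovery checks run at roughly 20,000 analysis rows (3,500 exposed), CI
coverage at 100 replicates of ~2,000 rows, null-calibration LRT size at 50
replicates of ~1,400 rows, and the bootstrap-behaviour and null-overlap
checks at a few hundred to a few thousand rows with 30–60 bootstrap
replicates; these sizes give Monte-Carlo error comfortably inside the
3-standard-error tolerances the tests assert while keeping the default
suite quick to run.

## Known limitations

- No set-level random effects or GEE-style robust coefficient SEs; the
  cluster bootstrap is the only design-respecting uncertainty measure.
- No zero-inflated (mixture) alternative to the hurdle; no delta-method
  intervals for predicted means.
- Same-day deduplication makes observed counts a slightly thinned version
  of the generator's latent totals (well under 1% at default rates); the
  thinning is group-differential only through the rate ratio and is far
  inside the recovery tolerances.
- Prescription costing assumes every chapter present in the events appears
  in the unit-cost table; there is no inflation adjustment across years
  and no per-specialty outpatient tariff.
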