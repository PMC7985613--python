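# Methods

## Study design being emulated

The package reproduces, on synthetic data, the analysis design of a
population-based interrupted time series of weekly primary-care contacts
around the introduction of UK COVID-19 restrictions: a pre-lockdown period
(January 1 2017 – March 7 2020), an adjustment-to-restrictions window
whose data are excluded (March 8–28 2020, chosen because population
behaviour was already changing before the announcement), and a
with-restrictions period (March 29 – July 18 2020). Self-harm uses a
shortened pre-lockdown period starting January 1 2019 (a per-condition
override).

All weekly aggregation uses consecutive 7-day blocks anchored on Sunday
January 1 2017. The period boundary dates above all fall on Sundays of
this grid and July 18 2020 is a Saturday, so every analysis period is a
whole number of grid weeks: 166 pre-lockdown, 3 excluded, 16
with-restrictions (185 in total).

## The synthetic-data generator

`carecontacts.synthetic` is the package's data source and truth oracle.
It emulates:

* **Demographics** — age band, sex, region (11 UK levels) and ethnicity
  drawn from the margins of a ~9.9-million-person UK primary-care
  denominator population (stored as 2017 counts, normalised at run time).
* **Registration churn** — an annual deregistration probability (default
  0.05/year) drives exponential spell lengths, conditioned on spells
  overlapping the study calendar; a churn-proportional share of patients
  registers during the study, exercising the 1-year run-in rule.
* **Birth dates at year resolution** — materialised as July 1 of the birth
  year, mirroring de-identified EHR precision. Ages everywhere are
  computed as completed years at the week start under this convention.
* **Chronic conditions** — dated diagnosis codes for diabetes, asthma,
  COPD and smoking history (default prevalences 5.6%, 9%, 2%, 25% —
  UK-plausible adult figures), placed at registration for prevalent cases
  (70%) or at a uniform onset otherwise, so denominator-entry-at-first-code
  logic is exercised. Asthma receives roughly annual follow-up codes (80%
  per year) so currency windows lapse and re-open.
* **Contact processes** — for each week a person is registered, a
  Bernoulli draw with probability `logistic(eta_t)` where

  `eta_t = baseline + trend*t + season(month) + [t >= t0](step + slope*(t - t0)) + eps_t`

  and `eps_t` is optional AR(1) noise on the logit scale, initialised at
  its stationary distribution and indexed by true calendar week (so
  non-contiguous requests keep the right correlation structure). The
  oracle (`eta_t`, `p_t`) is exposed with every simulated series.

At most one synthetic contact per person-week is generated, matching the
binomial "proportion of the population with contacts" outcome the models
fit. Real within-week contact multiplicity is unknown to us; this cap is a
modelling choice users should be aware of when comparing against real
data.

Two modes exist: full individual-level tables (patients, clinical events,
prescriptions), and a fast aggregated mode drawing weekly binomial counts
directly. Statistical validation uses the aggregated mode at study scale
(denominator 10⁶); the individual-level mode exercises the cohort and
extraction machinery. In individual-level mode the pipeline multiplies the
per-person weekly contact probability by a configurable factor (default
50) so panels of a few thousand simulated patients produce countable
weekly events; odds-ratio effects are unaffected by this scaling.

**Default scenario parameters** (in `carecontacts.scenarios`) anchor each
condition's baseline weekly contact rate and step odds ratio to the
published study-scale estimates for that condition; weekly recovery odds
ratios follow the published 1–2% (mental health) and 3–5% (alcohol,
unstable angina) ranges, with 2% elsewhere. Two values are derived rather
than printed: the COPD step (ratio of published with/without expected
weekly contacts, ≈0.54) and the asthma recovery (≈0.987/week, derived from
the two published snapshot ratios, which show asthma contacts falling
further below expectation over time). Default noise is seasonal amplitude
0.1 logit and AR(1) sigma 0.05, rho 0.3.

## Cohorts and phenotyping

Eligibility is evaluated at the week-start instant: a patient is in a
week's denominator iff at week start they meet the age minimum, have ≥1
year of registration, are alive and registered (a mid-week death or
deregistration still counts that week), and satisfy the chronic criterion.
Specific choices where the underlying rules are ambiguous:

* A chronic/smoking code dated exactly on the week start counts for that
  week (consistent with entry "from the date of the first record").
* Asthma currency: a week counts iff some asthma code satisfies
  `code <= week_start < code + window`, window 2 years when aged <18 at
  the week, 3 years otherwise. Whether the boundary week is inside the
  window is not specified by the source rules; the strict (`<`) reading is
  used. Records in patients aged ≥40 at the record date are discarded when
  a COPD code follows within 2 years; because this looks forward,
  eligibility is computed retrospectively over the full record.
* "Evidence of a smoking history" is any smoking code at or before the
  week start.
* Heart failure's "first ever" rule is an outcome rule; its denominator is
  simply all adults ≥31.

Episode deduplication uses a greedy transitive chain: a record starts a
new episode iff its gap from the immediately preceding record exceeds the
window, boundary inclusive (gap == window merges). The episode date is the
first record's date (onset). This is verified in tests against an
exhaustive merge-until-fixpoint partition oracle. Composite exacerbation
outcomes require a qualifying prescription within ±`co_occurrence_window`
days of the morbidity code (default 0 = same day, the conservative reading
of same-consultation prescribing); for COPD a prescription only qualifies
as *new* when no same-class issue occurred in the prior 28 days
(configurable). First-ever outcomes emit nothing when the first-ever
record precedes the study, and pre-study records chain with (and can
absorb) early in-study records.

Mixed anxiety-and-depression codes are counted in both the anxiety and the
depression outcome, as the condition definitions group them under both.

## Estimation

`fit_its` fits count/denominator with denominator weights in a binomial
GLM (logit link) in two stages: (1) fit trend + step + recovery
interaction + month dummies; (2) append the lag-1 residual (deviance by
default; Pearson/response configurable) over retained rows in week order —
the exclusion gap is bridged, the first row's lag is 0 — and refit. The
Pearson dispersion `phi` of the final fit scales standard errors by
`sqrt(phi)` when `phi > 1`, never deflating them. Confidence intervals are
Wald with z = 1.96. The time index is centred at the last pre-lockdown
week so the step coefficient is the contrast quoted in reports: start of
the with-restrictions period vs the end of the pre-lockdown trend. A
near-perfect stage-1 fit (residual range < 1e-6) skips the lag refit;
non-convergence, non-finite estimates or degenerate standard errors raise
a diagnostic error naming the condition.

Both `exp(delta)` (slope change) and `exp(beta1 + delta)` (net weekly
trend under restrictions, delta-method CI) are reported; the headline
recovery measure in this package's outputs is the net weekly odds ratio,
since "the weekly odds of contact during the with-restrictions period" is
most naturally the combined trend. Which of the two a given report quotes
is not always stated, so both are emitted.

`fit_poisson` refits the same design as a log-link Poisson count model
with a log-denominator offset (so expected contacts per million are
`1e6 * exp(x'beta)` regardless of denominator size). The no-restrictions
counterfactual zeroes the step, the recovery interaction and the
lagged-residual path — a world without restrictions leaves no channel for
any of them. Weekly differences (without − with) and the cumulative sum
from March 29 are reported per million persons. Presentation follows
disclosure conventions: 3 significant figures (space-grouped at five or
more digits), censoring below a per-condition threshold (10 for rare
conditions, 100 otherwise) as `<T`, and negative differences (excess
contacts) as `>-T`.

The sensitivity grid refits each condition under seven period
definitions: the main design; 5- and 7-week exclusions with the March 7
pre-period end; and 0/3/5/7-week exclusions with the pre-period ending
March 21 (the announcement week).

## Published outputs

Weekly series for publication pass through small-cell suppression: counts
of 1–4 are masked (distinguishable from true zeros via a flag), counts of
0 and ≥5 are shown. Model fitting always uses unsuppressed counts.
Historical (2017–19) averages are computed per ordinal week-of-year on the
Sunday grid, with mean, median and IQR all emitted since different
displays use different summaries.

## Problem sizes and numerical choices

Statistical tests and the acceptance script use the aggregated mode at the
study's own scale — 182 analysed weeks, denominator 10⁶ — with 20
replicates for parameter-recovery checks, 100–200 for bias/lag checks and
500 for null calibration; each replicate fits in milliseconds, so the full
suite runs in well under a minute of compute. Seeds are derived from a
single run seed via `numpy` `SeedSequence` substreams, making every
pipeline output deterministic given (config, seed) and independent of
condition processing order.

## Known limitations

* **Serial correlation and CI coverage.** The lagged-residual term
  reliably reduces residual autocorrelation (verified over 100 seeds), and
  with exchangeable extra-binomial noise the overdispersion-scaled step
  CI covers the null at ~95–96%. Under AR(1) noise (rho = 0.3), however,
  measured coverage drops to ~88%: the lag covariate does not propagate
  serial correlation into the Wald standard error of the step, whose
  sampling SD inflates by roughly sqrt((1+rho)/(1-rho)). This is a
  property of the lagged-residual method itself, not of this
  implementation; GLS/Newey–West-style alternatives are out of scope.
* The generator draws one shared weekly probability for all registered
  patients (no individual frailty, practice-level clustering, or
  demographic effect modification), so stratified analyses on synthetic
  data differ only by sampling noise.
* Codes are opaque strings in a synthetic namespace; no clinical
  terminology (SNOMED/Read/dm+d) semantics or hierarchy expansion.
* Deaths and deregistrations are simple exponential hazards; no
  practice-level data-quality windows or transfers.
* Cumulative deficit estimates carry no uncertainty intervals (weekly
  expected counts do).
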