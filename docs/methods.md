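# Methods

## Exposure model

The exposure unit is the calendar year; application dates collapse to
years on read because the density being reconstructed is annual. For a
known address at planar coordinates (metres) the annual density of
chemical *c* is the mass of active ingredient captured by a 500-m disc,
per acre of disc:

- every application is first *resolved* to a treated-field polygon.  A
  record carrying a `field_id` takes that field's geometry for the
  land-use survey period covering the application year; a record with
  only a `section_id` is spread over the crop-matching fields of the
  section, pounds split proportional to field area.  Unresolvable
  records are returned as data, never dropped, so pounds are always
  accountable.
- pounds are apportioned uniformly over the treated field: the disc
  captures `pounds × area(field ∩ disc)/area(field)`.  This reading
  conserves mass exactly — a disc containing every field captures the
  total pounds applied — and is asserted to 1e-9 relative in tests.  An
  alternative reading (summing treated-field per-acre rates directly)
  does not conserve mass and is not implemented.
- no distance decay is applied inside the disc.  The buffer radius
  stands in for the empirical finding that drift from commercial
  application is detectable in household dust of neighbouring homes;
  within that range the model is deliberately binary.
- the disc is a 128-vertex polygon (area within 0.1% of πr²; the
  geometry oracle tolerance is 0.5%, so the approximation error is
  negligible).  1 acre = 4046.8564224 m².

Person-years dispatch on the address timeline: a year covered by an
in-state, known-coordinate, high-certainty spell gets a density; a year
with no covering spell, unknown coordinates, or only a low-certainty
geocode (zip/city/county/state centroid) is `missing_location`; a year
covered by an out-of-state spell is `out_of_state_unassessed`.  Treating
low-certainty geocodes as missing is conservative and switchable
(`RunConfig.low_certainty_is_missing`).

## Imputation

Two rules, applied in order per person and chemical:

1. missing residential years ← the mean of that person's *observed*
   residential densities over the analysis window.  Out-of-state years
   are not imputed — the location is known but unassessable — and count
   as unexposed downstream.  The person-mean is computed per chemical
   and per setting; a window-only mean is used (years before the window
   start never enter).
2. missing workplace years ← the same year's post-imputation residential
   value (the assumption: out of the workforce means at home during
   working hours).

Imputation is idempotent and mean-preserving by construction, and a
series with no observed years at all is flagged rather than filled.
Missingness summaries must be computed pre-imputation; the code enforces
this.

## Classification

Exposed to *c* ⇔ some window year has density strictly above the
threshold (default 0, with a 1e-12 lb/acre floor absorbing
floating-point dust).  The window is the closed interval
`[1974, index_year − L]`: a latency of L years drops the L years
`index−L+1 … index` and retains through `index − L`; this endpoint
convention is pinned by tests.  The organochlorine group is exposed in a
setting iff any member chemical is (subsettable, e.g. to dicofol +
endosulfan).  The primary contrast compares persons exposed at both
residence and workplace against persons exposed at neither; discordant
persons (exactly one setting) form a third category excluded from the
primary fit, with an any-setting contrast available as a switch.

## Case–control model

Unconditional logistic regression (Newton/IRLS via statsmodels, gradient
tolerance 1e-8, 100 iterations max) of case status on the target
exposure indicator, indicators for each co-analysed pesticide, and the
adjustment set: continuous age and years lived in the study counties;
dummy-coded SES quintile, BMI, age at menarche, age at menopause,
parity, oral-contraceptive use, hormone-therapy use (reference = lowest
category throughout); and weekly alcohol use.  Wald 95% CIs
(`exp(β ± 1.96·SE)`) are reported rather than profile-likelihood
intervals, matching standard epidemiologic practice.  Separation and
collinearity are surfaced: a singular Hessian falls back to a
ridge-penalised Newton solver that returns finite, *flagged* estimates
(`converged=False`, `separation=True`) with NaN covariance, never a
silent number.

The change-in-estimate screen evaluates candidate confounders one at a
time against the core model and selects a candidate when it moves the
target OR by more than 10% relative (OR scale by default; log-OR scale
switchable); all selected candidates then enter the final model
together.  Covariates are complete-case: the readers reject missing
covariate values, and the generator produces complete tables.

## Synthetic-study generator

The generator emulates the structure of a registry-based case–control
study in an intensively farmed region:

- **landscape** — disjoint axis-aligned rectangular fields (analytic
  areas make geometry tests exact) with crop codes, a one-mile section
  grid and a survey period spanning the study years.  Default: 80 fields
  of 200–600 m sides in a 20 × 20 km region.
- **applications** — per field-year, a one-factor Gaussian copula
  induces co-application between chemicals; the latent loading is
  calibrated (bivariate-normal CDF + Brent root-finding) so the
  *indicator* correlation between chemical pairs equals the configured
  ρ (default 0.6).  Pounds = lognormal rate × field acres.  Chemicals
  are crop-restricted (e.g. the fumigant on row crops and vineyards,
  chlorpyrifos on orchards/cotton/row crops); this spatial segregation
  is what keeps person-level exposures to different chemicals partially
  discordant, reproducing the reported co-exposure pattern (defaults
  give roughly 51–57% of controls exposed to both organochlorines and
  chlorpyrifos, ~25% to neither, ~20% to exactly one).
- **population** — residential spells cover the window with
  Poisson-distributed moves (default rate 2 over the span); each spell
  is near-field (within drift range of a random field) with probability
  0.45, out of state with probability 0.05, and geocoded to parcel
  certainty with probability 0.92.  Workplace histories exist for 70% of
  persons and cover a subset of years.  Recall gaps are simulated by
  dropping each in-state spell-year independently (default 5%) and
  splitting spells around the holes.  Covariates are drawn from the
  categorical levels of the person schema; `years_in_counties` is
  derived from the generated history so the covariate is internally
  consistent.
- **outcomes** — case status follows
  `logit P(case) = α + Σ_c β_c·exposed_c + covariate effects`, where
  `exposed_c` is the indicator matching the analysis contrast (default:
  exposed at both settings) computed on the *un-masked* data through the
  real exposure engine, and α is calibrated by root-finding so the
  expected case count matches the quota.  The study is the first
  `n_cases` cases and `n_controls` controls drawn (defaults 155/150).
  Masking is applied after outcome assignment; the truth sidecar carries
  the exposure flags and coefficients that generated the outcomes.

What the generator does **not** emulate: wind-direction drift physics,
within-year application timing, crop rotation, geocoding error in the
coordinates themselves, and exposure from sources other than reported
applications.  Passing tests therefore validate the reconstruction and
inference machinery, not the epidemiologic truth of any real-world
estimate.

## Simulation experiments

Estimator validation (in `ambientpest.experiments`) uses outcome
redraws as the replicated unit: a synthetic cohort is generated a
handful of times (8 cohorts for coverage, 4 for null calibration and
confounding), and within each cohort the outcome vector is redrawn
independently per replicate from the calibrated outcome model.  Wald
coverage is conditionally valid given the design matrix, so this
measures the same property as regenerating the whole landscape per
replicate at a fraction of the cost.  The estimation scenarios switch
masking off: coverage of a planted value is a property of the
estimator, and measurement error would confound it.  Standard runs:
coverage of OR = 3.22 with 200 replicates of n = 2,000; null rejection
with 1,000 replicates; confounding attenuation with 100 replicates of
n = 1,000 in a scenario where all chemicals share crops and only
chlorpyrifos is causal.

## Numerical and design choices

- Geometry is validated, never reprojected; layers that look geographic
  (degree-range bounding box with implausibly small areas) are refused.
- Spell years are closed intervals; overlapping spells within a
  person-setting are rejected at read time.
- CSV interchange uses `%.17g` float formatting, so write→read
  round-trips are bit-exact and pipeline bundles are byte-identical
  under a fixed seed.  Stage timings are logged to stderr only, keeping
  the persisted provenance (seed, config hash, stage counts)
  deterministic.
- Sensitivity variants: latency 10/20 years, ≥30 window years in state
  and in the study counties, exclusion of persons with more than one
  third of residential window years missing, and a single-address
  comparison that pretends each person spent the whole window at their
  index-year residence.
- Known limitations: the section-linkage path assumes section ids are
  consistent between applications and fields; the ridge fallback's
  estimates under separation are regularised and should be read only as
  diagnostics; the change-in-estimate screen is the common one-pass
  variant, not a stepwise search.
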