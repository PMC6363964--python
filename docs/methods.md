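# Methods

## Model

The package fits flexible parametric survival models (FPMs) for relative
survival on the log cumulative excess hazard scale.  For a patient with
covariate vector x, writing H(t|x) for the cumulative *excess* hazard,

    ln H(t|x) = s(ln t | γ, k0) + x β                         (proportional hazards)
    ln H(t|x) = s(ln t | γ, k0) + x β + Σ_j s(ln t | δ_j, k_j) x_j   (time-dependent)

where s(·|·, k) is a restricted cubic spline with knot vector k.  The
spline construction is the standard one of this modelling tradition:
column 1 is the covariate itself and column j ≥ 2 is

    v_j(u) = (u − k_j)³₊ − λ_j (u − k_min)³₊ − (1 − λ_j)(u − k_max)³₊,
    λ_j = (k_max − k_j)/(k_max − k_min),

which is linear beyond the boundary knots and has continuous first and
second derivatives everywhere.  With one baseline degree of freedom the
spline is just ln t and the model is exactly Weibull (the package tests
this limit against an independent Weibull maximum-likelihood fit).  A
basis with df degrees of freedom has df columns and df + 1 knots; knots
for all time axes sit at equally spaced quantiles of the log event
times (boundary knots at the min and max), and knots for age at equally
spaced quantiles of the age distribution.  Quantiles use linear
interpolation between order statistics everywhere in the package.  Basis
columns are not orthogonalised; the optimiser instead works on a
centred/rescaled copy of the design (fitted values are invariant to
both choices).

The single modelled covariate is age at diagnosis, entered in decades
centred at the cohort mean for numerical conditioning.  Its main effect
is a restricted cubic spline; the time-dependent effect interacts a
spline in log time with the *linear* (centred, winsorised) age term.
Interacting with the full age basis is available as an option
(`tvc_full_age_basis`) but is not the default: the time-dependent
component models departures from proportionality, for which the linear
term is the parsimonious choice and needs fewer parameters.  An optional
`tvc_linear_only` flag restricts the interaction to the linear column of
the time spline, the fallback used for sparse cohorts with convergence
trouble.

## Likelihood

Relative survival R(t) = S(t)/S*(t) factorises the all-cause survival
into an expected part S*, taken as known from a life table, and an
excess part.  With delayed entry at t0 (period analysis), event
indicator d, expected hazard h* at the event time, Λ = exp(η) the
cumulative excess hazard and λ(t) = η'(ln t) Λ / t the excess hazard,
each row contributes

    d · ln( h* + λ(t) ) − Λ(t) + [t0 > 0] Λ(t0)

up to additive constants in the expected survival that do not involve
the parameters.  The fitted excess hazard is not constrained to be
non-negative at non-event times (the model lives on the cumulative
scale); only events require h* + λ > 0, and parameter values violating
that are rejected as inadmissible steps with likelihood −∞.

The score is analytic.  Maximisation runs BFGS from deterministic
starting values — a crude excess-rate exponential, refined by first
fitting the near-Weibull (1, df_age, 0) sub-model whose coefficients
carry over into the shared columns — followed by a damped Newton polish
using the observed information obtained by central finite differences of
the score (step 1e−5, relative).  A fit is flagged converged when the
scaled gradient norm max|g|/(1 + |ℓ|) is below 1e−5 and the observed
information is positive definite; the covariance is its inverse.  Rows
are sorted canonically (by exit time, entry time, status, age) before
the likelihood is assembled, so refits are bitwise invariant to input
row order.  AIC = −2ℓ + 2p and BIC = −2ℓ + p ln n with n the number of
analysis rows (not events); the events-based alternative is a known
variant, and the choice is documented here so comparisons are
reproducible.

## Life table and expected mortality

The life table is a complete grid of annual rates over sex × integer
age × calendar year.  Within each one-year band of attained age and
calendar year the rate is constant, so each patient's expected hazard
path is a step function with steps at every birthday and new year;
cumulative expected hazards are integrated exactly over these bands.
Ages above the table maximum reuse the maximum-age row and years outside
the range clamp to the nearest year (logged, never silently
extrapolated).  Expected-mortality lookups always use the patient's
*true* age at diagnosis; the 2nd/98th-percentile winsorisation affects
only the modelled covariate, since the constraint is on modelled
relative survival, not on population mortality.  Winsorisation cut
points are computed on the full cohort before the period window is
applied (logged), as the constraint describes the cancer-type
population, not the window sample.

## Period analysis

The period window [start, end) keeps only person-time inside the
window: patients whose follow-up ends earlier are dropped, diagnosis
before the window becomes delayed entry at t0 = start − dx, and
follow-up is censored at the right edge, with deaths exactly at the edge
treated as censored (the half-open convention makes the person-time
accounting unambiguous).

## Predictions and standardisation

Age-specific relative survival is R(t) = exp(−exp(η)) at the requested
age, clamped to the winsorisation cut points; 95% confidence intervals
are delta-method intervals on the η = ln(−ln R) scale (z = 1.959964),
back-transformed so they respect (0, 1].  The excess-hazard curve is
λ(t) = η'(ln t) exp(η)/t with intervals on the log-hazard scale where
the hazard is positive.

Age-group estimates average the *individual* predicted curves of the
group's members (not the curve at the group's mean age) with groups
assigned on true age: this matches the weighted-average semantics of
internal standardisation exactly.  The standardised curve is Σ_g w_g
R̄_g(t) with internal weights w_g equal to the cohort's group shares —
algebraically identical to averaging over all members — or external
weights summing to 1.  Group boundaries are 18–44, 45–54, 55–64, 65–74,
75+ by default, with the elderly-shifted variant 18–54, 55–64, 65–74,
75–84, 85+ selectable for prostate-like cohorts.  Variances for averaged
estimates propagate the delta method through the averaging operator over
each member's η.

## Non-parametric estimators

All three estimators share the risk set Y(u) = #{i : t0_i < u ≤ t_i}.
The Ederer II and Pohar Perme estimators are implemented in their
hazard-scale (Nelson–Aalen-style) dialects, which accommodate delayed
entry naturally — published implementations differ between hazard-scale
and actuarial interval dialects, so the choice is stated explicitly:

* Ederer II: Λ(t) = Σ_{s≤t} dN(s)/Y(s) − ∫₀ᵗ Σ_i Y_i(u) h*_i(u) / Y(u) du,
  relative survival exp(−Λ).  The integral is exact: the integrand is
  piecewise constant between consecutive entry/exit times and each
  patient's life-table band changes, and every sub-segment is integrated
  in closed form.
* Pohar Perme: the same construction with each patient weighted by the
  inverse of their own expected survival w_i(u) = 1/S*_i(u).  Per-patient
  expected-hazard increments over each inter-grid segment are exact;
  weighted sums are refreshed at every distinct entry and exit time with
  weights held at segment-start values across a segment, and event-time
  terms use exact weights at the event time.  This quadrature is exact
  whenever weights are constant across a segment, which makes the
  estimator *identically* equal to Ederer II on homogeneous cohorts (a
  tested invariant); on heterogeneous cohorts the within-segment weight
  drift is O(h* × gap), negligible at registry scale where gaps between
  consecutive exit times are tiny.  Weights are capped at 1e6 by default
  (logged), since 1/S* explodes for the very old with long follow-up.

With a zero life table both reduce to exp(−Nelson–Aalen) and the
Kaplan–Meier helper provides the product-limit cross-check.

## Sensitivity protocol

The df grid is the Cartesian product {3,4,5,6,7} × {3,4,5} × {2,3,4,5}
(60 models), in deterministic baseline-major order, with (5, 3, 3) as
the reference model.  Non-converged fits are retained and flagged but
excluded from minimum-AIC/BIC selection; ties are broken by fewer
parameters, then grid order; a non-converged reference model is a hard
error.  Difference-table cells are (reference − comparator) × 100 at 1
and 5 years — the sign convention is stated because absolute-value
summaries are sign-invariant anyway.  A transcription of the published
difference tables for ten English cancer types ships as packaged data
(`rsfpm/data/table2_differences.csv`, SHA-256 verified at load), so the
summary means and medians can be recomputed without registry access.
Medians computed from the rounded printed cells agree with the published
medians only loosely (±0.01); the means reproduce to three decimals.

## Synthetic registry

The generator draws ages from a truncated normal (mean 71, SD 12 on
[18, 99], matching the age structure of the common solid tumours),
diagnosis dates uniform on [2007, 2014), administrative censoring at
2014.0, and all-cause death as the minimum of two competing times:

* excess: ln H_e(t|z) = shape·ln(t/scale) + (β_age + δ_tvc ln t) z with
  z the age in decades centred at 70.  Defaults shape 0.7, scale 13.0,
  β_age 0.35, δ_tvc 0 give a falling excess hazard, five-year relative
  survival ≈ 0.68 at age 70 declining steeply with age — a mid-survival
  solid tumour.  The generating model is itself an FPM with one baseline
  df (plus a linear time-dependent age effect when δ_tvc ≠ 0), so the
  reference model nests the truth and recovery checks isolate estimation
  error from approximation error.
* population: inverse-transform sampling of each patient's exact
  life-table cumulative hazard, using the *same* Gompertz life table
  (rate a·e^{0.095·age} with a = 2.0e−5 / 1.2e−5 for men/women and a
  −0.5%/year calendar drift, capped at 1) that the analysis uses — no
  life-table misspecification by default, so estimator error is isolated
  from life-table error.

What the generator does *not* emulate: cancer-specific ICD coding,
multiple tumours, within-year seasonality of diagnosis, reporting delay,
or life tables with geography/deprivation axes.  Passing recovery tests
therefore demonstrates correctness of the estimation machinery under a
correctly specified life table, not robustness to the data problems of
real registries.

## Problem sizes and numerical choices

Tests and the acceptance script use cohorts of n = 20,000 with the
2011–2013 window (≈17,000 analysis rows, ≈4,000 deaths) for
registry-scale checks and n ≤ 5,000 elsewhere; at this size the grid of
60 fits completes in well under a minute and Monte-Carlo error on a
five-year survival prediction at a single age is roughly one percentage
point, which is the tolerance used by the recovery checks.  Other fixed
choices: exp-overflow guard at η = 200 (steps beyond are rejected);
finite-difference Hessian step 1e−5 relative; Newton polish accepts
steps that do not decrease the likelihood by more than 1e−10; weight cap
1e6.  Degenerate inputs fail loudly: duplicate interior knots, df
exceeding the distinct-value count, empty period windows, fewer than 30
events, fewer than 50 patients for percentile cut points, incomplete
life-table grids.

## Known limitations

* Only the log *cumulative* hazard scale is implemented (by design);
  log-hazard-scale FPMs, cure models and frailty are out of scope.
* One covariate (age) plus sex via the life table; no multi-covariate
  regression interface.
* The Pohar Perme variance is not implemented (the estimator is used
  here as a point-estimate comparator); Kaplan–Meier/Ederer II carry no
  variance either.
* Calendar dates are decimal years throughout; leap-year-exact date
  arithmetic is deliberately out of scope.
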