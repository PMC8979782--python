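# Methods

## The model

The package estimates how the *dose, duration and recency* of a
medication's use relate to the hazard of an acute event — here,
hospitalization for COPD exacerbation among elderly patients using
prescription paracetamol. Conventional time-varying Cox covariates
("current use", "any use in the past 30 days") collapse the exposure
history to a scalar; the weighted-cumulative-exposure (WCE) approach
instead enters the whole history through

    WCE(u) = sum_{t < u} w(u - t) X(t),

where `X(t)` is the daily dose (g/day) on follow-up day `t` and
`w(l)` is the weight of a dose taken `l` days ago, in units of log
hazard ratio per gram-day. The weight function is expanded on a cubic
B-spline basis over a finite window `[0, T]`,
`w(l) = sum_j theta_j B_j(l)`, which turns the WCE term into `J`
ordinary time-varying covariates

    D_j(u) = sum_{l=1..T} B_j(l) X(u - l),

so `theta` is estimated jointly with the other regression coefficients
by maximizing a stratified Cox partial likelihood. Everything
downstream is linear in `theta`: pointwise confidence bands for
`w(l)`, and the hazard ratio of an arbitrary exposure pattern
`x(1..T)` versus never-use,

    HR(x) = exp( sum_l w(l) x(l) ) = exp(d' theta),
    d_j = sum_l B_j(l) x(l),

with delta-method intervals from the `theta` block of the inverse
observed information.

Time runs in days since cohort entry. Risk (event) days are `u = 1..L`;
the covariate used at risk day `u` derives from day-level data up to
day `u - 1` (the dose of the same day never informs its own risk, so
the final follow-up day's dose is never consumed). Tied event days are
handled by Efron's method by default (Breslow selectable). The model is
stratified by baseline disease severity (separate baseline hazards,
shared coefficients), with fixed covariates (age at entry in completed
years, sex, medication-defined hypertension / heart failure / diabetes,
comorbidity count) and a daily statin indicator as an additional
time-varying covariate.

### Spline basis

Cubic (order 4) B-splines with boundary knots of full multiplicity at 0
and `T` and interior knots equally spaced on `(0, T)` (explicit knots
may be supplied). The unconstrained basis has `k + 4` columns for `k`
interior knots and satisfies partition of unity inside the window. The
*right-constrained* variant drops the two trailing columns, forcing the
fitted weight function to reach zero at `l = T` with zero slope — the
convention for imposing "no effect beyond the window" smoothly. Both
variants are exposed because the data rarely distinguish them; BIC
comparison across `(T, k, constrained)` candidates is provided
(`select_model`), with `BIC = -2 logPL + p log(number of events)` and
ties broken toward fewer parameters, then shorter windows.

### Optimization and numerics

Newton–Raphson on the exact score and observed information, with
step-halving whenever a step would decrease the log partial
likelihood; convergence when the maximum absolute score falls below
1e-8 or the relative log-likelihood change below 1e-10. Covariates are
centered internally (the partial likelihood is invariant to location
shifts) and each risk set's linear predictor is max-shifted before
exponentiation. A singular information matrix falls back to a small
ridge for the step only; the reported covariance is the inverse
observed information at the optimum. Coefficients exceeding 50 in
absolute value trigger a monotone-likelihood (separation) warning.
Degenerate inputs — no events, unknown tie methods, patterns longer
than the window — raise informative errors.

### Proportional-hazards diagnostics

Schoenfeld residuals are computed per event as the event covariate
minus the risk-set weighted mean, with the per-event-time risk-set
covariance retained. The test regresses the residuals on a transform of
event time (default: one minus the pooled Kaplan–Meier estimate;
identity and rank transforms available) and forms a score test —
per-parameter chi-square on one degree of freedom and a global test on
the rank of the pooled variance. A replicated simulation test bounds
the global rejection rate under proportional hazards.

## Exposure reconstruction

Dispensing claims carry no dose instruction, so exposure is
reconstructed under the maximum-dose convention for regular analgesic
use: 8 x 500 mg = 4.0 g/day and 6 x 665 mg controlled-release =
3.99 g/day. Days of supply is `floor(quantity / tablets_per_day)`,
minimum one day; the exact duration function is not standardized
anywhere, so it is isolated behind `days_of_supply` and the
tablets-per-day constants are overridable. Early refills *extend*
coverage: a fill dated before the current supply ends queues its full
supply after the current period (first-dispensed-first-consumed, so a
covered day carries the dose of the fill actually covering it); a fill
after a gap restarts coverage on its own date; coverage truncates at
the end of follow-up. Supply intervals are half-open `[start, end)` in
days, which removes off-by-one ambiguity and makes total covered days
exactly the sum of per-fill supplies absent truncation (a tested
conservation property).

## Cohort construction

The eligibility cascade at the study start (2011-01-01) requires age
45–100 in completed years, full claims entitlement for the prior 12
months (implemented as entitlement start at least 365 days before the
study start), evidence of existing COPD in the prior 12 months (a
qualifying inhaled-medication dispensing, or a hospitalization with a
qualifying code in *any* diagnosis position), no paracetamol dispensing
in the prior 6 months, no residential aged-care residence at the study
start, at least one paracetamol dispensing during the study, and more
than one day of follow-up. Every failed gate is recorded, so exclusion
counts reconcile against the input population. Cohort entry is the
first in-study paracetamol dispensing — follow-up cannot begin before
exposure can, which removes immortal time. The outcome is the first
admission after entry whose *primary* diagnosis is a qualifying COPD
code (J43x / J440 / J441 / J448 / J449; a deliberate asymmetry with the
any-position inclusion rule); censoring is the earliest of death,
residential-care entry and the study end. ICD codes are matched on
dot-stripped strings with `*` as a prefix wildcard, and all code lists
are configuration.

Comorbidity covariates come from a deliberately small, documented
ATC-prefix-to-category mapping (a user-replaceable stand-in for a full
medication-based comorbidity index): the three named flags plus a count
of remaining distinct categories, excluding hypertension, heart
failure, diabetes and COPD. Statins map to no category because statin
use enters the model as its own covariate.

`build_cohort` is a vectorized whole-table implementation; the
patient-at-a-time functions remain as the readable reference and the
two are tested for exact agreement. The counting-process export breaks
intervals where the daily dose or statin indicator changes; covariates
attached to `[a, b)` apply to risk days `a+1..b`, and a test verifies
that person-day re-expansion leaves all likelihoods unchanged.

## Nested case–control arm

Cases are members with the outcome, the index date is the event date.
Controls are drawn by incidence-density sampling: under follow-up at
the index date with no event on or before it, same sex, age at the
index date within 2 years, first paracetamol dispensing within 30
days; two controls per case, uniformly without replacement within the
set, independently across sets (so controls can be reused and later
become cases — matching the theory under which conditional-logistic
odds ratios estimate hazard ratios). Cases with an empty pool are
reported, not dropped silently. Age at the index date is the entry age
plus elapsed years; calipers are closed intervals.

The conditional-logistic likelihood conditions on each matched set;
the WCE covariates are evaluated from each member's own dosing history
at the set's index date (days before a member's entry contribute zero
dose). Adjustment covariates: the comorbidity flags and count, any
statin use in the 30 days before the index date, and the natural log of
(annual health-service count + 1) — the offset guards zeros since no
base or offset is standard. Estimation reuses the same Newton driver as
the Cox model; weight-function bands and pattern HRs come through the
same prediction code path.

## Synthetic claims generator

The generator emulates an elderly claims cohort with existing COPD so
every stage is testable without restricted data. Per patient: age
N(84, 7) truncated to 46–99 (median ≈ 85), 38% female, 39% high
baseline severity, COPD evidence always present in the baseline year
(hospitalization evidence reserved for high-severity patients so the
downstream stratum equals the generator's truth), comorbidity
medications dispensed with prevalences near the study population's
(hypertension 45%, heart failure 23%, diabetes 12.5%, plus four other
categories) and refilled every 70–110 days so any 12-month lookback
sees them; statin users (50%) refill every 30 days with high
persistence. Paracetamol initiation (90% of patients, uniform over the
study) starts a refill chain: packs of 100 x 500 mg or 96 x 665 mg CR
(67% CR users), next fill after `days_of_supply + Geometric(0.18) - 4`
days — producing both early refills (exercising the extension rule)
and gaps — with per-fill persistence 0.88 and possible re-initiation
after an exponential off-period. Death (2.2e-4/day) and residential
care (8e-5/day) censor; small fractions violate the washout (5%) or
residential-care (3%) gates to exercise the cascade.

Events are drawn in *discrete time*: on each post-entry day a Bernoulli
draw at

    h(u) = lambda_0 exp( severity + beta' Z + theta' D(u) )

with `lambda_0 = 2.4e-4`/day (chosen so 2000 source patients yield
roughly 300 events), severity log-HR 0.55, and age centered at 80
years. Daily Bernoulli draws at the model hazard (rather than
continuous-time inversion) match the day-resolution of the exposure
data and make the true hazard ratio of any pattern available in closed
form (`true_pattern_hr`), which is what recovery tests compare
against. Configurations whose implied hazard could exceed 1 are
rejected up front, and the realized hazards are checked again at run
time. The true covariate effects take magnitudes typical of COPD
exacerbation risk models (age +0.025/year, female -0.29, statin -0.19,
hypertension -0.22, heart failure +0.24, diabetes -0.12, comorbidity
count +0.06 per category).

The default true weight function is biphasic on the right-constrained
(T = 75, one interior knot) basis, `theta = (-0.0173, 0.01187,
0.00376)`: negative weights at lags 1–9 (a transient protective effect
right after initiation), positive weights around lags 14–45, near zero
beyond lag 60 and exactly zero at 75. It was frozen as the
least-squares projection of that target shape onto the basis; its
implied current-use pattern HRs are about 0.89 (4 g for 2 days), 0.77
(4 g for 7 days) and 1.16 (4 g for 30 days).

What the generator does *not* emulate: over-the-counter purchasing,
dose titration or partial-day dosing, seasonality, disease
progression, and any confounding between the exposure process and the
covariates (initiation and refills are independent of Z). Passing
recovery tests therefore demonstrate correctness of the estimation
machinery under the stated model, not robustness to confounding or
exposure misclassification in real claims.

## Study sizes and evaluation

The standard evaluation conditions: one recovery run at n = 2000
source patients (≈ 1300 members, ≈ 300 events); confidence-band
coverage and null calibration over 200 replicates at n = 500; BIC model
selection over 50 replicates at n = 1000 against candidates
{(75,1), (30,1), (75,2), (180,1)} and current-dose / windowed
mean- and cumulative-dose comparators; and one shared n = 2000
simulation for the cohort-versus-NCC comparison. The NCC/Cox
discrepancy is standardized by the conservative independent-variance
pooling (the two fits share data, so their difference's true standard
error is smaller than the pooled one). Replicate seeds derive
deterministically from a base seed.

## Known limitations

* Delta-method (Wald) bands; no profile-likelihood or bootstrap
  intervals by default (a parametric bootstrap of `theta` is trivial
  from the stored covariance and is used as a test oracle).
* The conditional-logistic arm ignores control reuse when computing the
  covariance (standard practice; intervals near lag zero are wide
  regardless).
* Knot placement is equally spaced unless explicit knots are given;
  quantile placement of exposure support is not automated.
* The comorbidity mapping is a minimal stand-in; real analyses should
  supply a complete medication-based index.
* Left truncation beyond the entry rule, competing risks and
  time-varying coefficients are out of scope.
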