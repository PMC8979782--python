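# wcesurv

Weighted cumulative exposure (WCE) survival modelling for
pharmacy-claims cohorts.

## The problem

In elderly populations regular analgesic use (e.g. paracetamol for
osteoarthritis) may influence the risk of acute respiratory events such
as hospitalization for COPD exacerbation, and the effect plausibly
depends on *how much*, *for how long* and *how recently* the medicine
was taken. Claims databases record dispensings, not intake, and
conventional time-varying Cox covariates ("current use", "any use in
the past month") cannot express such dose-timing structure.

`wcesurv` implements the full analysis pipeline for this class of
pharmacoepidemiologic questions:

* **exposure reconstruction** from dispensing claims, with the
  maximum-dose convention (8 × 500 mg = 4 g/day, 6 × 665 mg
  controlled-release = 3.99 g/day) and supply-extension of early
  refills;
* **new-user cohort construction** — eligibility cascade, entry at the
  first dispensing (no immortal time), primary-diagnosis outcome,
  censoring, severity strata and medication-based comorbidities;
* the **WCE model**: the hazard on day `u` depends on
  `Σ_t w(u−t) X(t)`, past daily doses weighted by a lag function `w`
  expanded on cubic regression splines over a window of `T` days and
  estimated inside a stratified Cox partial likelihood (Efron ties,
  Newton–Raphson), with BIC selection of `(T, knots)`, pointwise
  confidence bands for `w`, and hazard ratios for arbitrary exposure
  patterns `HR(x) = exp(Σ_t ŵ(t) x(t))` with delta-method intervals;
* a **nested case–control arm** — incidence-density sampling (2
  controls per case matched on sex, age ±2 years, first dispensing
  ±30 days) and conditional-logistic WCE estimation — to confirm the
  cohort results with a different design;
* **conventional comparator models** (current dose, windowed mean and
  cumulative dose) on both arms;
* a **synthetic claims generator** with a known true weight function
  and covariate effects, so that every stage is testable end to end
  without access to restricted claims data.

The estimators are scikit-learn style (`fit`, fitted attributes with a
trailing underscore, `get_params`/`set_params`): `WCECoxModel`,
`ConventionalCoxModel`, `WCEConditionalLogit`,
`ConventionalConditionalLogit`.

## Worked example

The package ships a CLI (`wcesurv`) running the pipeline stage by
stage. On a synthetic population of 2000 patients:

```bash
wcesurv simulate --seed 7 --n-patients 2000 --out demo/tables
# wrote 2000 patients, 151320 dispensings, 677 episodes to demo/tables

wcesurv build-cohort --tables demo/tables --out demo/cohort
# 1303 members (288 events), 697 excluded

wcesurv fit-wce --cohort demo/cohort --out demo/fit
# fit: 288 events, BIC 3384.9

wcesurv predict --fit demo/fit/wce_cox_fit.json --pattern 4,4,4,4,4,4,4
# HR = 0.845 (95% CI 0.567-1.259)
```

The `predict` call asks: compared with never-use, what is the hazard
of a patient who took 4 g/day for the last 7 days? The generator's
true weight function is biphasic — protective in the first week after
initiation, harmful at lags of two to six weeks — and its true HR for
this pattern is 0.77; the fitted value 0.845 recovers it within the
interval. A 30-day pattern flips the sign of the effect:

```bash
wcesurv predict --fit demo/fit/wce_cox_fit.json \
    --pattern 4,4,4,...   # thirty 4's
# HR = 1.343 (95% CI 0.835-2.160)
```

`demo/fit/covariate_table.csv` holds the adjusted covariate hazard
ratios (age, sex, statin use, comorbidities), e.g. heart failure
HR 1.48 (95% CI 1.15–1.92) in this run. `wcesurv report` exports the
weight function with confidence bands, a dose × duration HR grid for
current use, and past-use HR curves by time since stopping (CSV;
`--plots` renders PNGs). `wcesurv fit-ncc` runs the matched
case–control arm from the same cohort artifacts.

Everything is also available as a library:

```python
from wcesurv import SimulationConfig, simulate_population, WCECoxModel
from wcesurv.evaluation import run_pipeline

data = run_pipeline(SimulationConfig(n_patients=2000, seed=7))
model = WCECoxModel(window=75, n_interior_knots=1, constrained=True)
model.fit(data["members"], data["exposures"], data["statins"])
model.weight_function()            # lag, estimate, lower, upper
model.predict_pattern_hr([4.0]*7)  # (0.845, 0.567, 1.259)
```

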