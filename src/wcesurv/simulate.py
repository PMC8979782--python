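"""Synthetic pharmacy-claims generator with known ground truth.

Emulates an elderly claims cohort with existing chronic obstructive
pulmonary disease (COPD): every generated patient carries COPD evidence
in the year before the study start (an inhaled-anticholinergic dispensing
or a COPD hospitalization), a configurable fraction initiate prescription
paracetamol during the study through a refill process with early refills
and gaps, comorbidity medications and statins are dispensed as sentinel
ATC codes, and death / residential aged-care entry censor follow-up.

Hospitalization for COPD exacerbation is generated in discrete time: on
each follow-up day ``u`` after paracetamol initiation a Bernoulli draw at

    h(u) = baseline_hazard * exp(severity + beta' Z + theta' D(u))

decides the event, where ``D(u)`` are the true-weight-basis cumulative
exposure covariates computed from the patient's reconstructed daily dose
series. The first success becomes a primary-position COPD episode. This
makes the true hazard ratio of any exposure pattern available in closed
form (``true_pattern_hr``), which is what the recovery, calibration and
model-selection studies test against.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from datetime import date, timedelta
from typing import Mapping

import numpy as np
import pandas as pd

from .basis import SplineWeightBasis, WeightFunction
from .cox import wce_covariates
from .exposure import build_daily_series, build_binary_series


def _completed_years(dob: date, ref: date) -> int:
    years = ref.year - dob.year
    if (ref.month, ref.day) < (dob.month, dob.day):
        years -= 1
    return years

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "default_true_weights",
    "simulate_population",
    "true_pattern_hr",
    "write_tables",
]

#: Biphasic true weight coefficients on the right-constrained
#: (window 75, 1 interior knot) cubic basis: negative weights at lags
#: 1-9 (transient protective effect after initiation), positive weights
#: around lags 14-45, near zero beyond lag 60.
DEFAULT_TRUE_THETA = (-0.0173, 0.01187, 0.00376)


def default_true_weights() -> WeightFunction:
    basis = SplineWeightBasis(window=75, n_interior_knots=1,
                              constrained=True)
    return WeightFunction(basis, np.asarray(DEFAULT_TRUE_THETA))


#: Covariate log hazard ratios used as simulation truth; values mirror
#: effect sizes typical of COPD exacerbation risk models (age per year,
#: female sex, daily statin use, medication-defined comorbidities).
DEFAULT_COVARIATE_EFFECTS: Mapping[str, float] = {
    "age_entry": 0.025,
    "female": -0.29,
    "statin": -0.19,
    "hypertension": -0.22,
    "chf": 0.24,
    "diabetes": -0.12,
    "comorbidity_count": 0.06,
}

_COMORBIDITY_ATC = {
    "hypertension": "C09AA02",
    "chf": "C03DA01",
    "diabetes": "A10BA02",
    "depression": "N06AB04",
    "gord": "A02BC01",
    "osteoporosis": "M05BA04",
    "chronic_pain": "N02AA05",
}

_COMORBIDITY_PREVALENCE = {
    "hypertension": 0.45,
    "chf": 0.23,
    "diabetes": 0.125,
    "depression": 0.18,
    "gord": 0.30,
    "osteoporosis": 0.25,
    "chronic_pain": 0.12,
}

_COPD_EVENT_CODES = ("J440", "J441", "J448", "J449", "J439")


@dataclass
class RefillModel:
    """Paracetamol refill process.

    After each fill the next one arrives ``days_of_supply + gap`` days
    later with ``gap = G - gap_shift``, ``G ~ Geometric(gap_p)`` (support
    1, 2, ...). Negative gaps are early refills that exercise the
    supply-extension rule; positive gaps leave uncovered days. Each
    refill continues with probability ``persistence``; after a treatment
    episode ends a new one may start after an exponential off-period.
    """

    gap_p: float = 0.18
    gap_shift: int = 4
    persistence: float = 0.88
    reinitiation_prob: float = 0.45
    mean_off_days: float = 180.0
    cr_fraction: float = 0.67          # controlled-release users
    pack_quantity_500: int = 100       # 12 days at 8 tablets/day
    pack_quantity_665: int = 96        # 16 days at 6 tablets/day


@dataclass
class SimulationConfig:
    """Data-generating conditions for the synthetic cohort."""

    n_patients: int = 2000
    study_start: date = date(2011, 1, 1)
    study_end: date = date(2015, 9, 30)
    age_range: tuple[int, int] = (45, 100)
    age_mean: float = 84.0
    age_sd: float = 7.0
    sex_ratio_female: float = 0.38
    true_weights: WeightFunction = field(default_factory=default_true_weights)
    true_covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS))
    age_reference: float = 80.0        # age is centered here in the hazard
    baseline_hazard: float = 2.4e-4    # events per person-day, low stratum
    high_severity_log_hr: float = 0.55
    high_severity_fraction: float = 0.39
    refill_model: RefillModel = field(default_factory=RefillModel)
    death_rate: float = 2.2e-4         # per day
    rac_rate: float = 8.0e-5           # per day
    initiation_prob: float = 0.90
    prior_paracetamol_frac: float = 0.05
    rac_at_start_frac: float = 0.03
    statin_prob: float = 0.50
    statin_refill_days: int = 30
    statin_persistence: float = 0.995
    health_services_mean: float = 40.0
    seed: int = 0

    def __post_init__(self):
        for name in ("baseline_hazard", "death_rate", "rac_rate",
                     "initiation_prob", "prior_paracetamol_frac",
                     "rac_at_start_frac", "statin_prob",
                     "sex_ratio_female", "high_severity_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.study_start >= self.study_end:
            raise ValueError("study_start must precede study_end")
        self.validate_hazard_bound()

    @property
    def study_days(self) -> int:
        return (self.study_end - self.study_start).days

    def max_linear_predictor(self) -> float:
        """Upper bound on the log relative hazard over all patients/days."""
        eff = self.true_covariate_effects
        bound = self.high_severity_log_hr
        w = self.true_weights.values
        bound += 4.0 * np.clip(w, 0, None).sum()   # max positive WCE term
        lo, hi = self.age_range
        a = eff.get("age_entry", 0.0)
        bound += max(a * (hi - self.age_reference),
                     a * (lo - self.age_reference))
        for name in ("female", "statin", "hypertension", "chf", "diabetes"):
            bound += max(eff.get(name, 0.0), 0.0)
        bound += max(eff.get("comorbidity_count", 0.0), 0.0) * \
            len(_COMORBIDITY_PREVALENCE)
        return bound

    def validate_hazard_bound(self):
        worst = self.baseline_hazard * np.exp(self.max_linear_predictor())
        if worst > 1.0:
            raise ValueError(
                f"hazard-overflow: implied daily hazard can reach "
                f"{worst:.3g} > 1")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying one simulated population."""

    theta: np.ndarray
    covariate_effects: dict
    weight_function: WeightFunction
    entry_day: dict            # patient_id -> calendar offset of entry
    event_day: dict            # patient_id -> follow-up day of event
    hazards: dict              # patient_id -> daily hazard array
    covariates: dict = field(default_factory=dict)  # true per-patient Z

    def to_json(self, path, include_hazards: bool = False):
        payload = {
            "theta": np.asarray(self.theta).tolist(),
            "covariate_effects": dict(self.covariate_effects),
            "basis": {
                "window": self.weight_function.basis.window,
                "n_interior_knots":
                    self.weight_function.basis.n_interior_knots,
                "constrained": self.weight_function.basis.constrained,
            },
            "entry_day": {str(k): int(v)
                          for k, v in self.entry_day.items()},
            "event_day": {str(k): int(v)
                          for k, v in self.event_day.items()},
        }
        if include_hazards:
            payload["hazards"] = {str(k): np.asarray(v).tolist()
                                  for k, v in self.hazards.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh)


def true_pattern_hr(config: SimulationConfig, pattern) -> float:
    """Closed-form hazard ratio of an exposure pattern under the truth.

    ``exp(sum_t w_true(t) x(t))`` — the recovery target for the fitted
    model's ``predict_pattern_hr``.
    """
    return float(np.exp(config.true_weights.pattern_log_hr(pattern)))


# ----------------------------------------------------------------------


def _refill_chain(rng, config: SimulationConfig, first_day: int,
                  horizon: int):
    """Paracetamol fills as (day_offset, strength, quantity) tuples."""
    rm = config.refill_model
    is_cr = rng.random() < rm.cr_fraction
    strength = 665 if is_cr else 500
    quantity = rm.pack_quantity_665 if is_cr else rm.pack_quantity_500
    supply = quantity // (6 if is_cr else 8)
    fills = []
    day = first_day
    while day < horizon:
        fills.append((day, strength, quantity))
        if rng.random() >= rm.persistence:
            # treatment episode ends; possibly re-initiate later
            if rng.random() >= rm.reinitiation_prob:
                break
            off = rng.exponential(rm.mean_off_days)
            day = day + supply + max(int(off), 1)
        else:
            gap = rng.geometric(rm.gap_p) - rm.gap_shift
            day = day + max(supply + gap, 1)
    return fills


def _statin_chain(rng, config: SimulationConfig, start_day: int,
                  horizon: int):
    fills = []
    day = start_day
    while day < horizon:
        fills.append(day)
        if rng.random() >= config.statin_persistence:
            break
        day += config.statin_refill_days
    return fills


#: covariates whose truth the generator records per patient
_EXCLUDED_FROM_COUNT = ("hypertension", "chf", "diabetes")


def simulate_population(config: SimulationConfig):
    """Generate (patients, dispensings, episodes, truth) tables.

    Identical config (including seed) produces byte-identical tables.
    Baseline COPD hospitalizations are generated only for high-severity
    patients, and comorbidity medications refill throughout the study,
    so the cohort builder's stratum and covariate derivations reproduce
    the generator's truth exactly.
    """
    rng = np.random.default_rng(config.seed)
    start = config.study_start
    study_days = config.study_days
    basis = config.true_weights.basis
    eff = dict(config.true_covariate_effects)

    patients, dispensings, episodes = [], [], []
    truth_entry, truth_event, truth_hazard = {}, {}, {}
    truth_cov = {}

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        my_disp = []

        def fill(day_offset, atc, strength="", qty=30):
            my_disp.append({
                "patient_id": pid,
                "supply_date": start + timedelta(days=int(day_offset)),
                "atc_code": atc, "strength_mg": strength,
                "quantity": qty})

        age = float(np.clip(rng.normal(config.age_mean, config.age_sd),
                            config.age_range[0] + 1,
                            config.age_range[1] - 1))
        dob = start - timedelta(days=int(age * 365.25))
        female = rng.random() < config.sex_ratio_female
        high_severity = rng.random() < config.high_severity_fraction

        death_gap = rng.exponential(1.0 / config.death_rate)
        death = (start + timedelta(days=int(death_gap))
                 if death_gap < 2 * study_days else None)
        rac_at_start = rng.random() < config.rac_at_start_frac
        if rac_at_start:
            rac = start - timedelta(days=int(rng.integers(10, 300)))
        else:
            rac_gap = rng.exponential(1.0 / config.rac_rate)
            rac = (start + timedelta(days=int(rac_gap))
                   if rac_gap < 2 * study_days else None)

        # --- baseline COPD evidence and severity markers --------------
        # hospitalization evidence is reserved for high-severity patients
        # so the severity stratum derived downstream matches the truth
        had_copd_hosp = high_severity and rng.random() < 0.45
        if had_copd_hosp:
            position = "primary" if rng.random() < 0.5 else "secondary"
            episodes.append({
                "patient_id": pid,
                "admission_date": start - timedelta(
                    days=int(rng.integers(10, 360))),
                "icd10_code": str(rng.choice(_COPD_EVENT_CODES)),
                "position": position})
        if high_severity and not had_copd_hosp:
            fill(-rng.integers(10, 360), "H02AB06")
        if not had_copd_hosp or rng.random() < 0.8:
            fill(-rng.integers(10, 360), "R03BB04")

        # --- comorbidity medications (refilling through the study) ----
        categories = {cat: bool(rng.random() < prev)
                      for cat, prev in _COMORBIDITY_PREVALENCE.items()}
        for cat, present in categories.items():
            if present:
                day = -int(rng.integers(280, 360))
                while day < study_days:
                    fill(day, _COMORBIDITY_ATC[cat])
                    day += int(rng.integers(70, 110))

        # --- statins --------------------------------------------------
        statin_user = rng.random() < config.statin_prob
        statin_days = []
        if statin_user:
            statin_days = _statin_chain(rng, config,
                                        -int(rng.integers(0, 330)),
                                        study_days)
            for day in statin_days:
                fill(day, "C10AA05")

        # --- paracetamol washout violators / initiation ---------------
        if rng.random() < config.prior_paracetamol_frac:
            fill(-rng.integers(5, 175), "N02BE01", 500, 100)
        initiates = rng.random() < config.initiation_prob
        first_day = int(rng.integers(0, max(study_days - 30, 1))) \
            if initiates else None

        # censoring horizon in calendar days from study start
        horizon_date = config.study_end
        if death is not None:
            horizon_date = min(horizon_date, death)
        if rac is not None and not rac_at_start:
            horizon_date = min(horizon_date, rac)

        para_fills = []
        if initiates and first_day is not None \
                and first_day < (horizon_date - start).days:
            para_fills = _refill_chain(
                rng, config, first_day,
                min((horizon_date - start).days, study_days))
            for day, strength, qty in para_fills:
                fill(day, "N02BE01", strength, qty)

        patients.append({
            "patient_id": pid,
            "date_of_birth": dob,
            "sex": "F" if female else "M",
            "death_date": death,
            "rac_entry_date": rac,
            "full_entitlement_start": start - timedelta(days=400),
            "health_services_year": int(rng.poisson(
                config.health_services_mean
                + 15.0 * high_severity)),
        })
        dispensings.extend(my_disp)

        # --- outcome generation (post-entry daily Bernoulli) ----------
        if not para_fills or rac_at_start:
            continue
        entry_day = para_fills[0][0]
        entry_date = start + timedelta(days=entry_day)
        L = (horizon_date - entry_date).days
        if L <= 1:
            continue
        doses = build_daily_series(
            [{"supply_date": start + timedelta(days=d),
              "strength_mg": s, "quantity": q}
             for d, s, q in para_fills],
            entry_date, horizon_date, patient_id=pid).doses
        statin = build_binary_series(
            [{"supply_date": start + timedelta(days=d),
              "strength_mg": "", "quantity": 30}
             for d in statin_days],
            entry_date, horizon_date, patient_id=pid,
            default_supply_days=config.statin_refill_days)

        age_entry = _completed_years(dob, entry_date)
        count = sum(v for c, v in categories.items()
                    if c not in _EXCLUDED_FROM_COUNT)
        cov = {
            "age_entry": age_entry,
            "female": int(female),
            "hypertension": int(categories["hypertension"]),
            "chf": int(categories["chf"]),
            "diabetes": int(categories["diabetes"]),
            "comorbidity_count": count,
            "high_severity": int(high_severity),
        }
        truth_cov[pid] = cov
        lp_fixed = (
            eff.get("age_entry", 0.0) * (age_entry - config.age_reference)
            + eff.get("female", 0.0) * cov["female"]
            + eff.get("hypertension", 0.0) * cov["hypertension"]
            + eff.get("chf", 0.0) * cov["chf"]
            + eff.get("diabetes", 0.0) * cov["diabetes"]
            + eff.get("comorbidity_count", 0.0) * count
            + (config.high_severity_log_hr if high_severity else 0.0))
        D = wce_covariates(doses, basis)            # (L+1, J)
        lp = lp_fixed + D[1:L + 1] @ config.true_weights.theta
        lp = lp + eff.get("statin", 0.0) * statin[:L]
        hazard = config.baseline_hazard * np.exp(lp)
        if np.any(hazard > 1.0):
            raise ValueError("hazard-overflow: simulated daily hazard "
                             "exceeded 1")
        draws = rng.random(L)
        hits = np.flatnonzero(draws < hazard)
        truth_entry[pid] = entry_day
        truth_hazard[pid] = hazard
        if hits.size:
            event_u = int(hits[0]) + 1       # risk days are 1-based
            truth_event[pid] = event_u
            episodes.append({
                "patient_id": pid,
                "admission_date": entry_date + timedelta(days=event_u),
                "icd10_code": str(rng.choice(_COPD_EVENT_CODES[:4])),
                "position": "primary"})

    patients_df = pd.DataFrame(patients, columns=[
        "patient_id", "date_of_birth", "sex", "death_date",
        "rac_entry_date", "full_entitlement_start",
        "health_services_year"])
    dispensings_df = pd.DataFrame(
        dispensings, columns=["patient_id", "supply_date", "atc_code",
                              "strength_mg", "quantity"])
    episodes_df = pd.DataFrame(
        episodes, columns=["patient_id", "admission_date", "icd10_code",
                           "position"])
    for df, col in ((dispensings_df, "supply_date"),
                    (episodes_df, "admission_date")):
        if not df.empty:
            df.sort_values([col, "patient_id"], inplace=True,
                           kind="stable")
            df.reset_index(drop=True, inplace=True)
    truth = SyntheticTruth(
        theta=np.asarray(config.true_weights.theta),
        covariate_effects=eff,
        weight_function=config.true_weights,
        entry_day=truth_entry,
        event_day=truth_event,
        hazards=truth_hazard,
        covariates=truth_cov,
    )
    return patients_df, dispensings_df, episodes_df, truth


def write_tables(outdir, patients, dispensings, episodes, truth=None):
    """Write the three claims tables (ISO-8601 dates) and truth JSON."""
    import pathlib

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    patients.to_csv(outdir / "patients.csv", index=False)
    dispensings.to_csv(outdir / "dispensings.csv", index=False)
    episodes.to_csv(outdir / "episodes.csv", index=False)
    if truth is not None:
        truth.to_json(outdir / "truth.json")
    return outdir
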