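"""Cohort construction from claims tables.

Implements a new-user cohort design for elderly patients with existing
chronic obstructive pulmonary disease (COPD) initiating paracetamol:

* eligibility cascade at the study start (age 45–100, 12 months of full
  claims entitlement, COPD evidence, 6-month paracetamol washout, not in
  residential aged care, initiation during the study, > 1 day follow-up);
* cohort entry on the first paracetamol dispensing after the study start,
  which avoids immortal time before initiation;
* outcome: first hospitalization after entry with a *primary* COPD
  exacerbation diagnosis (J43*, J440, J441, J448, J449); cohort-inclusion
  evidence, by contrast, accepts primary or secondary positions;
* censoring at death, residential aged-care entry or study end;
* baseline severity stratum (any COPD hospitalization or systemic
  glucocorticoid use in the 12 months before study start);
* medication-based comorbidity covariates via a configurable
  ATC-prefix-to-category mapping (a simplified, user-replaceable stand-in
  for a full medication-based comorbidity index).

The time scale of all downstream models is days since cohort entry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exposure import build_binary_series, build_daily_series

__all__ = [
    "CohortConfig",
    "DEFAULT_COMORBIDITY_MAP",
    "assess_eligibility",
    "determine_entry",
    "define_outcome_and_censoring",
    "classify_stratum",
    "derive_covariates",
    "build_cohort",
    "build_exposure_series",
    "build_statin_series",
    "build_counting_process",
    "expand_person_days",
]

logger = logging.getLogger(__name__)

#: Simplified medication-to-comorbidity mapping (ATC prefix -> category).
#: A stand-in for a full medication-based comorbidity index: small,
#: documented and user-replaceable. Statins deliberately map to no
#: category because statin use enters the models as its own covariate.
DEFAULT_COMORBIDITY_MAP: Mapping[str, str] = {
    "C09AA": "hypertension",
    "C02": "hypertension",
    "C03DA": "chf",
    "C01AA": "chf",
    "A10BA": "diabetes",
    "A10BB": "diabetes",
    "N06AB": "depression",
    "A02BC": "gord",
    "M05BA": "osteoporosis",
    "N02AA": "chronic_pain",
    "R03BB": "copd",
    "R03AC": "copd",
}

FIXED_COVARIATES = (
    "age_entry",
    "female",
    "hypertension",
    "chf",
    "diabetes",
    "comorbidity_count",
)


@dataclass
class CohortConfig:
    """Study dates, code lists and windows for cohort construction."""

    study_start: date = date(2011, 1, 1)
    study_end: date = date(2015, 9, 30)
    age_range: tuple[int, int] = (45, 100)
    lookback_days: int = 365        # baseline window for evidence/covariates
    washout_days: int = 182         # paracetamol-free window before start
    paracetamol_atc: str = "N02BE01"
    copd_med_prefix: str = "R03BB"
    copd_med_exclude: tuple[str, ...] = ("R03BB01",)
    copd_icd_patterns: tuple[str, ...] = ("J43*", "J440", "J441", "J448",
                                          "J449")
    glucocorticoid_prefix: str = "H02AB"
    statin_prefix: str = "C10AA"
    comorbidity_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_COMORBIDITY_MAP))
    comorbidity_count_excludes: tuple[str, ...] = (
        "hypertension", "chf", "diabetes", "copd")


# ----------------------------------------------------------------------
# code matching helpers

def _norm_icd(code: str) -> str:
    return str(code).replace(".", "").strip().upper()


def matches_icd(code: str, patterns: Sequence[str]) -> bool:
    """Dot-stripped ICD-10 match; a trailing ``*`` is a prefix wildcard."""
    c = _norm_icd(code)
    for pat in patterns:
        p = _norm_icd(pat)
        if p.endswith("*"):
            if c.startswith(p[:-1]):
                return True
        elif c == p:
            return True
    return False


def _age_at(dob: date, ref: date) -> int:
    """Age in completed years at the reference date."""
    years = ref.year - dob.year
    if (ref.month, ref.day) < (dob.month, dob.day):
        years -= 1
    return years


def _as_date(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, pd.Timestamp):
        return value.date()
    if isinstance(value, date):
        return value
    if pd.isna(value):
        return None
    return pd.Timestamp(value).date()


# ----------------------------------------------------------------------
# eligibility cascade

def _copd_evidence(dispensings, episodes, window_start, window_end,
                   config) -> bool:
    """COPD evidence: qualifying inhaled-medication dispensing or a COPD
    diagnosis in any position within the window [window_start, window_end)."""
    for rec in dispensings.itertuples():
        d = _as_date(rec.supply_date)
        code = str(rec.atc_code)
        if (window_start <= d < window_end
                and code.startswith(config.copd_med_prefix)
                and not any(code.startswith(x)
                            for x in config.copd_med_exclude)):
            return True
    for rec in episodes.itertuples():
        d = _as_date(rec.admission_date)
        if (window_start <= d < window_end
                and matches_icd(rec.icd10_code, config.copd_icd_patterns)):
            return True
    return False


def determine_entry(dispensings: pd.DataFrame, study_start: date,
                    paracetamol_atc: str = "N02BE01") -> date:
    """Cohort entry: date of the first paracetamol fill on/after study start."""
    dates = [
        _as_date(rec.supply_date)
        for rec in dispensings.itertuples()
        if str(rec.atc_code).startswith(paracetamol_atc)
        and _as_date(rec.supply_date) >= study_start
    ]
    if not dates:
        raise ValueError("no in-study paracetamol dispensing")
    return min(dates)


def assess_eligibility(patient, dispensings: pd.DataFrame,
                       episodes: pd.DataFrame,
                       config: CohortConfig) -> tuple[bool, list[str]]:
    """Apply the eligibility cascade; returns (eligible, failed gates).

    Every failed gate is reported, so exclusion counts reconcile with the
    input population.
    """
    start = config.study_start
    reasons: list[str] = []

    dob = _as_date(patient["date_of_birth"])
    if dob is None:
        raise ValueError(f"unusable record: patient "
                         f"{patient['patient_id']} has no birth date")
    lo, hi = config.age_range
    if not (lo <= _age_at(dob, start) <= hi):
        reasons.append("age-range")

    ent = _as_date(patient.get("full_entitlement_start"))
    if ent is None or ent > start - timedelta(days=config.lookback_days):
        reasons.append("entitlement")

    baseline_start = start - timedelta(days=config.lookback_days)
    if not _copd_evidence(dispensings, episodes, baseline_start, start,
                          config):
        reasons.append("no-copd-evidence")

    washout_start = start - timedelta(days=config.washout_days)
    for rec in dispensings.itertuples():
        d = _as_date(rec.supply_date)
        if (washout_start <= d < start
                and str(rec.atc_code).startswith(config.paracetamol_atc)):
            reasons.append("prior-paracetamol")
            break

    rac = _as_date(patient.get("rac_entry_date"))
    if rac is not None and rac <= start:
        reasons.append("residential-care")

    try:
        entry = determine_entry(dispensings, start, config.paracetamol_atc)
    except ValueError:
        entry = None
    if entry is None or entry > config.study_end:
        reasons.append("no-initiation")
    else:
        end_date, _, _ = _censoring(patient, entry, config)
        if (end_date - entry).days <= 1:
            reasons.append("insufficient-followup")

    return (not reasons), reasons


# ----------------------------------------------------------------------
# outcome, censoring, stratum, covariates

def _censoring(patient, entry: date, config: CohortConfig):
    """Censoring date = min(death, residential-care entry, study end)."""
    candidates = {"study-end": config.study_end}
    death = _as_date(patient.get("death_date"))
    if death is not None:
        candidates["death"] = death
    rac = _as_date(patient.get("rac_entry_date"))
    if rac is not None and rac > entry:
        candidates["rac"] = rac
    reason = min(candidates, key=lambda k: candidates[k])
    return candidates[reason], reason, candidates


def define_outcome_and_censoring(patient, entry: date,
                                 episodes: pd.DataFrame,
                                 config: CohortConfig):
    """First primary-position COPD exacerbation admission after entry.

    Returns ``(event, end_date, reason)`` where ``reason`` is "event" or
    the censoring cause. Only primary-position diagnoses count as the
    outcome; admissions on or before the entry date are ignored.
    """
    censor_date, censor_reason, _ = _censoring(patient, entry, config)
    event_dates = [
        _as_date(rec.admission_date)
        for rec in episodes.itertuples()
        if str(rec.position) == "primary"
        and matches_icd(rec.icd10_code, config.copd_icd_patterns)
        and _as_date(rec.admission_date) > entry
    ]
    if event_dates:
        first = min(event_dates)
        if first <= censor_date:
            return True, first, "event"
    return False, censor_date, censor_reason


def classify_stratum(dispensings: pd.DataFrame, episodes: pd.DataFrame,
                     config: CohortConfig) -> str:
    """Baseline severity: "high" iff a COPD hospitalization or a systemic
    glucocorticoid dispensing occurred in the 12 months before study start."""
    start = config.study_start
    w0 = start - timedelta(days=config.lookback_days)
    for rec in dispensings.itertuples():
        d = _as_date(rec.supply_date)
        if (w0 <= d < start
                and str(rec.atc_code).startswith(
                    config.glucocorticoid_prefix)):
            return "high"
    for rec in episodes.itertuples():
        d = _as_date(rec.admission_date)
        if (w0 <= d < start
                and matches_icd(rec.icd10_code, config.copd_icd_patterns)):
            return "high"
    return "low"


def map_comorbidities(atc_codes, comorbidity_map: Mapping[str, str]):
    """Distinct comorbidity categories hit by a collection of ATC codes.

    Longest-prefix wins when several map entries match one code. Unmapped
    codes count in no category.
    """
    cats = set()
    unmapped = set()
    for code in atc_codes:
        code = str(code)
        best = None
        for prefix, cat in comorbidity_map.items():
            if code.startswith(prefix):
                if best is None or len(prefix) > len(best[0]):
                    best = (prefix, cat)
        if best is not None:
            cats.add(best[1])
        else:
            unmapped.add(code)
    if unmapped:
        logger.debug("unmapped ATC codes ignored: %s", sorted(unmapped))
    return cats


def derive_covariates(patient, dispensings: pd.DataFrame, entry: date,
                      config: CohortConfig) -> dict:
    """Fixed-in-time baseline covariates from the 12 months before entry."""
    w0 = entry - timedelta(days=config.lookback_days)
    codes = [
        str(rec.atc_code) for rec in dispensings.itertuples()
        if w0 <= _as_date(rec.supply_date) < entry
    ]
    cats = map_comorbidities(codes, config.comorbidity_map)
    count = len(cats - set(config.comorbidity_count_excludes))
    dob = _as_date(patient["date_of_birth"])
    return {
        "age_entry": _age_at(dob, entry),
        "female": int(str(patient["sex"]).upper().startswith("F")),
        "hypertension": int("hypertension" in cats),
        "chf": int("chf" in cats),
        "diabetes": int("diabetes" in cats),
        "comorbidity_count": count,
    }


# ----------------------------------------------------------------------
# cohort assembly

def build_cohort_reference(patients: pd.DataFrame,
                           dispensings: pd.DataFrame,
                           episodes: pd.DataFrame,
                           config: CohortConfig | None = None
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Patient-at-a-time cascade using the per-operation functions.

    Readable reference implementation; :func:`build_cohort` is the
    vectorized equivalent and must agree with it row for row.
    """
    config = config or CohortConfig()
    disp_by = dict(tuple(dispensings.groupby("patient_id")))
    epi_by = dict(tuple(episodes.groupby("patient_id")))
    empty_disp = dispensings.iloc[0:0]
    empty_epi = episodes.iloc[0:0]

    rows, excl = [], []
    for patient in patients.to_dict("records"):
        pid = patient["patient_id"]
        disp = disp_by.get(pid, empty_disp)
        epi = epi_by.get(pid, empty_epi)
        ok, reasons = assess_eligibility(patient, disp, epi, config)
        if not ok:
            excl.extend({"patient_id": pid, "reason": r} for r in reasons)
            continue
        entry = determine_entry(disp, config.study_start,
                                config.paracetamol_atc)
        event, end_date, reason = define_outcome_and_censoring(
            patient, entry, epi, config)
        cov = derive_covariates(patient, disp, entry, config)
        rows.append({
            "patient_id": pid,
            "entry_date": entry,
            "end_date": end_date,
            "followup_days": (end_date - entry).days,
            "event": int(event),
            "end_reason": reason,
            "stratum": classify_stratum(disp, epi, config),
            **cov,
        })
    members = pd.DataFrame(rows, columns=MEMBER_COLUMNS)
    exclusions = pd.DataFrame(excl, columns=["patient_id", "reason"])
    return members, exclusions


MEMBER_COLUMNS = [
    "patient_id", "entry_date", "end_date", "followup_days", "event",
    "end_reason", "stratum", *FIXED_COVARIATES,
]


def _match_icd_series(codes: pd.Series, patterns) -> pd.Series:
    norm = codes.astype(str).str.replace(".", "", regex=False) \
        .str.strip().str.upper()
    mask = pd.Series(False, index=codes.index)
    for pat in patterns:
        p = _norm_icd(pat)
        if p.endswith("*"):
            mask |= norm.str.startswith(p[:-1])
        else:
            mask |= norm == p
    return mask


def build_cohort(patients: pd.DataFrame, dispensings: pd.DataFrame,
                 episodes: pd.DataFrame, config: CohortConfig | None = None
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full cascade and return (members, exclusions).

    ``members`` has one row per eligible patient with entry/end dates,
    event indicator, follow-up length in days, severity stratum and fixed
    covariates. ``exclusions`` has one row per (patient, failed gate), so
    reason counts reconcile with the input population. Vectorized
    whole-table implementation of the same cascade as
    :func:`build_cohort_reference`.
    """
    config = config or CohortConfig()
    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)
    baseline_start = start - pd.Timedelta(days=config.lookback_days)
    washout_start = start - pd.Timedelta(days=config.washout_days)

    pats = patients.copy()
    for col in ("date_of_birth", "death_date", "rac_entry_date",
                "full_entitlement_start"):
        pats[col] = pd.to_datetime(pats[col], errors="coerce")
    if pats["date_of_birth"].isna().any():
        bad = pats.loc[pats["date_of_birth"].isna(), "patient_id"]
        raise ValueError(f"unusable record: missing birth date for "
                         f"{list(bad)[:5]}")
    pats = pats.set_index("patient_id", drop=False)

    disp = dispensings.copy()
    disp["supply_date"] = pd.to_datetime(disp["supply_date"])
    atc = disp["atc_code"].astype(str)
    is_para = atc.str.startswith(config.paracetamol_atc)
    is_copd_med = atc.str.startswith(config.copd_med_prefix)
    for x in config.copd_med_exclude:
        is_copd_med &= ~atc.str.startswith(x)
    is_gc = atc.str.startswith(config.glucocorticoid_prefix)
    d = disp["supply_date"]

    epi = episodes.copy()
    if not epi.empty:
        epi["admission_date"] = pd.to_datetime(epi["admission_date"])
        epi_copd = _match_icd_series(epi["icd10_code"],
                                     config.copd_icd_patterns)
    else:
        epi["admission_date"] = pd.to_datetime(epi.get(
            "admission_date", pd.Series(dtype=object)))
        epi_copd = pd.Series(False, index=epi.index)

    def pid_set(frame_mask, frame, col="patient_id"):
        return set(frame.loc[frame_mask, col])

    # --- per-gate sets ------------------------------------------------
    age = pats["date_of_birth"].apply(
        lambda dob: _age_at(dob.date(), config.study_start))
    lo, hi = config.age_range
    age_ok = (age >= lo) & (age <= hi)

    ent_ok = pats["full_entitlement_start"].notna() & (
        pats["full_entitlement_start"] <= baseline_start)

    med_evidence = pid_set(is_copd_med & (d >= baseline_start)
                           & (d < start), disp)
    hosp_evidence = pid_set(
        epi_copd & (epi["admission_date"] >= baseline_start)
        & (epi["admission_date"] < start), epi)
    copd_ok = pats["patient_id"].isin(med_evidence | hosp_evidence)

    washout_hit = pid_set(is_para & (d >= washout_start) & (d < start),
                          disp)
    rac_at_start = pats["rac_entry_date"].notna() & (
        pats["rac_entry_date"] <= start)

    entry = disp.loc[is_para & (d >= start), ["patient_id", "supply_date"]
                     ].groupby("patient_id")["supply_date"].min()
    entry = entry[entry <= end]
    pats["entry"] = pats["patient_id"].map(entry)

    censor = pd.concat([
        pats["death_date"],
        pats["rac_entry_date"].where(pats["rac_entry_date"]
                                     > pats["entry"]),
        pd.Series(end, index=pats.index),
    ], axis=1).min(axis=1)
    followup = (censor - pats["entry"]).dt.days

    reasons = {
        "age-range": ~age_ok,
        "entitlement": ~ent_ok,
        "no-copd-evidence": ~copd_ok,
        "prior-paracetamol": pats["patient_id"].isin(washout_hit),
        "residential-care": rac_at_start,
        "no-initiation": pats["entry"].isna(),
        "insufficient-followup": pats["entry"].notna() & (followup <= 1),
    }
    excl_rows = []
    any_reason = pd.Series(False, index=pats.index)
    for name, mask in reasons.items():
        any_reason |= mask
        excl_rows.extend({"patient_id": pid, "reason": name}
                         for pid in pats.loc[mask, "patient_id"])
    exclusions = pd.DataFrame(excl_rows, columns=["patient_id", "reason"])
    exclusions = exclusions.sort_values(
        "patient_id", kind="stable").reset_index(drop=True)

    elig = pats.loc[~any_reason].copy()
    if elig.empty:
        return pd.DataFrame(columns=MEMBER_COLUMNS), exclusions

    # --- outcome ------------------------------------------------------
    epi_primary = epi.loc[epi_copd & (epi["position"].astype(str)
                                      == "primary"),
                          ["patient_id", "admission_date"]].copy()
    epi_primary["entry"] = epi_primary["patient_id"].map(elig["entry"])
    post = epi_primary.loc[
        epi_primary["entry"].notna()
        & (epi_primary["admission_date"] > epi_primary["entry"])]
    first_event = post.groupby("patient_id")["admission_date"].min()
    elig["event_date"] = elig["patient_id"].map(first_event)
    elig["censor_date"] = censor.loc[elig.index]
    has_event = elig["event_date"].notna() & (
        elig["event_date"] <= elig["censor_date"])
    elig["end_date"] = elig["censor_date"].where(~has_event,
                                                 elig["event_date"])
    elig["event"] = has_event.astype(int)

    at_study_end = elig["censor_date"] == end   # study-end wins ties
    death_is_end = elig["death_date"].notna() & (
        elig["death_date"] == elig["censor_date"]) & ~at_study_end
    rac_is_end = elig["rac_entry_date"].notna() & (
        elig["rac_entry_date"] == elig["censor_date"]) \
        & ~death_is_end & ~at_study_end
    elig["end_reason"] = np.select(
        [has_event, death_is_end, rac_is_end],
        ["event", "death", "rac"], default="study-end")

    # --- stratum ------------------------------------------------------
    gc_hit = pid_set(is_gc & (d >= baseline_start) & (d < start), disp)
    elig["stratum"] = np.where(
        elig["patient_id"].isin(gc_hit | hosp_evidence), "high", "low")

    # --- covariates (12 months before entry) --------------------------
    dd = disp.merge(
        elig[["patient_id", "entry"]].reset_index(drop=True),
        on="patient_id")
    in_window = (dd["supply_date"] >= dd["entry"]
                 - pd.Timedelta(days=config.lookback_days)) \
        & (dd["supply_date"] < dd["entry"])
    dd = dd.loc[in_window, ["patient_id", "atc_code"]]
    cat = pd.Series(pd.NA, index=dd.index, dtype=object)
    code = dd["atc_code"].astype(str)
    for prefix in sorted(config.comorbidity_map, key=len):
        cat[code.str.startswith(prefix)] = config.comorbidity_map[prefix]
    dd = dd.assign(category=cat).dropna(subset=["category"])
    cat_sets = dd.drop_duplicates(["patient_id", "category"]) \
        .groupby("patient_id")["category"].agg(set)
    cats = elig["patient_id"].map(cat_sets).apply(
        lambda s: s if isinstance(s, set) else set())
    excludes = set(config.comorbidity_count_excludes)
    elig["hypertension"] = cats.apply(
        lambda s: int("hypertension" in s)).to_numpy()
    elig["chf"] = cats.apply(lambda s: int("chf" in s)).to_numpy()
    elig["diabetes"] = cats.apply(lambda s: int("diabetes" in s)).to_numpy()
    elig["comorbidity_count"] = cats.apply(
        lambda s: len(s - excludes)).to_numpy()
    elig["age_entry"] = [
        _age_at(dob.date(), e.date())
        for dob, e in zip(elig["date_of_birth"], elig["entry"])]
    elig["female"] = elig["sex"].astype(str).str.upper() \
        .str.startswith("F").astype(int)

    members = pd.DataFrame({
        "patient_id": elig["patient_id"].to_numpy(),
        "entry_date": [t.date() for t in elig["entry"]],
        "end_date": [t.date() for t in elig["end_date"]],
        "followup_days": (elig["end_date"] - elig["entry"]).dt.days
        .to_numpy(),
        "event": elig["event"].to_numpy(),
        "end_reason": elig["end_reason"].to_numpy(),
        "stratum": elig["stratum"].to_numpy(),
        **{k: elig[k].to_numpy() for k in FIXED_COVARIATES},
    })
    extra = [c for c in ("health_services_year",) if c in elig.columns]
    for c in extra:
        members[c] = elig[c].to_numpy()
    return members.reset_index(drop=True), exclusions


def build_exposure_series(members: pd.DataFrame, dispensings: pd.DataFrame,
                          config: CohortConfig | None = None) -> dict:
    """Daily paracetamol dose series per member, origin at cohort entry."""
    config = config or CohortConfig()
    para = dispensings[
        dispensings["atc_code"].astype(str).str.startswith(
            config.paracetamol_atc)]
    by = dict(tuple(para.groupby("patient_id")))
    out = {}
    for m in members.itertuples():
        disp = by.get(m.patient_id, para.iloc[0:0])
        series = build_daily_series(
            disp, _as_date(m.entry_date), _as_date(m.end_date),
            patient_id=m.patient_id)
        out[m.patient_id] = series.doses
    return out


def build_statin_series(members: pd.DataFrame, dispensings: pd.DataFrame,
                        config: CohortConfig | None = None,
                        default_supply_days: int = 30) -> dict:
    """Daily binary statin coverage per member, origin at cohort entry."""
    config = config or CohortConfig()
    statin = dispensings[
        dispensings["atc_code"].astype(str).str.startswith(
            config.statin_prefix)]
    by = dict(tuple(statin.groupby("patient_id")))
    out = {}
    for m in members.itertuples():
        disp = by.get(m.patient_id, statin.iloc[0:0])
        out[m.patient_id] = build_binary_series(
            disp, _as_date(m.entry_date), _as_date(m.end_date),
            patient_id=m.patient_id,
            default_supply_days=default_supply_days)
    return out


def build_counting_process(members: pd.DataFrame, exposures: Mapping,
                           statins: Mapping | None = None) -> pd.DataFrame:
    """Coalesced counting-process table.

    One row per maximal interval ``[start, stop)`` of follow-up days on
    which the daily dose and the statin indicator are both constant. A
    covariate attached to the interval applies to risk (event) days
    ``start + 1 .. stop``: the model evaluates time-varying covariates
    from the day before each risk day. The event flag sits on the final
    interval of event patients. ``start`` doubles as the day index for
    weighted-cumulative-exposure lookups.
    """
    rows = []
    for m in members.itertuples():
        L = int(m.followup_days)
        x = np.asarray(exposures[m.patient_id], dtype=float)
        if x.size != L:
            raise ValueError(
                f"internal consistency failure: exposure length {x.size} "
                f"!= follow-up {L} for patient {m.patient_id}")
        s = (np.asarray(statins[m.patient_id], dtype=float)
             if statins is not None else np.zeros(L))
        if s.size != L:
            raise ValueError("internal consistency failure: statin length")
        tv = np.column_stack([x, s])
        change = np.ones(L, dtype=bool)
        change[1:] = np.any(tv[1:] != tv[:-1], axis=1)
        starts = np.flatnonzero(change)
        stops = np.append(starts[1:], L)
        fixed = {k: getattr(m, k) for k in FIXED_COVARIATES}
        for a, b in zip(starts, stops):
            rows.append({
                "patient_id": m.patient_id,
                "start": int(a),
                "stop": int(b),
                "event": int(m.event) if b == L else 0,
                "stratum": m.stratum,
                **fixed,
                "statin": s[a],
                "dose_g": x[a],
            })
    return pd.DataFrame(rows)


def expand_person_days(table: pd.DataFrame) -> pd.DataFrame:
    """Expand a counting-process table to one row per person-day.

    Row ``(u - 1, u]`` carries the covariates applying to risk day ``u``.
    Used by brute-force likelihood oracles and external fitters.
    """
    rows = []
    for r in table.itertuples():
        for u in range(int(r.start) + 1, int(r.stop) + 1):
            rows.append({
                "patient_id": r.patient_id,
                "start": u - 1,
                "stop": u,
                "event": int(r.event) if u == int(r.stop) else 0,
                "stratum": r.stratum,
                **{k: getattr(r, k) for k in FIXED_COVARIATES},
                "statin": r.statin,
                "dose_g": r.dose_g,
            })
    return pd.DataFrame(rows)
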