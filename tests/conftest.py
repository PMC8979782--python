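"""Shared fixtures: small simulated populations and hand-built cohorts."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from wcesurv.evaluation import run_pipeline
from wcesurv.simulate import SimulationConfig


@pytest.fixture(scope="session")
def small_pipeline():
    """Full pipeline output on a 300-patient simulated population."""
    return run_pipeline(SimulationConfig(n_patients=300, seed=42))


@pytest.fixture(scope="session")
def midsize_pipeline():
    """Pipeline output large enough for stable model fits (~120 events)."""
    return run_pipeline(SimulationConfig(n_patients=900, seed=2024))


def make_members(rows):
    """Build a members table from (pid, followup, event, stratum, Z...)"""
    entry = date(2011, 3, 1)
    recs = []
    for r in rows:
        rec = {
            "patient_id": r["pid"],
            "entry_date": entry,
            "end_date": entry + timedelta(days=r["followup"]),
            "followup_days": r["followup"],
            "event": int(r["event"]),
            "end_reason": "event" if r["event"] else "study-end",
            "stratum": r.get("stratum", "low"),
        }
        for k in ("age_entry", "female", "hypertension", "chf",
                  "diabetes", "comorbidity_count"):
            rec[k] = r.get(k, 0)
        recs.append(rec)
    return pd.DataFrame(recs)


@pytest.fixture
def tiny_cohort():
    """Eight hand-laid subjects, two strata, staggered follow-up."""
    rng = np.random.default_rng(7)
    rows = []
    followups = [30, 45, 45, 60, 75, 90, 110, 120]
    events = [1, 0, 1, 1, 0, 1, 0, 1]
    strata = ["low", "low", "low", "high", "high", "low", "high", "high"]
    for i, (L, e, s) in enumerate(zip(followups, events, strata)):
        rows.append({"pid": f"T{i}", "followup": L, "event": e,
                     "stratum": s, "age_entry": 70 + i,
                     "female": i % 2})
    members = make_members(rows)
    exposures = {f"T{i}": np.round(
        rng.choice([0.0, 4.0], size=L, p=[0.4, 0.6]), 2)
        for i, L in enumerate(followups)}
    statins = {f"T{i}": (rng.random(L) < 0.5).astype(float)
               for i, L in enumerate(followups)}
    return members, exposures, statins
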