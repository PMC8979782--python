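"""Small constructors shared across test modules."""

from datetime import date, timedelta

import pandas as pd


def simple_member(pid="A", followup=3, event=1, stratum="low", **cov):
    entry = date(2011, 3, 1)
    rec = {
        "patient_id": pid,
        "entry_date": entry,
        "end_date": entry + timedelta(days=followup),
        "followup_days": followup,
        "event": int(event),
        "end_reason": "event" if event else "study-end",
        "stratum": stratum,
        "age_entry": cov.get("age_entry", 80),
        "female": cov.get("female", 0),
        "hypertension": cov.get("hypertension", 0),
        "chf": cov.get("chf", 0),
        "diabetes": cov.get("diabetes", 0),
        "comorbidity_count": cov.get("comorbidity_count", 0),
    }
    return pd.DataFrame([rec])
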