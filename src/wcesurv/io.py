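"""Reading and writing the pipeline's tabular and fit artifacts.

Claims tables travel as CSV with ISO-8601 dates; fitted models serialize
to JSON carrying the spline descriptor, coefficients and covariance, so
hazard-ratio predictions can be recomputed without refitting.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .basis import SplineWeightBasis

__all__ = [
    "read_patients", "read_dispensings", "read_episodes",
    "write_fit_json", "read_fit_json", "restore_predictor",
]

_DATE_COLS = {
    "patients": ["date_of_birth", "death_date", "rac_entry_date",
                 "full_entitlement_start"],
    "dispensings": ["supply_date"],
    "episodes": ["admission_date"],
}


def _read(path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in _DATE_COLS[kind]:
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], format="ISO8601",
                                     errors="coerce")
    return df


def read_patients(path) -> pd.DataFrame:
    return _read(path, "patients")


def read_dispensings(path) -> pd.DataFrame:
    return _read(path, "dispensings")


def read_episodes(path) -> pd.DataFrame:
    return _read(path, "episodes")


def write_fit_json(model, path) -> None:
    """Serialize a fitted WCE model (Cox or conditional-logistic)."""
    payload = {
        "names": list(model.names_),
        "coef": np.asarray(model.coef_).tolist(),
        "covariance": np.asarray(model.covariance_).tolist(),
        "loglik": model.loglik_,
        "bic": model.bic_,
        "kind": type(model).__name__,
    }
    if hasattr(model, "basis_"):
        payload["basis"] = {
            "window": model.basis_.window,
            "n_interior_knots": model.basis_.n_interior_knots,
            "constrained": model.basis_.constrained,
        }
        payload["theta"] = np.asarray(model.theta_).tolist()
        payload["theta_covariance"] = \
            np.asarray(model.theta_covariance_).tolist()
    if hasattr(model, "n_events_"):
        payload["n_events"] = int(model.n_events_)
    Path(path).write_text(json.dumps(payload, indent=1))


def read_fit_json(path) -> dict:
    return json.loads(Path(path).read_text())


class restore_predictor:
    """Pattern-HR predictor rebuilt from a fit JSON (no refitting).

    Exposes ``weight_function`` / ``predict_pattern_hr`` / ``hr_surface``
    with the same semantics as the fitted estimators.
    """

    def __init__(self, payload: dict):
        from .cox import WCEPredictionMixin

        if "basis" not in payload:
            raise ValueError("fit JSON carries no spline basis")
        b = payload["basis"]
        self.basis_ = SplineWeightBasis(
            window=b["window"], n_interior_knots=b["n_interior_knots"],
            constrained=b["constrained"])
        self.theta_ = np.asarray(payload["theta"])
        self.theta_covariance_ = np.asarray(payload["theta_covariance"])
        self.names_ = payload["names"]
        self.coef_ = np.asarray(payload["coef"])
        self.covariance_ = np.asarray(payload["covariance"])
        mixin = WCEPredictionMixin
        self.weight_function = mixin.weight_function.__get__(self)
        self.predict_pattern_hr = mixin.predict_pattern_hr.__get__(self)
        self.hr_surface = mixin.hr_surface.__get__(self)
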