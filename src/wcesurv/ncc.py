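"""Nested case–control arm: incidence-density sampling and conditional
logistic weighted-cumulative-exposure models.

Cases are the cohort members who experience the outcome; each case's
index date is its event date. Controls are sampled from members still at
risk on that date (entered, under follow-up, no event on or before the
index date), matched on sex, age at the index date (within 2 years) and
the date of the first paracetamol dispensing (within 30 days). Controls
may be reused across sets and may become cases later. Incidence-density
sampling makes the conditional-logistic odds ratios estimate the Cox
hazard ratios, so the WCE weight function estimated here is directly
comparable with the full-cohort fit.
"""

from __future__ import annotations

import logging
from types import SimpleNamespace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .basis import SplineWeightBasis, WeightFunction
from .cox import WCEPredictionMixin, _newton

__all__ = [
    "sample_risk_sets",
    "WCEConditionalLogit",
    "ConventionalConditionalLogit",
    "fit_wce_clogit",
    "conventional_clogit",
]

logger = logging.getLogger(__name__)


def _dates(series) -> np.ndarray:
    return pd.to_datetime(series).to_numpy()


def sample_risk_sets(members: pd.DataFrame, seed: int,
                     n_controls: int = 2, age_caliper: float = 2.0,
                     entry_caliper_days: int = 30
                     ) -> tuple[pd.DataFrame, list]:
    """Incidence-density sampling of matched sets from a cohort table.

    For each case, the eligible pool contains members who are under
    follow-up at the case's index date with no event on or before it, of
    the same sex, within ``age_caliper`` years of age at the index date,
    and whose first paracetamol dispensing (cohort entry) lies within
    ``entry_caliper_days`` of the case's. ``n_controls`` are drawn
    uniformly without replacement within the set; sampling across sets is
    independent, so reuse is possible. Cases with an empty pool are
    reported in the second return value, not raised.

    Returns ``(sets, unmatched_case_ids)`` where ``sets`` has one row per
    set member (columns: set_id, case_id, patient_id, role, index_date).
    """
    rng = np.random.default_rng(seed)
    entry = _dates(members["entry_date"])
    end = _dates(members["end_date"])
    event = members["event"].to_numpy(dtype=bool)
    female = members["female"].to_numpy()
    age_entry = members["age_entry"].to_numpy(dtype=float)
    pids = members["patient_id"].to_numpy()

    case_order = np.flatnonzero(event)
    # deterministic case ordering: by index date then patient id
    case_order = case_order[np.lexsort(
        (pids[case_order].astype(str), end[case_order]))]

    day = np.timedelta64(1, "D")
    rows, unmatched = [], []
    set_id = 0
    for ci in case_order:
        c = end[ci]
        under_followup = (entry <= c) & np.where(event, end > c, end >= c)
        age_at_index = age_entry + (c - entry) / day / 365.25
        pool = (under_followup
                & (female == female[ci])
                & (np.abs(age_at_index - age_at_index[ci]) <= age_caliper)
                & (np.abs((entry - entry[ci]) / day) <= entry_caliper_days))
        pool[ci] = False
        pool_idx = np.flatnonzero(pool)
        if pool_idx.size == 0:
            unmatched.append(pids[ci])
            continue
        take = min(n_controls, pool_idx.size)
        controls = rng.choice(pool_idx, size=take, replace=False)
        index_date = pd.Timestamp(c).date()
        rows.append({"set_id": set_id, "case_id": pids[ci],
                     "patient_id": pids[ci], "role": "case",
                     "index_date": index_date})
        for k in np.sort(controls):
            rows.append({"set_id": set_id, "case_id": pids[ci],
                         "patient_id": pids[k], "role": "control",
                         "index_date": index_date})
        set_id += 1
    return pd.DataFrame(rows), unmatched


# ----------------------------------------------------------------------
# conditional logistic likelihood


class _ConditionalLogitLikelihood:
    """Conditional logistic log likelihood over matched sets.

    Each set contributes ``eta_case - log sum_k exp(eta_k)``. Covariates
    are centered for numerical stability (invariant to location shifts).
    """

    def __init__(self, X: np.ndarray, case_row: np.ndarray,
                 groups: list[np.ndarray]):
        self.center = X.mean(axis=0)
        self.X = X - self.center
        self.case_row = case_row
        self.groups = groups
        # the Newton driver only queries the parameter count
        self.design = SimpleNamespace(n_params=X.shape[1])

    def loglik(self, par):
        return self.loglik_score_info(par)[0]

    def loglik_score_info(self, par):
        p = self.X.shape[1]
        eta = self.X @ par
        ll = 0.0
        score = np.zeros(p)
        info = np.zeros((p, p))
        for g, case in zip(self.groups, self.case_row):
            e = eta[g]
            c = e.max()
            w = np.exp(e - c)
            S = w.sum()
            prob = w / S
            Xg = self.X[g]
            mean = prob @ Xg
            ll += eta[case] - (np.log(S) + c)
            score += self.X[case] - mean
            info += (Xg * prob[:, None]).T @ Xg - np.outer(mean, mean)
        return ll, score, info


def _member_lookup(members: pd.DataFrame) -> dict:
    return {m.patient_id: m for m in members.itertuples()}


def _wce_at_index(doses: np.ndarray, u: int,
                  basis: SplineWeightBasis) -> np.ndarray:
    """``D_j`` at day offset ``u``: doses at lags ``1..T`` before ``u``."""
    x = np.asarray(doses, dtype=float)
    lo = max(0, u - basis.window)
    lagged = x[lo:u][::-1]              # lag 1 first
    return lagged @ basis.matrix[: lagged.size]


class WCEConditionalLogit(WCEPredictionMixin, BaseEstimator):
    """Conditional-logistic WCE model on matched case–control sets.

    The linear predictor of member ``k`` of set ``s`` is
    ``sum_j theta_j D_j(index_s) + beta' Z_k`` with the WCE covariates
    evaluated from each member's own dosing history at the set's index
    date. The default adjustment covariates are the baseline comorbidity
    indicators and count, any statin use in the 30 days before the index
    date, and the log-transformed annual health-service count (natural
    log of count + 1) when a ``health_services_year`` column is present.
    """

    def __init__(self, window: int = 75, n_interior_knots: int = 1,
                 constrained: bool = False, knot_placement: str = "equal",
                 covariates: Sequence[str] = ("hypertension", "chf",
                                              "diabetes",
                                              "comorbidity_count"),
                 use_statin: bool = True, statin_window_days: int = 30,
                 use_health_services: bool = True,
                 max_iter: int = 100, tol_score: float = 1e-8,
                 tol_loglik: float = 1e-10):
        self.window = window
        self.n_interior_knots = n_interior_knots
        self.constrained = constrained
        self.knot_placement = knot_placement
        self.covariates = covariates
        self.use_statin = use_statin
        self.statin_window_days = statin_window_days
        self.use_health_services = use_health_services
        self.max_iter = max_iter
        self.tol_score = tol_score
        self.tol_loglik = tol_loglik

    # ------------------------------------------------------------------
    def _member_row(self, m, u: int, exposures, statins, basis):
        z = [float(getattr(m, c)) for c in self.covariates]
        if self.use_statin and statins is not None:
            s = np.asarray(statins[m.patient_id], dtype=float)
            lo = max(0, u - self.statin_window_days)
            z.append(float(s[lo:u].max(initial=0.0) > 0))
        if self.use_health_services and hasattr(m, "health_services_year"):
            z.append(float(np.log1p(m.health_services_year)))
        D = _wce_at_index(exposures[m.patient_id], u, basis)
        return np.concatenate([z, D])

    def fit(self, sets: pd.DataFrame, members: pd.DataFrame,
            exposures: Mapping, statins: Mapping | None = None):
        if sets.empty:
            raise ValueError("no matched sets")
        basis = SplineWeightBasis(self.window, self.n_interior_knots,
                                  self.constrained, self.knot_placement)
        lookup = _member_lookup(members)
        names = list(self.covariates)
        if self.use_statin and statins is not None:
            names.append("statin_30d")
        if self.use_health_services and \
                "health_services_year" in members.columns:
            names.append("log_health_services")
        names += [f"wce_{j + 1}" for j in range(basis.n_terms)]

        rows, case_rows, groups = [], [], []
        k = 0
        for _, grp in sets.groupby("set_id", sort=True):
            idx = []
            case_at = None
            index_date = pd.Timestamp(grp["index_date"].iloc[0]).date()
            for r in grp.itertuples():
                m = lookup[r.patient_id]
                u = (index_date - pd.Timestamp(m.entry_date).date()).days
                rows.append(self._member_row(m, u, exposures, statins,
                                             basis))
                if r.role == "case":
                    case_at = k
                idx.append(k)
                k += 1
            if case_at is None:
                raise ValueError("set without a case")
            groups.append(np.asarray(idx))
            case_rows.append(case_at)
        X = np.asarray(rows)
        lik = _ConditionalLogitLikelihood(X, np.asarray(case_rows), groups)
        n_identical = sum(
            1 for g in groups
            if np.all(X[g] == X[g[0]]))
        if n_identical:
            logger.info("%d sets have identical covariate rows and carry "
                        "no information", n_identical)
        par, ll, score, info, n_iter = _newton(
            lik, self.max_iter, self.tol_score, self.tol_loglik)
        self.coef_ = par
        self.names_ = names
        self.loglik_ = float(ll)
        self.covariance_ = np.linalg.inv(info)
        self.n_sets_ = len(groups)
        self.n_iter_ = n_iter
        self.converged_ = True
        p = len(names)
        self.bic_ = -2.0 * self.loglik_ + p * np.log(self.n_sets_)
        J = basis.n_terms
        self.basis_ = basis
        self.theta_ = par[-J:]
        self.beta_ = par[:-J]
        self.theta_covariance_ = self.covariance_[-J:, -J:]
        self.weight_function_ = WeightFunction(basis, self.theta_)
        return self

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.covariance_))
        z = self.coef_ / se
        return pd.DataFrame({
            "parameter": self.names_,
            "coef": self.coef_,
            "se": se,
            "or": np.exp(self.coef_),
            "p": 2 * stats.norm.sf(np.abs(z)),
        })


class ConventionalConditionalLogit(BaseEstimator):
    """Comparator conditional-logistic models with fixed-window exposure.

    ``metric`` is ``mean_dose`` (mean g/day over the window before the
    index date, pre-entry days counting as zero) or ``any_exposure``
    (binary indicator of any dose in the window). Standard windows are
    7, 15, 30, 60, 75 and 90 days; any positive window is accepted.
    """

    STANDARD_WINDOWS = (7, 15, 30, 60, 75, 90)

    def __init__(self, metric: str = "mean_dose", window_days: int = 30,
                 covariates: Sequence[str] = ("hypertension", "chf",
                                              "diabetes",
                                              "comorbidity_count"),
                 use_statin: bool = True, statin_window_days: int = 30,
                 use_health_services: bool = True,
                 max_iter: int = 100, tol_score: float = 1e-8,
                 tol_loglik: float = 1e-10):
        self.metric = metric
        self.window_days = window_days
        self.covariates = covariates
        self.use_statin = use_statin
        self.statin_window_days = statin_window_days
        self.use_health_services = use_health_services
        self.max_iter = max_iter
        self.tol_score = tol_score
        self.tol_loglik = tol_loglik

    def fit(self, sets: pd.DataFrame, members: pd.DataFrame,
            exposures: Mapping, statins: Mapping | None = None):
        if self.metric not in ("mean_dose", "any_exposure"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.window_days < 1:
            raise ValueError("window_days must be positive")
        lookup = _member_lookup(members)
        w = self.window_days
        names = list(self.covariates)
        use_statin = self.use_statin and statins is not None
        use_hs = self.use_health_services and \
            "health_services_year" in members.columns
        if use_statin:
            names.append("statin_30d")
        if use_hs:
            names.append("log_health_services")
        names.append(self.metric)

        rows, case_rows, groups = [], [], []
        k = 0
        for _, grp in sets.groupby("set_id", sort=True):
            idx = []
            case_at = None
            index_date = pd.Timestamp(grp["index_date"].iloc[0]).date()
            for r in grp.itertuples():
                m = lookup[r.patient_id]
                u = (index_date - pd.Timestamp(m.entry_date).date()).days
                z = [float(getattr(m, c)) for c in self.covariates]
                if use_statin:
                    s = np.asarray(statins[m.patient_id], dtype=float)
                    lo = max(0, u - self.statin_window_days)
                    z.append(float(s[lo:u].max(initial=0.0) > 0))
                if use_hs:
                    z.append(float(np.log1p(m.health_services_year)))
                x = np.asarray(exposures[m.patient_id], dtype=float)
                windowed = x[max(0, u - w):u]
                if self.metric == "mean_dose":
                    z.append(float(windowed.sum() / w))
                else:
                    z.append(float(np.any(windowed > 0)))
                rows.append(np.asarray(z))
                if r.role == "case":
                    case_at = k
                idx.append(k)
                k += 1
            groups.append(np.asarray(idx))
            case_rows.append(case_at)
        X = np.asarray(rows)
        lik = _ConditionalLogitLikelihood(X, np.asarray(case_rows), groups)
        par, ll, score, info, n_iter = _newton(
            lik, self.max_iter, self.tol_score, self.tol_loglik)
        self.coef_ = par
        self.names_ = names
        self.loglik_ = float(ll)
        self.covariance_ = np.linalg.inv(info)
        self.n_sets_ = len(groups)
        self.bic_ = -2.0 * self.loglik_ + len(names) * np.log(self.n_sets_)
        self.exposure_coef_ = par[-1]
        self.converged_ = True
        return self


def fit_wce_clogit(sets, members, exposures, statins=None,
                   **kwargs) -> WCEConditionalLogit:
    """Fit a :class:`WCEConditionalLogit`; thin functional wrapper."""
    return WCEConditionalLogit(**kwargs).fit(sets, members, exposures,
                                             statins)


def conventional_clogit(sets, members, exposures, statins=None,
                        metric: str = "mean_dose", window_days: int = 30,
                        **kwargs) -> ConventionalConditionalLogit:
    """Fit a :class:`ConventionalConditionalLogit`; thin wrapper."""
    return ConventionalConditionalLogit(
        metric=metric, window_days=window_days, **kwargs
    ).fit(sets, members, exposures, statins)
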