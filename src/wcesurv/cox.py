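"""Stratified Cox models with weighted-cumulative-exposure covariates.

The weighted cumulative exposure (WCE) of a patient on follow-up day ``u``
is ``sum_{t<u} w(u - t) X(t)``: past daily doses ``X(t)`` weighted by a
lag-dependent weight function ``w``. Expanding ``w`` on a spline basis
``B_j`` turns this into ``J`` time-varying covariates

    D_j(u) = sum_{l=1..T} B_j(l) X(u - l),

so the spline coefficients ``theta`` are ordinary Cox regression
coefficients and the whole model — WCE terms plus conventional covariates,
stratified by baseline severity — is estimated by maximizing the
stratified partial likelihood with Newton–Raphson. Everything downstream
(weight-function confidence bands, hazard ratios of arbitrary exposure
patterns, BIC-based window/knot selection) is read off the fitted
``(theta, beta)`` and their joint covariance.

Time runs in days since cohort entry. Events happen on integer risk days
``u = 1..L``; the covariate value used at risk day ``u`` derives from
day-level data up to day ``u - 1`` (doses strictly before ``u``, the
statin/exposure status of the day leading into ``u``), so same-day doses
never inform their own day's risk.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .basis import SplineWeightBasis, WeightFunction
from .cohort import FIXED_COVARIATES

__all__ = [
    "WCECoxModel",
    "ConventionalCoxModel",
    "ConvergenceError",
    "fit_wce_cox",
    "select_model",
    "wce_covariates",
]

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Raised when Newton–Raphson fails to converge ("fit-failure")."""


# ----------------------------------------------------------------------
# design assembly


def wce_covariates(doses: np.ndarray, basis: SplineWeightBasis,
                   day_u: int | None = None) -> np.ndarray:
    """WCE covariates ``D_j(u) = sum_l B_j(l) X(u-l)`` via convolution.

    ``doses[t]`` is the dose on day ``t`` of follow-up. Returns the full
    array of shape ``(L + 1, J)`` indexed by risk day ``u = 0..L`` (row 0
    is zero — no past doses exist), or the single row ``day_u``.
    """
    x = np.asarray(doses, dtype=float)
    L = x.size
    kern = basis.kernel()  # (T+1, J), row 0 = 0
    D = np.empty((L + 1, basis.n_terms))
    for j in range(basis.n_terms):
        D[:, j] = np.convolve(x, kern[:, j])[: L + 1]
    if day_u is not None:
        return D[day_u]
    return D


@dataclass
class _CoxDesign:
    """Per-patient arrays feeding the stratified partial likelihood."""

    followup: np.ndarray          # (n,) int, days of follow-up L_i
    event: np.ndarray             # (n,) bool, event at day L_i
    stratum: np.ndarray           # (n,) stratum labels
    fixed: np.ndarray             # (n, q) fixed covariates
    varying: list                 # n arrays (L_i + 1, r), value at risk day u
    names: list                   # q + r covariate names, fixed first

    @property
    def n_params(self) -> int:
        return len(self.names)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


def _build_design(members: pd.DataFrame, varying_fn, varying_names,
                  covariates: Sequence[str]) -> _CoxDesign:
    followup = members["followup_days"].to_numpy(dtype=int)
    event = members["event"].to_numpy(dtype=bool)
    stratum = members["stratum"].to_numpy()
    fixed = members[list(covariates)].to_numpy(dtype=float) \
        if covariates else np.zeros((len(members), 0))
    varying = [varying_fn(pid, L)
               for pid, L in zip(members["patient_id"], followup)]
    names = list(covariates) + list(varying_names)
    return _CoxDesign(followup, event, stratum, fixed, varying, names)


class _PartialLikelihood:
    """Stratified Cox partial likelihood, score and information.

    Risk sets are formed within stratum on the days-since-entry time
    scale; tied event days are handled by the Efron or Breslow method.
    Covariates are centered internally (a location shift leaves the
    partial likelihood invariant) for numerical stability.
    """

    def __init__(self, design: _CoxDesign, ties: str = "efron"):
        if ties not in ("efron", "breslow"):
            raise ValueError("ties must be 'efron' or 'breslow'")
        self.ties = ties
        self.design = design
        p = design.n_params
        q = design.fixed.shape[1]

        center_sum = np.zeros(p)
        center_n = 0

        # pad time-varying covariates into (n, Lmax + 1, r) for fast
        # risk-set gathers; days past a patient's follow-up are never read
        r = p - q
        Lmax = int(design.followup.max(initial=0))
        pad = np.zeros((len(design.varying), Lmax + 1, r))
        for i, v in enumerate(design.varying):
            pad[i, : v.shape[0]] = v

        # Pre-gather, per (stratum, event day): covariate matrix of the
        # risk set and positions of the tied events within it.
        self.blocks = []  # (Xu, event_rows, day)
        for s in np.unique(design.stratum):
            in_s = np.flatnonzero(design.stratum == s)
            L_s = design.followup[in_s]
            ev_s = design.event[in_s]
            event_days = np.unique(L_s[ev_s])
            for u in event_days:
                at_risk = in_s[L_s >= u]
                Xu = np.empty((at_risk.size, p))
                Xu[:, :q] = design.fixed[at_risk]
                Xu[:, q:] = pad[at_risk, u, :]
                is_event = (design.followup[at_risk] == u) \
                    & design.event[at_risk]
                self.blocks.append((Xu, np.flatnonzero(is_event), int(u)))
                center_sum += Xu.sum(axis=0)
                center_n += Xu.shape[0]

        self.center = center_sum / max(center_n, 1)
        for Xu, _, _ in self.blocks:
            Xu -= self.center

    def loglik(self, par: np.ndarray) -> float:
        return self.loglik_score_info(par)[0]

    def loglik_score_info(self, par: np.ndarray):
        p = self.design.n_params
        ll = 0.0
        score = np.zeros(p)
        info = np.zeros((p, p))
        for Xu, ev, _ in self.blocks:
            eta = Xu @ par
            c = eta.max()
            w = np.exp(eta - c)
            d = ev.size
            S0 = w.sum()
            S1 = Xu.T @ w
            S2 = (Xu * w[:, None]).T @ Xu
            wd = w[ev]
            Xd = Xu[ev]
            Sd0 = wd.sum()
            Sd1 = Xd.T @ wd
            Sd2 = (Xd * wd[:, None]).T @ Xd
            ll += eta[ev].sum()
            score += Xd.sum(axis=0)
            fr = (np.arange(d) / d) if self.ties == "efron" else np.zeros(d)
            for f in fr:
                denom = S0 - f * Sd0
                m = (S1 - f * Sd1) / denom
                ll -= np.log(denom) + c
                score -= m
                info += (S2 - f * Sd2) / denom - np.outer(m, m)
        return ll, score, info


def _newton(pll: _PartialLikelihood, max_iter: int, tol_score: float,
            tol_loglik: float):
    p = pll.design.n_params
    par = np.zeros(p)
    ll, score, info = pll.loglik_score_info(par)
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(score)) < tol_score:
            converged = True
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            ridge = 1e-8 * max(np.trace(info) / max(p, 1), 1.0)
            step = np.linalg.solve(info + ridge * np.eye(p), score)
        # step-halving until the log partial likelihood does not decrease
        factor = 1.0
        for _ in range(30):
            cand = par + factor * step
            ll_new, score_new, info_new = pll.loglik_score_info(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            factor /= 2.0
        else:
            raise ConvergenceError("fit-failure: step-halving exhausted")
        rel_change = abs(ll_new - ll) / (abs(ll) + 1.0)
        par, ll, score, info = cand, ll_new, score_new, info_new
        if rel_change < tol_loglik:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"fit-failure: no convergence after {max_iter} iterations "
            f"(max |score| = {np.max(np.abs(score)):.3g})")
    if np.max(np.abs(par)) > 50:
        warnings.warn("monotone-likelihood: possible separation "
                      "(a coefficient exceeds 50 in absolute value)")
    return par, ll, score, info, n_iter


# ----------------------------------------------------------------------
# estimators


class _BaseCoxModel(BaseEstimator):
    """Shared machinery: fitting, BIC, Schoenfeld diagnostics."""

    def _fit_design(self, design: _CoxDesign):
        if design.n_events == 0:
            raise ValueError("no events in the data")
        pll = _PartialLikelihood(design, ties=self.ties)
        par, ll, score, info, n_iter = _newton(
            pll, self.max_iter, self.tol_score, self.tol_loglik)
        self.coef_ = par
        self.loglik_ = float(ll)
        self.covariance_ = np.linalg.inv(info)
        self.n_events_ = design.n_events
        self.n_iter_ = n_iter
        self.converged_ = True
        p = design.n_params
        self.bic_ = -2.0 * self.loglik_ + p * np.log(design.n_events)
        self.names_ = list(design.names)
        self._pll = pll
        self._design = design
        return self

    # -- diagnostics ----------------------------------------------------
    def schoenfeld_residuals(self) -> tuple[np.ndarray, np.ndarray, list]:
        """Per-event Schoenfeld residuals and risk-set covariance.

        Returns ``(times, residuals, variances)`` with one entry per
        event (tied events contribute separately), residuals measured
        against the risk-set weighted covariate mean.
        """
        par = self.coef_
        times, resid, variances = [], [], []
        for Xu, ev, u in self._pll.blocks:
            if ev.size == 0:
                continue
            eta = Xu @ par
            w = np.exp(eta - eta.max())
            S0 = w.sum()
            mean = (Xu.T @ w) / S0
            V = (Xu * w[:, None]).T @ Xu / S0 - np.outer(mean, mean)
            for i in ev:
                times.append(u)
                resid.append(Xu[i] - mean)
                variances.append(V)
        order = np.argsort(times, kind="stable")
        return (np.asarray(times)[order],
                np.asarray(resid)[order],
                [variances[i] for i in order])

    def schoenfeld_test(self, transform: str = "km") -> pd.DataFrame:
        """Score test for proportional hazards from Schoenfeld residuals.

        Tests a zero slope of the residuals on a transform of event time
        (default: one minus the Kaplan–Meier survival estimate). Returns
        one row per parameter plus a GLOBAL row with a chi-square test.
        """
        times, resid, variances = self.schoenfeld_residuals()
        d = times.size
        if d < 3:
            raise ValueError("untestable: fewer than 3 events")
        g = self._time_transform(times, transform)
        gc = g - g.mean()
        u_stat = gc @ resid
        var = np.zeros((len(self.names_),) * 2)
        for gk, Vk in zip(gc, variances):
            var += gk * gk * Vk
        rows = []
        for j, name in enumerate(self.names_):
            vj = var[j, j]
            chi2 = (u_stat[j] ** 2 / vj) if vj > 0 else 0.0
            rows.append({"parameter": name, "chi2": chi2, "df": 1,
                         "p": float(stats.chi2.sf(chi2, 1))})
        vinv = np.linalg.pinv(var)
        chi2_g = float(u_stat @ vinv @ u_stat)
        df_g = int(np.linalg.matrix_rank(var))
        rows.append({"parameter": "GLOBAL", "chi2": chi2_g, "df": df_g,
                     "p": float(stats.chi2.sf(chi2_g, df_g))})
        return pd.DataFrame(rows)

    def _time_transform(self, times: np.ndarray, transform: str):
        if transform == "identity":
            return times.astype(float)
        if transform == "rank":
            return stats.rankdata(times).astype(float)
        if transform == "km":
            # left-continuous KM of pooled follow-up, evaluated at events
            L = self._design.followup
            ev = self._design.event
            order = np.argsort(L)
            n = L.size
            surv = 1.0
            km_t, km_s = [0], [1.0]
            at_risk = n
            for u in np.unique(L):
                dying = int(((L == u) & ev).sum())
                if dying:
                    km_t.append(u)
                    km_s.append(km_s[-1] * (1 - dying / at_risk))
                at_risk -= int((L == u).sum())
            km_t = np.asarray(km_t, dtype=float)
            km_s = np.asarray(km_s)
            idx = np.searchsorted(km_t, times, side="left") - 1
            return 1.0 - km_s[np.clip(idx, 0, km_s.size - 1)]
        raise ValueError(f"unknown transform {transform!r}")

    def summary(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.covariance_))
        z = self.coef_ / se
        return pd.DataFrame({
            "parameter": self.names_,
            "coef": self.coef_,
            "se": se,
            "hr": np.exp(self.coef_),
            "hr_lower": np.exp(self.coef_ - 1.959963984540054 * se),
            "hr_upper": np.exp(self.coef_ + 1.959963984540054 * se),
            "p": 2 * stats.norm.sf(np.abs(z)),
        })


class WCEPredictionMixin:
    """Weight-function and pattern-HR predictions shared by WCE fits.

    Requires fitted attributes ``basis_``, ``theta_`` and
    ``theta_covariance_``.
    """

    def weight_function(self, level: float = 0.95) -> pd.DataFrame:
        """Estimated weight function with pointwise normal bands.

        ``w_hat(t) = b(t)' theta`` with variance ``b(t)' Cov(theta) b(t)``
        at each integer lag ``1..T``.
        """
        cov = self.theta_covariance_
        if not np.all(np.isfinite(cov)):
            raise ValueError("unstable-fit: non-finite theta covariance")
        B = self.basis_.matrix
        est = B @ self.theta_
        var = np.einsum("ij,jk,ik->i", B, cov, B)
        if np.any(var < -1e-8):
            raise ValueError("unstable-fit: negative pointwise variance")
        se = np.sqrt(np.clip(var, 0, None))
        z = stats.norm.ppf(0.5 + level / 2)
        return pd.DataFrame({
            "lag": np.arange(1, self.basis_.window + 1),
            "estimate": est,
            "lower": est - z * se,
            "upper": est + z * se,
        })

    def predict_pattern_hr(self, pattern, level: float = 0.95
                           ) -> tuple[float, float, float]:
        """Hazard ratio of an exposure pattern versus never-use.

        ``pattern[i]`` is the dose at lag ``i + 1`` days before the
        evaluation day. Returns ``(hr, lower, upper)`` from the delta
        method on ``d' theta``.
        """
        d = self.basis_.pattern_loading(pattern)
        log_hr = float(d @ self.theta_)
        var = float(d @ self.theta_covariance_ @ d)
        se = np.sqrt(max(var, 0.0))
        z = stats.norm.ppf(0.5 + level / 2)
        return (float(np.exp(log_hr)),
                float(np.exp(log_hr - z * se)),
                float(np.exp(log_hr + z * se)))

    def hr_surface(self, doses: Sequence[float],
                   durations: Sequence[int],
                   stop_lags: Sequence[int] = (0,),
                   level: float = 0.95) -> pd.DataFrame:
        """Hazard-ratio grid over dose x duration x recency.

        ``stop_lag = 0`` is current use (dose at lags ``1..duration``);
        ``stop_lag = s > 0`` is past use stopped ``s`` days ago (dose at
        lags ``s+1..s+duration``), truncated at the window.
        """
        T = self.basis_.window
        rows = []
        for s in stop_lags:
            for dur in durations:
                for dose in doses:
                    pattern = np.zeros(min(s + dur, T))
                    lo = min(s, T)
                    pattern[lo:] = dose
                    hr, lwr, upr = self.predict_pattern_hr(pattern, level)
                    rows.append({"dose": dose, "duration": dur,
                                 "stop_lag": s, "hr": hr,
                                 "lower": lwr, "upper": upr})
        return pd.DataFrame(rows)


class WCECoxModel(WCEPredictionMixin, _BaseCoxModel):
    """Stratified Cox model with spline weighted-cumulative-exposure terms.

    Parameters
    ----------
    window : int
        Time window ``T`` (days); doses further in the past carry no
        weight.
    n_interior_knots : int
        Interior knots of the cubic spline basis, equally spaced on
        ``(0, T)`` by default.
    constrained : bool
        Force the weight function smoothly to zero at the end of the
        window.
    covariates : sequence of str
        Columns of the cohort table used as fixed-in-time covariates.
    use_statin : bool
        Include the daily statin indicator as a time-varying covariate.
    ties : {"efron", "breslow"}
        Tied-event handling in the partial likelihood.

    Attributes (after ``fit``)
    --------------------------
    theta_ : spline coefficients of the weight function.
    beta_ : covariate log hazard ratios (fixed covariates, then statin).
    covariance_ : joint covariance of ``(beta_fixed, statin, theta)`` in
        the order of ``names_`` (from the inverse observed information).
    loglik_, bic_, n_events_, converged_, n_iter_ : fit diagnostics.
    """

    def __init__(self, window: int = 75, n_interior_knots: int = 1,
                 constrained: bool = False, knot_placement: str = "equal",
                 covariates: Sequence[str] = FIXED_COVARIATES,
                 use_statin: bool = True, ties: str = "efron",
                 max_iter: int = 100, tol_score: float = 1e-8,
                 tol_loglik: float = 1e-10):
        self.window = window
        self.n_interior_knots = n_interior_knots
        self.constrained = constrained
        self.knot_placement = knot_placement
        self.covariates = covariates
        self.use_statin = use_statin
        self.ties = ties
        self.max_iter = max_iter
        self.tol_score = tol_score
        self.tol_loglik = tol_loglik

    # ------------------------------------------------------------------
    def fit(self, members: pd.DataFrame, exposures: Mapping,
            statins: Mapping | None = None):
        """Fit to a cohort table plus per-patient daily dose series.

        ``exposures[pid]`` is the daily dose array (g/day, length equal
        to follow-up days); ``statins[pid]`` the daily statin indicator.
        """
        basis = SplineWeightBasis(self.window, self.n_interior_knots,
                                  self.constrained, self.knot_placement)
        use_statin = self.use_statin and statins is not None

        def tv(pid, L):
            D = wce_covariates(exposures[pid], basis)
            if use_statin:
                s = np.zeros((L + 1, 1))
                s[1:, 0] = np.asarray(statins[pid], dtype=float)[:L]
                return np.hstack([s, D])
            return D

        tv_names = (["statin"] if use_statin else []) + \
            [f"wce_{j + 1}" for j in range(basis.n_terms)]
        design = _build_design(members, tv, tv_names, self.covariates)
        self._fit_design(design)
        self.basis_ = basis
        J = basis.n_terms
        self.theta_ = self.coef_[-J:]
        self.beta_ = self.coef_[:-J]
        self.theta_covariance_ = self.covariance_[-J:, -J:]
        self.weight_function_ = WeightFunction(basis, self.theta_)
        return self


class ConventionalCoxModel(_BaseCoxModel):
    """Comparator Cox models with scalar time-varying exposure.

    ``metric`` is one of:

    * ``current_dose`` — the dose on the current day of follow-up;
    * ``mean_dose`` — mean daily dose over the ``window_days`` days before
      the current day (missing pre-entry days count as zero);
    * ``cumulative_dose`` — total dose over the same window.

    Fitted with the identical stratified partial-likelihood machinery as
    the WCE model, so BIC values are directly comparable.
    """

    def __init__(self, metric: str = "current_dose", window_days: int = 30,
                 covariates: Sequence[str] = FIXED_COVARIATES,
                 use_statin: bool = True, ties: str = "efron",
                 max_iter: int = 100, tol_score: float = 1e-8,
                 tol_loglik: float = 1e-10):
        self.metric = metric
        self.window_days = window_days
        self.covariates = covariates
        self.use_statin = use_statin
        self.ties = ties
        self.max_iter = max_iter
        self.tol_score = tol_score
        self.tol_loglik = tol_loglik

    def fit(self, members: pd.DataFrame, exposures: Mapping,
            statins: Mapping | None = None):
        if self.metric not in ("current_dose", "mean_dose",
                               "cumulative_dose"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.metric != "current_dose" and not (
                2 <= self.window_days <= 90):
            raise ValueError("window_days must lie in [2, 90]")
        use_statin = self.use_statin and statins is not None
        w = self.window_days

        def tv(pid, L):
            x = np.asarray(exposures[pid], dtype=float)
            col = np.zeros(L + 1)
            if self.metric == "current_dose":
                col[1:] = x[:L]
            else:
                kern = np.zeros(w + 1)
                kern[1:] = 1.0
                total = np.convolve(x, kern)[: L + 1]
                col = total / w if self.metric == "mean_dose" else total
            out = col[:, None]
            if use_statin:
                s = np.zeros((L + 1, 1))
                s[1:, 0] = np.asarray(statins[pid], dtype=float)[:L]
                out = np.hstack([s, out])
            return out

        tv_names = (["statin"] if use_statin else []) + [self.metric]
        design = _build_design(members, tv, tv_names, self.covariates)
        self._fit_design(design)
        self.exposure_coef_ = self.coef_[-1]
        return self


# ----------------------------------------------------------------------
# functional front-ends


def fit_wce_cox(members: pd.DataFrame, exposures: Mapping,
                statins: Mapping | None = None, window: int = 75,
                n_interior_knots: int = 1, constrained: bool = False,
                ties: str = "efron", **kwargs) -> WCECoxModel:
    """Fit a :class:`WCECoxModel`; thin functional wrapper."""
    model = WCECoxModel(window=window, n_interior_knots=n_interior_knots,
                        constrained=constrained, ties=ties, **kwargs)
    return model.fit(members, exposures, statins)


def select_model(candidates, members: pd.DataFrame, exposures: Mapping,
                 statins: Mapping | None = None,
                 **fit_kwargs) -> pd.DataFrame:
    """Fit WCE candidates ``(window, knots, constrained)``, rank by BIC.

    Ties break toward fewer parameters, then the smaller window. Failed
    fits are excluded with a logged reason; at least one candidate must
    succeed. Returns a ranked table with a ``model`` column holding the
    fitted estimators.
    """
    if len(candidates) == 0:
        raise ValueError("no candidates supplied")
    rows = []
    for cand in candidates:
        window, knots, constrained = (tuple(cand) + (False,))[:3]
        try:
            model = WCECoxModel(window=window, n_interior_knots=knots,
                                constrained=constrained,
                                **fit_kwargs).fit(members, exposures,
                                                  statins)
        except (ConvergenceError, ValueError) as exc:
            logger.warning("candidate (T=%s, k=%s, c=%s) excluded: %s",
                           window, knots, constrained, exc)
            continue
        rows.append({"window": window, "n_knots": knots,
                     "constrained": bool(constrained),
                     "bic": model.bic_, "loglik": model.loglik_,
                     "n_params": len(model.names_), "model": model})
    if not rows:
        raise ConvergenceError("fit-failure: every candidate failed")
    out = pd.DataFrame(rows).sort_values(
        ["bic", "n_params", "window"], kind="stable").reset_index(drop=True)
    out.index.name = "rank"
    return out
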