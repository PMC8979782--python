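"""Partial-likelihood machinery, WCE covariates, predictions, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from tests_helpers import simple_member
from wcesurv.basis import SplineWeightBasis
from wcesurv.cox import (ConventionalCoxModel, WCECoxModel,
                         _build_design, _newton, _PartialLikelihood,
                         select_model, wce_covariates)


# ----------------------------------------------------------------------
# WCE covariates


def test_wce_covariates_match_double_loop():
    rng = np.random.default_rng(3)
    doses = rng.choice([0.0, 3.99, 4.0], size=90)
    basis = SplineWeightBasis(window=75, n_interior_knots=1)
    D = wce_covariates(doses, basis)
    B = basis.matrix
    for u in (1, 5, 40, 75, 76, 90):
        brute = np.zeros(basis.n_terms)
        for lag in range(1, min(u, 75) + 1):
            brute += B[lag - 1] * doses[u - lag]
        np.testing.assert_allclose(D[u], brute, atol=1e-12)
    np.testing.assert_array_equal(D[0], 0.0)


def test_wce_covariates_single_dose():
    basis = SplineWeightBasis(window=75, n_interior_knots=1)
    doses = np.zeros(50)
    doses[44] = 4.0   # dose on day u-5 for u = 49
    D = wce_covariates(doses, basis, day_u=49)
    np.testing.assert_allclose(D, 4.0 * basis.design([5.0])[0], atol=1e-12)


def test_wce_covariates_zero_series():
    basis = SplineWeightBasis(window=30, n_interior_knots=2)
    np.testing.assert_array_equal(
        wce_covariates(np.zeros(40), basis), 0.0)


# ----------------------------------------------------------------------
# partial likelihood against independent oracles


def _two_group_design():
    """Six subjects, one binary covariate, no ties, single stratum."""
    rows = []
    subjects = [(10, 1, 1), (20, 1, 1), (30, 0, 1),
            (12, 1, 0), (25, 0, 0), (40, 1, 0)]
    for i, (L, e, x) in enumerate(subjects):
        rows.append({"patient_id": f"S{i}", "followup_days": L,
                     "event": e, "stratum": "all", "x": float(x)})
    members = pd.DataFrame(rows)
    design = _build_design(members, lambda pid, L: np.zeros((L + 1, 0)),
                           [], ["x"])
    return members, design, subjects


def test_two_group_cox_matches_analytic_score_root():
    _, design, subjects = _two_group_design()
    pll = _PartialLikelihood(design, ties="efron")
    par, ll, score, info, _ = _newton(pll, 100, 1e-10, 1e-12)

    def analytic_score(beta):
        # independent implementation: loop over event times directly
        s = 0.0
        for L, e, x in subjects:
            if not e:
                continue
            risk = [(Li, xi) for Li, ei, xi in subjects if Li >= L]
            num = sum(xi * np.exp(beta * xi) for _, xi in risk)
            den = sum(np.exp(beta * xi) for _, xi in risk)
            s += x - num / den
        return s

    beta_ref = brentq(analytic_score, -5, 5, xtol=1e-12)
    assert par[0] == pytest.approx(beta_ref, abs=1e-8)


def _person_day_loglik(members, exposures, statins, basis, par,
                       covariates, ties="efron"):
    """Brute-force Efron/Breslow log partial likelihood from person-days.

    Independent of the fitting code: explicit loops, covariates built by
    direct summation rather than convolution.
    """
    B = basis.matrix
    frames = []
    for m in members.itertuples():
        L = int(m.followup_days)
        x = np.asarray(exposures[m.patient_id], dtype=float)
        s = np.asarray(statins[m.patient_id], dtype=float)
        for u in range(1, L + 1):
            D = np.zeros(basis.n_terms)
            for lag in range(1, min(u, basis.window) + 1):
                D += B[lag - 1] * x[u - lag]
            z = [getattr(m, c) for c in covariates] + [s[u - 1]] + list(D)
            frames.append({"stratum": m.stratum, "u": u,
                           "event": int(m.event) and u == L,
                           "z": np.asarray(z, dtype=float)})
    ll = 0.0
    for stratum in {f["stratum"] for f in frames}:
        rows = [f for f in frames if f["stratum"] == stratum]
        event_days = sorted({f["u"] for f in rows if f["event"]})
        for u in event_days:
            risk = [f for f in rows if f["u"] == u]
            dead = [f for f in risk if f["event"]]
            eta = np.array([f["z"] @ par for f in risk])
            eta_d = np.array([f["z"] @ par for f in dead])
            d = len(dead)
            for r in range(d):
                f = r / d if ties == "efron" else 0.0
                ll -= np.log(np.exp(eta).sum() - f * np.exp(eta_d).sum())
            ll += eta_d.sum()
    return ll


def test_loglik_matches_person_day_bruteforce(tiny_cohort):
    members, exposures, statins = tiny_cohort
    model = WCECoxModel(window=20, n_interior_knots=1,
                        covariates=("age_entry", "female"))
    model.fit(members, exposures, statins)
    basis = model.basis_
    rng = np.random.default_rng(5)
    for par in (np.zeros(len(model.names_)),
                rng.normal(0, 0.05, len(model.names_)),
                model.coef_):
        ll_brute = _person_day_loglik(members, exposures, statins, basis,
                                      par, ("age_entry", "female"))
        assert model._pll.loglik(par) == pytest.approx(ll_brute, abs=1e-6)


def test_score_matches_finite_differences(tiny_cohort):
    members, exposures, statins = tiny_cohort
    model = WCECoxModel(window=20, n_interior_knots=1,
                        covariates=("age_entry",)).fit(
                            members, exposures, statins)
    pll = model._pll
    for par in (np.zeros(len(model.names_)),
                np.full(len(model.names_), 0.02)):
        _, score, info = pll.loglik_score_info(par)
        h = 1e-6
        for j in range(par.size):
            up, dn = par.copy(), par.copy()
            up[j] += h
            dn[j] -= h
            fd = (pll.loglik(up) - pll.loglik(dn)) / (2 * h)
            assert score[j] == pytest.approx(fd, abs=1e-6)
        # observed information is the negative Hessian of the log PL
        j = 0
        up, dn = par.copy(), par.copy()
        up[j] += h
        dn[j] -= h
        fd_info = -(pll.loglik_score_info(up)[1][j]
                    - pll.loglik_score_info(dn)[1][j]) / (2 * h)
        assert info[j, j] == pytest.approx(fd_info, rel=1e-4)


def test_efron_equals_breslow_without_ties(tiny_cohort):
    members, exposures, statins = tiny_cohort
    kw = dict(window=20, n_interior_knots=1, covariates=("age_entry",))
    m_e = WCECoxModel(ties="efron", **kw).fit(members, exposures, statins)
    m_b = WCECoxModel(ties="breslow", **kw).fit(members, exposures,
                                                statins)
    np.testing.assert_allclose(m_e.coef_, m_b.coef_, atol=1e-8)


def test_efron_differs_from_breslow_with_ties(small_pipeline):
    kw = dict(window=75, n_interior_knots=1, constrained=True)
    m_e = WCECoxModel(ties="efron", **kw).fit(
        small_pipeline["members"], small_pipeline["exposures"],
        small_pipeline["statins"])
    m_b = WCECoxModel(ties="breslow", **kw).fit(
        small_pipeline["members"], small_pipeline["exposures"],
        small_pipeline["statins"])
    assert not np.allclose(m_e.coef_, m_b.coef_, atol=1e-8)
    assert m_e.bic_ == pytest.approx(
        -2 * m_e.loglik_ + len(m_e.names_) * np.log(m_e.n_events_))


def test_matches_lifelines_time_varying_fitter(small_pipeline):
    """Stratified Efron fit agrees with an independent implementation."""
    import warnings

    from lifelines import CoxTimeVaryingFitter

    members = small_pipeline["members"]
    exposures = small_pipeline["exposures"]
    statins = small_pipeline["statins"]
    model = WCECoxModel(window=75, n_interior_knots=1, constrained=True,
                        covariates=("age_entry", "female")).fit(
                            members, exposures, statins)
    rows = []
    for m in members.itertuples():
        L = int(m.followup_days)
        D = wce_covariates(exposures[m.patient_id], model.basis_)
        s = statins[m.patient_id]
        for u in range(1, L + 1):
            rows.append({
                "id": m.patient_id, "start": u - 1, "stop": u,
                "event": int(m.event) if u == L else 0,
                "strat": m.stratum, "age_entry": m.age_entry,
                "female": m.female, "statin": s[u - 1],
                **{f"w{j}": D[u, j] for j in range(model.basis_.n_terms)},
            })
    df = pd.DataFrame(rows)
    ctv = CoxTimeVaryingFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ctv.fit(df, id_col="id", event_col="event", start_col="start",
                stop_col="stop", strata=["strat"])
    order = ["age_entry", "female", "statin"] + \
        [f"w{j}" for j in range(model.basis_.n_terms)]
    np.testing.assert_allclose(ctv.params_.reindex(order).to_numpy(),
                               model.coef_, atol=1e-6)
    assert ctv.log_likelihood_ == pytest.approx(model.loglik_, abs=1e-6)


# ----------------------------------------------------------------------
# predictions


def test_pattern_hr_trivials(midsize_pipeline):
    model = WCECoxModel(window=75, n_interior_knots=1,
                        constrained=True).fit(
        midsize_pipeline["members"], midsize_pipeline["exposures"],
        midsize_pipeline["statins"])
    assert model.predict_pattern_hr([]) == (1.0, 1.0, 1.0)
    assert model.predict_pattern_hr(np.zeros(75)) == (1.0, 1.0, 1.0)
    # null coefficients force HR 1 for any pattern
    null = WCECoxModel(window=75, n_interior_knots=1, constrained=True)
    null.basis_ = model.basis_
    null.theta_ = np.zeros(model.basis_.n_terms)
    null.theta_covariance_ = np.zeros((model.basis_.n_terms,) * 2)
    hr, lo, hi = null.predict_pattern_hr([4.0] * 30)
    assert (hr, lo, hi) == (1.0, 1.0, 1.0)


def test_ci_levels_nested(midsize_pipeline):
    model = WCECoxModel(window=75, n_interior_knots=1,
                        constrained=True).fit(
        midsize_pipeline["members"], midsize_pipeline["exposures"],
        midsize_pipeline["statins"])
    w95 = model.weight_function(level=0.95)
    w80 = model.weight_function(level=0.80)
    assert (w95["upper"] - w95["lower"] + 1e-15
            >= w80["upper"] - w80["lower"]).all()
    hr95 = model.predict_pattern_hr([4.0] * 7, level=0.95)
    hr80 = model.predict_pattern_hr([4.0] * 7, level=0.80)
    assert hr95[1] <= hr80[1] and hr95[2] >= hr80[2]


def test_weight_band_matches_parametric_bootstrap(midsize_pipeline):
    model = WCECoxModel(window=75, n_interior_knots=1,
                        constrained=True).fit(
        midsize_pipeline["members"], midsize_pipeline["exposures"],
        midsize_pipeline["statins"])
    rng = np.random.default_rng(11)
    draws = rng.multivariate_normal(model.theta_,
                                    model.theta_covariance_, size=10000)
    B = model.basis_.matrix
    boot_var = (draws @ B.T).var(axis=0, ddof=1)
    analytic = np.einsum("ij,jk,ik->i", B, model.theta_covariance_, B)
    keep = analytic > 1e-12
    np.testing.assert_allclose(boot_var[keep], analytic[keep], rtol=0.05)


def test_zero_covariance_collapses_bands(midsize_pipeline):
    model = WCECoxModel(window=75, n_interior_knots=1,
                        constrained=True).fit(
        midsize_pipeline["members"], midsize_pipeline["exposures"],
        midsize_pipeline["statins"])
    model.theta_covariance_ = np.zeros_like(model.theta_covariance_)
    wf = model.weight_function()
    np.testing.assert_array_equal(wf["lower"], wf["estimate"])
    np.testing.assert_array_equal(wf["upper"], wf["estimate"])


def test_hr_surface_consistency(midsize_pipeline):
    model = WCECoxModel(window=75, n_interior_knots=1,
                        constrained=True).fit(
        midsize_pipeline["members"], midsize_pipeline["exposures"],
        midsize_pipeline["statins"])
    surf = model.hr_surface(doses=[2.0, 4.0], durations=[7, 30],
                            stop_lags=[0, 10, 75, 90])
    for r in surf.itertuples():
        pattern = np.zeros(min(r.stop_lag + r.duration, 75))
        pattern[min(r.stop_lag, 75):] = r.dose
        hr, lo, hi = model.predict_pattern_hr(pattern)
        assert r.hr == pytest.approx(hr, abs=1e-12)
    # stop lags at or beyond the window: pattern leaves the memory window
    far = surf[surf["stop_lag"] >= 75]
    assert (far["hr"] == 1.0).all() and (far["lower"] == 1.0).all()
    # stop_lag 0 reproduces direct current-use predictions
    cur = surf[(surf["stop_lag"] == 0) & (surf["dose"] == 4.0)
               & (surf["duration"] == 7)]["hr"].iloc[0]
    assert cur == pytest.approx(model.predict_pattern_hr([4.0] * 7)[0])


def test_monotone_in_positive_weight_lag(midsize_pipeline):
    model = WCECoxModel(window=75, n_interior_knots=1,
                        constrained=True).fit(
        midsize_pipeline["members"], midsize_pipeline["exposures"],
        midsize_pipeline["statins"])
    w = model.weight_function()["estimate"].to_numpy()
    lag = int(np.argmax(w)) + 1
    assert w[lag - 1] > 0
    base = np.zeros(lag)
    base[-1] = 1.0
    more = base.copy()
    more[-1] = 2.0
    assert model.predict_pattern_hr(more)[0] \
        > model.predict_pattern_hr(base)[0]


# ----------------------------------------------------------------------
# model selection and conventional comparators


def test_select_model_single_and_duplicate(small_pipeline):
    members = small_pipeline["members"]
    exposures = small_pipeline["exposures"]
    statins = small_pipeline["statins"]
    one = select_model([(30, 1, True)], members, exposures, statins)
    assert len(one) == 1
    dup = select_model([(30, 1, True), (30, 1, True), (30, 0, True)],
                       members, exposures, statins)
    assert len(dup) == 3
    pair = dup[dup["n_knots"] == 1]["bic"]
    assert pair.iloc[0] == pytest.approx(pair.iloc[1], abs=1e-6)
    # ranking is deterministic: sorted by BIC, then parameter count
    assert (dup["bic"].is_monotonic_increasing
            or list(dup["n_params"]) == sorted(dup["n_params"]))


def test_cumulative_is_scaled_mean_dose(small_pipeline):
    members = small_pipeline["members"]
    kw = dict(window_days=30, covariates=("age_entry",), use_statin=False)
    mean = ConventionalCoxModel(metric="mean_dose", **kw).fit(
        members, small_pipeline["exposures"])
    cum = ConventionalCoxModel(metric="cumulative_dose", **kw).fit(
        members, small_pipeline["exposures"])
    # identical model up to covariate scaling by the window length
    assert cum.loglik_ == pytest.approx(mean.loglik_, abs=1e-6)
    assert cum.exposure_coef_ * 30 == pytest.approx(mean.exposure_coef_,
                                                    rel=1e-6)


def test_current_equals_windowed_mean_under_saturated_exposure():
    members = pd.concat([
        simple_member("A", followup=60, event=1),
        simple_member("B", followup=80, event=1),
        simple_member("C", followup=100, event=0),
        simple_member("D", followup=90, event=1, female=1),
    ], ignore_index=True)
    exposures = {p: np.full(int(L), 4.0 if p in ("A", "B") else 0.0)
                 for p, L in zip(members["patient_id"],
                                 members["followup_days"])}
    kw = dict(covariates=("female",), use_statin=False, window_days=30)
    cur = ConventionalCoxModel(metric="current_dose", **kw).fit(
        members, exposures)
    mean = ConventionalCoxModel(metric="mean_dose", **kw).fit(
        members, exposures)
    # every event day lies beyond the window, so the two exposure
    # metrics coincide at all evaluated risk sets
    assert cur.loglik_ == pytest.approx(mean.loglik_, abs=1e-9)
    np.testing.assert_allclose(cur.coef_, mean.coef_, atol=1e-6)


def test_invalid_metric_and_window():
    members = simple_member()
    with pytest.raises(ValueError, match="unknown metric"):
        ConventionalCoxModel(metric="peak_dose").fit(
            members, {"A": np.zeros(3)})
    with pytest.raises(ValueError, match="window_days"):
        ConventionalCoxModel(metric="mean_dose", window_days=120).fit(
            members, {"A": np.zeros(3)})


# ----------------------------------------------------------------------
# proportional hazards diagnostics


def test_schoenfeld_residuals_hand_example():
    """Residuals equal covariate minus risk-set weighted mean."""
    rows = []
    subjects = [(5, 1, 1.0), (8, 1, 0.0), (11, 1, 1.0), (14, 1, 0.0),
            (20, 0, 1.0)]
    for i, (L, e, x) in enumerate(subjects):
        rows.append({"patient_id": f"S{i}", "followup_days": L,
                     "event": e, "stratum": "all", "x": float(x)})
    members = pd.DataFrame(rows)
    design = _build_design(members, lambda pid, L: np.zeros((L + 1, 0)),
                           [], ["x"])
    pll = _PartialLikelihood(design)
    par, *_ = _newton(pll, 100, 1e-10, 1e-12)
    model = WCECoxModel()
    model.coef_ = par
    model.names_ = ["x"]
    model._pll = pll
    model._design = design
    times, resid, variances = model.schoenfeld_residuals()
    b = par[0]
    for t, r in zip(times, resid):
        risk = [(xi, np.exp(b * xi)) for L, e, xi in subjects if L >= t]
        mean = sum(x * w for x, w in risk) / sum(w for _, w in risk)
        x_event = next(x for L, e, x in subjects if L == t and e)
        # residuals are computed on centered covariates; centering
        # cancels in the difference
        assert r[0] == pytest.approx(x_event - mean, abs=1e-10)
    table = model.schoenfeld_test(transform="identity")
    assert ((table["p"] >= 0) & (table["p"] <= 1)).all()


def test_schoenfeld_test_requires_events():
    rows = [{"patient_id": f"S{i}", "followup_days": L, "event": e,
             "stratum": "all", "x": x}
            for i, (L, e, x) in enumerate(
                [(5, 1, 1.0), (9, 1, 0.0), (15, 0, 1.0), (20, 0, 0.0)])]
    design = _build_design(pd.DataFrame(rows),
                           lambda pid, L: np.zeros((L + 1, 0)), [], ["x"])
    pll = _PartialLikelihood(design)
    par, *_ = _newton(pll, 100, 1e-10, 1e-12)
    model = WCECoxModel()
    model.coef_ = par
    model.names_ = ["x"]
    model._pll = pll
    model._design = design
    with pytest.raises(ValueError, match="untestable"):
        model.schoenfeld_test()


def test_schoenfeld_calibration_under_proportional_hazards():
    """Under the truth (proportional hazards) gross over-rejection
    of the global test would indicate broken residual scaling."""
    from wcesurv.evaluation import run_pipeline
    from wcesurv.simulate import SimulationConfig

    rejections = 0
    n_reps = 25
    for s in range(n_reps):
        data = run_pipeline(SimulationConfig(n_patients=250,
                                             seed=9_000 + s))
        model = WCECoxModel(window=75, n_interior_knots=1,
                            constrained=True).fit(
            data["members"], data["exposures"], data["statins"])
        p = model.schoenfeld_test().set_index("parameter") \
            .loc["GLOBAL", "p"]
        rejections += int(p < 0.05)
    assert rejections / n_reps <= 0.2
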