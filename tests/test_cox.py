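"""Cox engine tests: closed forms, independent oracles, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import lfevents as lf
from lfevents.cox import RecurrentCoxModel

from conftest import make_intervals, simulate_fitted_cohort


def naive_loglik(beta, intervals, terms, ties="efron"):
    """Independent enumeration of the Efron/Breslow partial log-likelihood."""
    beta = np.asarray(beta, float)
    X = intervals[list(terms)].to_numpy(float)
    start = intervals["start"].to_numpy()
    stop = intervals["stop"].to_numpy()
    status = intervals["status"].to_numpy()
    ll = 0.0
    for t in np.unique(stop[status == 1]):
        risk = np.flatnonzero((start < t) & (t <= stop))
        dead = np.flatnonzero((status == 1) & (stop == t))
        psi = np.exp(X @ beta)
        ll += float(np.sum(X[dead] @ beta))
        d = len(dead)
        for l in range(d):
            f = l / d if ties == "efron" else 0.0
            ll -= np.log(psi[risk].sum() - f * psi[dead].sum())
    return ll


def naive_score_residuals(beta, intervals, terms, ties="efron"):
    """Score residuals from their definition, by plain loops."""
    beta = np.asarray(beta, float)
    X = intervals[list(terms)].to_numpy(float)
    start = intervals["start"].to_numpy()
    stop = intervals["stop"].to_numpy()
    status = intervals["status"].to_numpy()
    psi = np.exp(X @ beta)
    U = np.zeros_like(X)
    for t in np.unique(stop[status == 1]):
        risk = np.flatnonzero((start < t) & (t <= stop))
        dead = np.flatnonzero((status == 1) & (stop == t))
        d = len(dead)
        for l in range(d):
            f = l / d if ties == "efron" else 0.0
            # at-risk weight: 1 off the tied set, (1 - l/d) on it (Efron)
            w = np.ones(len(X))
            w[dead] = 1.0 - f
            S0 = float(np.sum(w[risk] * psi[risk]))
            v = (w[risk] * psi[risk]) @ X[risk] / S0
            for i in risk:
                U[i] -= w[i] * psi[i] * (X[i] - v) / S0
            for i in dead:
                U[i] += (X[i] - v) / d
    return U


class TestClosedForms:
    def test_two_subject_partial_likelihood(self, toy_intervals):
        spec = lf.CoxModelSpec(("x",))
        assert lf.partial_loglik([0.0], toy_intervals, spec) == pytest.approx(
            np.log(0.5), abs=1e-12
        )
        assert lf.partial_loglik([np.log(2)], toy_intervals, spec) == pytest.approx(
            np.log(2.0 / 3.0), abs=1e-12
        )

    def test_efron_tied_pair_hand_formula(self):
        # 3 subjects, 2 tied events at t=1: ll = x1b + x2b
        #   - log(S0) - log(S0 - (psi1+psi2)/2)
        iv = pd.DataFrame(
            {
                "cluster_id": [1, 2, 3],
                "start": [0.0, 0.0, 0.0],
                "stop": [1.0, 1.0, 2.0],
                "status": [1, 1, 0],
                "x": [1.0, 0.5, 0.0],
            }
        )
        b = 0.3
        psi = np.exp(b * iv["x"].to_numpy())
        expected = (
            b * 1.5 - np.log(psi.sum()) - np.log(psi.sum() - (psi[0] + psi[1]) / 2)
        )
        got = lf.partial_loglik([b], iv, lf.CoxModelSpec(("x",)))
        assert got == pytest.approx(expected, abs=1e-12)
        breslow = lf.partial_loglik([b], iv, lf.CoxModelSpec(("x",), ties="breslow"))
        assert breslow == pytest.approx(b * 1.5 - 2 * np.log(psi.sum()), abs=1e-12)


class TestDerivatives:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    def test_gradient_hessian_match_finite_differences(self, seed, ties):
        rng = np.random.default_rng(seed)
        iv = make_intervals(rng, n_subjects=6, n_cov=2)
        # force a tie to exercise the correction
        if ties == "efron":
            stops = iv.loc[iv["status"] == 1, "stop"]
            if len(stops) >= 2:
                iv.loc[stops.index[1], "stop"] = stops.iloc[0]
                iv = iv[iv["stop"] > iv["start"]]
        model = RecurrentCoxModel(iv, lf.CoxModelSpec(("x0", "x1"), ties=ties))
        beta = rng.normal(scale=0.5, size=2)
        h = 1e-5
        grad = model.score(beta)
        hess = -model.information(beta)
        for j in range(2):
            e = np.zeros(2)
            e[j] = h
            fd = (model.loglik(beta + e) - model.loglik(beta - e)) / (2 * h)
            assert grad[j] == pytest.approx(fd, abs=1e-6)
            fd_row = (model.score(beta + e) - model.score(beta - e)) / (2 * h)
            assert np.allclose(hess[:, j], fd_row, atol=1e-6)

    def test_matches_naive_enumeration(self):
        rng = np.random.default_rng(3)
        iv = make_intervals(rng, n_subjects=6, n_cov=2)
        beta = [0.4, -0.2]
        for ties in ("efron", "breslow"):
            spec = lf.CoxModelSpec(("x0", "x1"), ties=ties)
            assert lf.partial_loglik(beta, iv, spec) == pytest.approx(
                naive_loglik(beta, iv, ("x0", "x1"), ties), abs=1e-10
            )

    def test_efron_equals_breslow_without_ties(self, random_intervals):
        iv = random_intervals
        a = lf.fit_cox(iv, lf.CoxModelSpec(("x0", "x1"), ties="efron"))
        b = lf.fit_cox(iv, lf.CoxModelSpec(("x0", "x1"), ties="breslow"))
        assert np.allclose(a.params, b.params, atol=1e-10)


class TestFit:
    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_matches_brute_force_maximization(self, seed):
        rng = np.random.default_rng(seed)
        iv = make_intervals(rng, n_subjects=6, n_cov=2)
        model = RecurrentCoxModel(iv, lf.CoxModelSpec(("x0", "x1")))
        res = model.fit()
        opt = optimize.minimize(
            lambda b: -model.loglik(b),
            np.zeros(2),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 10_000},
        )
        assert res.converged
        assert np.max(np.abs(res.params.to_numpy() - opt.x)) < 1e-6

    def test_empty_model_null_loglik(self, random_intervals):
        res = lf.fit_cox(random_intervals, lf.CoxModelSpec(()))
        assert len(res.params) == 0
        assert res.loglik == pytest.approx(res.null_loglik)
        assert res.robust_cov.shape == (0, 0)

    def test_rank_deficiency_names_terms(self, random_intervals):
        iv = random_intervals.assign(x2=random_intervals["x0"])
        with pytest.raises(np.linalg.LinAlgError, match="x2"):
            lf.fit_cox(iv, lf.CoxModelSpec(("x0", "x1", "x2")))

    def test_monotone_likelihood_flagged(self):
        iv = pd.DataFrame(
            {
                "cluster_id": [1, 2, 3, 4],
                "start": [0.0] * 4,
                "stop": [1.0, 2.0, 3.0, 4.0],
                "status": [1, 1, 0, 0],
                "x": [1.0, 1.0, 0.0, 0.0],
            }
        )
        res = lf.fit_cox(iv, lf.CoxModelSpec(("x",)))
        assert not res.converged
        assert "monotone" in res.message

    def test_single_cluster_rejected(self):
        # one patient cannot support the model: every risk set is a
        # singleton, so the design is flagged before the sandwich (which
        # itself requires >= 2 clusters) is ever formed
        iv = pd.DataFrame(
            {
                "cluster_id": [1, 1],
                "start": [0.0, 1.0],
                "stop": [1.0, 2.0],
                "status": [1, 1],
                "x": [1.0, 0.0],
            }
        )
        with pytest.raises((ValueError, np.linalg.LinAlgError)):
            lf.fit_cox(iv, lf.CoxModelSpec(("x",)))


class TestRobustVariance:
    def test_score_residuals_match_naive(self):
        rng = np.random.default_rng(7)
        iv = make_intervals(rng, n_subjects=8, n_cov=2)
        res = lf.fit_cox(iv, lf.CoxModelSpec(("x0", "x1")))
        naive = naive_score_residuals(res.params.to_numpy(), iv, ("x0", "x1"))
        # engine residuals are computed on centered covariates; centering is
        # score-invariant so the residuals agree directly
        assert np.allclose(res.score_residuals, naive, atol=1e-10)

    def test_sandwich_assembly_three_subjects(self):
        iv = pd.DataFrame(
            {
                "cluster_id": [1, 2, 3],
                "start": [0.0] * 3,
                "stop": [1.0, 2.0, 3.0],
                "status": [1, 1, 0],
                "x": [1.0, 0.0, 0.5],
            }
        )
        res = lf.fit_cox(iv, lf.CoxModelSpec(("x",)))
        U = naive_score_residuals(res.params.to_numpy(), iv, ("x",))
        V = res.model_cov
        expected = V @ (U.T @ U) @ V  # one interval per cluster
        assert np.allclose(res.robust_cov, expected, atol=1e-12)

    def test_robust_close_to_model_se_for_independent_events(self):
        """With at most one event per subject the sandwich and the inverse
        information estimate the same variance."""
        spec = lf.CohortSpec(n_patients=500, seed=31, dropout_rate=0.0, max_months=12)
        cov = lf.simulate_covariates(spec)
        events, fu = lf.simulate_recurrent_events(spec, cov)
        first = events.groupby("patient_id")["time_months"].min()
        rows = []
        for pid, c in zip(fu["patient_id"], fu["person_months"]):
            t = first.get(pid, np.inf)
            if t <= c:
                rows.append((pid, 0.0, t, 1))
            else:
                rows.append((pid, 0.0, c, 0))
        iv = pd.DataFrame(rows, columns=["cluster_id", "start", "stop", "status"])
        iv = iv.merge(cov[["patient_id", "score"]], left_on="cluster_id", right_on="patient_id")
        res = lf.fit_cox(iv, lf.CoxModelSpec(("score",)))
        ratio = res.robust_se["score"] / res.model_se["score"]
        assert 0.85 < ratio < 1.15


class TestLifelinesCrossCheck:
    def test_coefficients_match_reference_implementation(self):
        from lifelines import CoxTimeVaryingFitter

        _, _, _, _, iv = simulate_fitted_cohort(seed=5, n_patients=120)
        res = lf.fit_cox(iv, lf.CoxModelSpec(("score", "female")))
        ctv = CoxTimeVaryingFitter()
        ctv.fit(
            iv.rename(columns={"cluster_id": "id", "status": "event"})[
                ["id", "start", "stop", "event", "score", "female"]
            ],
            id_col="id",
            start_col="start",
            stop_col="stop",
            event_col="event",
        )
        assert np.allclose(res.params.to_numpy(), ctv.params_.to_numpy(), atol=1e-6)

    def test_time_dependent_model_matches_episode_split(self):
        from lifelines import CoxTimeVaryingFitter

        _, _, events, _, iv = simulate_fitted_cohort(seed=6, n_patients=80)
        res = lf.fit_cox(
            iv, lf.CoxModelSpec(("score", "female"), td_terms=(("female", "identity"),))
        )
        etimes = np.sort(events["time_months"].unique())
        rows = []
        for _, r in iv.iterrows():
            cuts = (
                [r["start"]]
                + [t for t in etimes if r["start"] < t < r["stop"]]
                + [r["stop"]]
            )
            for a, b in zip(cuts[:-1], cuts[1:]):
                rows.append(
                    dict(
                        id=r["cluster_id"],
                        start=a,
                        stop=b,
                        event=int(r["status"]) if b == r["stop"] else 0,
                        score=r["score"],
                        female=r["female"],
                        female_t=r["female"] * b,
                    )
                )
        split = pd.DataFrame(rows)
        ctv = CoxTimeVaryingFitter()
        ctv.fit(split, id_col="id", start_col="start", stop_col="stop", event_col="event")
        assert np.allclose(res.params.to_numpy(), ctv.params_.to_numpy(), atol=1e-6)


class TestSchoenfeld:
    def test_residual_is_case_minus_risk_mean(self):
        iv = pd.DataFrame(
            {
                "cluster_id": [1, 2, 3, 4],
                "start": [0.0, 0.0, 1.5, 1.5],
                "stop": [1.0, 2.0, 3.0, 4.0],
                "status": [1, 0, 1, 0],
                "x": [1.0, 0.0, 1.0, 0.0],
            }
        )
        model = RecurrentCoxModel(iv, lf.CoxModelSpec(("x",)))
        resid, times, _ = model._derivs(np.zeros(1), order=0, schoenfeld=True)["schoenfeld"]
        # only two subjects at risk at each event time; mean x = 0.5
        assert np.allclose(resid.ravel(), [0.5, 0.5])
        assert np.allclose(times, [1.0, 3.0])

    def test_power_against_time_varying_effect(self):
        _, _, _, _, iv = simulate_fitted_cohort(seed=23, n_patients=400)
        res = lf.fit_cox(iv, lf.CoxModelSpec(("score", "female")))
        sch = res.schoenfeld_test()
        assert sch.table.loc["female", "p"] < 0.05
        assert set(sch.table.index) == {"score", "female"}
        assert ((sch.table["p"] >= 0) & (sch.table["p"] <= 1)).all()
        assert len(sch.residuals) == res.n_events

    def test_too_few_events_rejected(self, toy_intervals):
        res = lf.fit_cox(toy_intervals, lf.CoxModelSpec(("x",)))
        with pytest.raises(ValueError, match="fewer events"):
            res.schoenfeld_test()


class TestExtendedModel:
    def test_hr_at_time_closed_form(self, random_intervals):
        res = lf.fit_cox(
            random_intervals,
            lf.CoxModelSpec(("x0",), td_terms=(("x0", "identity"),)),
        )
        res.params[:] = [0.0, np.log(1.04)]
        assert res.hr_at_time("x0", 0.0) == pytest.approx(1.0)
        assert res.hr_at_time("x0", 1.0) == pytest.approx(1.04)
        assert res.hr_at_time("x0", 10.0) == pytest.approx(1.04**10)
        with pytest.raises(ValueError):
            res.hr_at_time("x0", -1.0)
        with pytest.raises(KeyError):
            res.hr_at_time("x1", 1.0)

    def test_two_stage_adds_violating_significant_term(self):
        _, _, _, _, iv = simulate_fitted_cohort(seed=23, n_patients=400)
        ph, sch, ext = lf.two_stage_extended_fit(iv, lf.CoxModelSpec(("score", "female")))
        assert "female" in sch.violations()
        assert "female:time" in ext.params.index
        assert ext.params["female:time"] > 0

    def test_two_stage_skips_nonsignificant_violator(self):
        # time-varying effect whose average over follow-up is ~zero:
        # PH violated but the main effect is not significant -> no extension
        spec = lf.CohortSpec(
            n_patients=400,
            seed=21,
            dropout_rate=0.0,
            max_months=12,
            log_hr={"score": np.log(1.17), "female": -0.48},
            td_log_hr={"female": 0.08},
        )
        cov = lf.simulate_covariates(spec)
        events, fu = lf.simulate_recurrent_events(spec, cov)
        iv = lf.build_intervals(events, fu, cov, "ALL6", covariate_cols=["score", "female"])
        ph, sch, ext = lf.two_stage_extended_fit(iv, lf.CoxModelSpec(("score", "female")))
        assert sch.table.loc["female", "p"] < 0.05
        assert ph.wald_p["female"] > 0.05
        assert ext is ph

    def test_no_violations_returns_ph_fit(self):
        spec = lf.CohortSpec(
            n_patients=200, seed=41, dropout_rate=0.0, max_months=12, td_log_hr={}
        )
        cov = lf.simulate_covariates(spec)
        events, fu = lf.simulate_recurrent_events(spec, cov)
        iv = lf.build_intervals(events, fu, cov, "ALL6", covariate_cols=["score", "female"])
        ph, sch, ext = lf.two_stage_extended_fit(iv, lf.CoxModelSpec(("score", "female")))
        eligible = [
            t
            for t in ("score", "female")
            if sch.table.loc[t, "p"] < 0.05 and ph.wald_p[t] < 0.05
        ]
        if eligible:
            assert set(ext.params.index) == {"score", "female"} | {
                f"{t}:time" for t in eligible
            }
        else:
            assert ext is ph


def test_summary_table_shape(random_intervals):
    res = lf.fit_cox(random_intervals, lf.CoxModelSpec(("x0", "x1")))
    table = res.summary()
    assert list(table.index) == ["x0", "x1"]
    assert (table["hr"] > 0).all()
    assert (table["hr_low"] <= table["hr"]).all() and (table["hr"] <= table["hr_high"]).all()
    assert res.n_clusters == res.model.n_clusters
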