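"""Survival-model tests: closed forms, brute-force likelihood oracles,
episode-splitting equivalence and hand-computed meta-analysis."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from ki67prog import survival_models as sm
from ki67prog._cox import partial_likelihood_at

from conftest import surv_frame


def brute_force_loglik(beta, entry, exit_, event, x):
    """Direct Breslow=Efron (tie-free) partial likelihood for one covariate."""
    ll = 0.0
    for i in np.flatnonzero(event == 1):
        t = exit_[i]
        risk = (entry < t) & (exit_ >= t)
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        df = surv_frame([0, 0, 0], [2, 4, 6], [0, 0, 0], g=["a"] * 3)
        curves = sm.km_estimate(df, "g")
        assert curves["a"].event_times.size == 0
        assert curves["a"].survival_at(5.0) == 1.0

    def test_closed_form_three_subjects(self):
        # events at 1 and 2, censored at 3: S(2) = (2/3)(1/2) = 1/3
        df = surv_frame([0, 0, 0], [1, 2, 3], [1, 1, 0], g=["a"] * 3)
        c = sm.km_estimate(df, "g")["a"]
        assert c.survival_at(1.0) == pytest.approx(2 / 3)
        assert c.survival_at(2.5) == pytest.approx(1 / 3)

    def test_delayed_entry_matches_manual_risk_sets(self):
        # five subjects, staggered entry; risk sets built by hand:
        # t=2: at risk {1,2,3} (entry<2<=exit) -> S = 2/3
        # t=4: at risk {2,4,5}                 -> S = (2/3)(2/3) = 4/9
        df = surv_frame(
            entry=[0.0, 0.0, 1.0, 3.0, 3.5],
            exit_=[2.0, 5.0, 2.5, 4.0, 6.0],
            event=[1, 0, 0, 1, 0],
            g=["a"] * 5,
        )
        c = sm.km_estimate(df, "g")["a"]
        assert c.survival_at(2.0) == pytest.approx(2 / 3)
        assert c.survival_at(4.5) == pytest.approx(4 / 9)

    def test_curves_truncated_at_horizon(self):
        df = surv_frame([0] * 4, [2, 8, 12, 15], [1, 1, 1, 1], g=["a"] * 4)
        c = sm.km_estimate(df, "g", horizon=10.0)["a"]
        assert np.all(c.event_times <= 10.0)

    def test_empty_group_rejected(self):
        df = surv_frame([5.0], [6.0], [1], g=["a"])
        with pytest.raises(ValueError, match="no entered subjects"):
            sm.km_estimate(df.assign(entry_time=[11.0], exit_time=[12.0]), "g")


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        base = surv_frame([0] * 4, [1, 2, 3, 4], [1, 1, 0, 1])
        df = pd.concat([base.assign(g="a"), base.assign(g="b")], ignore_index=True)
        stat, dof, p = sm.logrank(df, "g")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert dof == 1
        assert p == pytest.approx(1.0)

    def test_matches_lifelines_without_delayed_entry(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(2)
        n = 120
        g = rng.integers(0, 2, n)
        t = rng.exponential(5 / (1 + g), n).round(1) + 0.1
        e = rng.binomial(1, 0.7, n)
        df = surv_frame(np.zeros(n), t, e, g=g)
        stat, dof, p = sm.logrank(df, "g", horizon=np.inf)
        ref = multivariate_logrank_test(t, g, e)
        assert stat == pytest.approx(ref.test_statistic, rel=1e-9)
        assert p == pytest.approx(ref.p_value, rel=1e-9)

    def test_six_subject_two_group_hand_table(self):
        # group a: events at 1, 3; group b: event at 2, censored 4 (+2 censored)
        df = surv_frame(
            [0] * 6, [1, 3, 5, 2, 4, 6], [1, 1, 0, 1, 0, 0],
            g=["a", "a", "a", "b", "b", "b"],
        )
        stat, dof, p = sm.logrank(df, "g", horizon=np.inf)
        # hand computation: O_a = 2, E_a = 3/6 + 2/5 + 2/4 = 1.4
        # V = sum d(n-d)/ (n-1) * na/n * (1-na/n) with d=1: 0.25 + 0.24 + 0.25 = 0.74
        assert stat == pytest.approx((2 - 1.4) ** 2 / 0.74, rel=1e-9)

    def test_null_simulation_p_uniformish(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(200):
            n = 80
            g = rng.integers(0, 2, n)
            t = rng.exponential(5, n)
            e = rng.binomial(1, 0.8, n)
            ps.append(sm.logrank(surv_frame(np.zeros(n), t, e, g=g), "g", horizon=np.inf)[2])
        from scipy.stats import kstest

        assert kstest(ps, "uniform").pvalue > 0.01


class TestCoxFit:
    def test_four_subject_brute_force_oracle(self):
        # tie-free single binary covariate: grid/golden-section maximiser of
        # the explicit partial likelihood must match the Newton fitter
        entry = np.array([0.0, 0.0, 0.0, 0.0])
        exit_ = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 1, 0])
        x = np.array([1.0, 0.0, 1.0, 0.0])
        df = surv_frame(entry, exit_, event, x=x)
        fit = sm.cox_fit(df, ["x"], horizon=np.inf)
        res = minimize_scalar(
            lambda b: -brute_force_loglik(b, entry, exit_, event, x),
            bounds=(-5, 5), method="bounded",
            options={"xatol": 1e-10},
        )
        assert fit.coefficients["x"] == pytest.approx(res.x, abs=1e-4)
        assert fit.log_partial_likelihood == pytest.approx(-res.fun, abs=1e-8)

    def test_left_truncated_fixture_brute_force(self):
        entry = np.array([0.0, 0.5, 1.5, 0.0, 2.0, 0.0])
        exit_ = np.array([1.0, 2.5, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 1, 0, 1, 0])
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0])
        df = surv_frame(entry, exit_, event, x=x)
        fit = sm.cox_fit(df, ["x"], horizon=np.inf)
        res = minimize_scalar(
            lambda b: -brute_force_loglik(b, entry, exit_, event, x),
            bounds=(-5, 5), method="bounded", options={"xatol": 1e-10},
        )
        assert fit.coefficients["x"] == pytest.approx(res.x, abs=1e-4)

    def test_matches_lifelines_with_ties_and_truncation(self):
        from lifelines import CoxTimeVaryingFitter

        rng = np.random.default_rng(3)
        n = 300
        x = rng.binomial(1, 0.4, n).astype(float)
        z = rng.normal(0, 1, n)
        t = (rng.exponential(1 / (0.1 * np.exp(0.6 * x + 0.3 * z))).round(1) + 0.1)
        e = rng.binomial(1, 0.8, n)
        entry = np.where(rng.random(n) < 0.3, rng.exponential(0.5, n), 0.0)
        keep = t > entry
        df = surv_frame(entry[keep], t[keep], e[keep], x=x[keep], z=z[keep])
        fit = sm.cox_fit(df, ["x", "z"], horizon=np.inf)
        ref = CoxTimeVaryingFitter()
        ldf = df.rename(columns={"entry_time": "start", "exit_time": "stop"})
        ldf["id"] = np.arange(len(ldf))
        ref.fit(ldf, id_col="id", start_col="start", stop_col="stop", event_col="event")
        np.testing.assert_allclose(fit.coefficients.values, ref.params_.values, atol=1e-6)
        np.testing.assert_allclose(fit.se.values, ref.standard_errors_.values, atol=1e-6)

    def test_effect_recovery(self):
        rng = np.random.default_rng(4)
        betas = []
        for rep in range(20):
            n = 1000
            x = rng.binomial(1, 0.5, n).astype(float)
            t = rng.exponential(1 / (0.1 * np.exp(np.log(2) * x)))
            c = rng.exponential(10, n)
            df = surv_frame(np.zeros(n), np.minimum(t, c), (t <= c).astype(int), x=x)
            betas.append(sm.cox_fit(df, ["x"], horizon=np.inf).coefficients["x"])
        assert np.mean(betas) == pytest.approx(np.log(2), abs=0.05)

    def test_constant_covariate_rejected(self):
        df = surv_frame([0, 0, 0], [1, 2, 3], [1, 1, 0], x=[1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="constant"):
            sm.cox_fit(df, ["x"])

    def test_sign_agrees_with_km_ordering(self):
        rng = np.random.default_rng(6)
        n = 800
        x = rng.binomial(1, 0.5, n)
        t = rng.exponential(1 / (0.15 * np.exp(1.0 * x)))
        df = surv_frame(np.zeros(n), np.minimum(t, 10), ((t <= 10)).astype(int), x=x.astype(float))
        fit = sm.cox_fit(df, ["x"])
        curves = sm.km_estimate(df, df["x"].map({0: "lo", 1: "hi"}))
        assert fit.coefficients["x"] > 0
        assert curves["hi"].survival_at(5) < curves["lo"].survival_at(5)


class TestTimeVaryingCoefficient:
    def _sim(self, rng, n=800, hr0=2.0, T=0.9):
        x = rng.binomial(1, 0.35, n).astype(float)
        # piecewise-constant inversion on a fine grid
        grid = np.arange(0, 30, 0.05)
        lam = 0.05 * np.exp((np.log(hr0) + np.log(T) * (grid + 0.025))[None, :] * x[:, None])
        cum = np.cumsum(lam * 0.05, axis=1)
        u = rng.exponential(1, n)
        idx = np.argmax(cum >= u[:, None], axis=1)
        t = np.where(cum[:, -1] < u, 30.0, grid[idx] + 0.05)
        c = rng.exponential(12, n)
        exit_ = np.minimum(np.minimum(t, c), 10.0)
        event = ((t <= c) & (t <= 10.0)).astype(int)
        return surv_frame(np.zeros(n), np.maximum(exit_, 1e-3), event, x=x)

    def test_theta_zero_reproduces_plain_cox(self):
        rng = np.random.default_rng(8)
        df = self._sim(rng, n=400, hr0=2.0, T=1.0)
        plain = sm.cox_fit(df, ["x"])
        # constrained evaluation: the tvc likelihood at theta=0 equals the
        # plain partial likelihood at the same beta
        ll_tvc, _, _ = partial_likelihood_at(
            np.array([plain.coefficients["x"], 0.0]),
            df["entry_time"].to_numpy(), df["exit_time"].to_numpy(),
            df["event"].to_numpy(), df[["x"]].to_numpy(), tvc_cols=[0],
        )
        assert ll_tvc == pytest.approx(plain.log_partial_likelihood, abs=1e-6)

    def test_equals_episode_split_interaction_fit(self):
        from lifelines import CoxTimeVaryingFitter

        rng = np.random.default_rng(9)
        df = self._sim(rng, n=150, hr0=2.0, T=0.85)
        fit = sm.cox_tvc_fit(df, ["x"], tvc_vars="x")
        ets = np.sort(df.loc[df.event == 1, "exit_time"].unique())
        rows = []
        for i, r in df.iterrows():
            cuts = ets[(ets > r.entry_time) & (ets < r.exit_time)]
            edges = np.concatenate([[r.entry_time], cuts, [r.exit_time]])
            for a, b in zip(edges[:-1], edges[1:]):
                rows.append((i, a, b, int(r.event and b == r.exit_time), r.x, r.x * b))
        split = pd.DataFrame(rows, columns=["id", "start", "stop", "event", "x", "xt"])
        ref = CoxTimeVaryingFitter()
        ref.fit(split, id_col="id", start_col="start", stop_col="stop", event_col="event")
        got = fit.coefficients[["x", "x:t"]].to_numpy()
        want = ref.params_[["x", "xt"]].to_numpy()
        np.testing.assert_allclose(got, want, atol=1e-6)

    def test_recovers_waning_effect(self):
        rng = np.random.default_rng(10)
        hr0s, Ts = [], []
        for _ in range(8):
            df = self._sim(rng, n=2000, hr0=2.0, T=0.9)
            fit = sm.cox_tvc_fit(df, ["x"], tvc_vars="x")
            hr0s.append(fit.hr_baseline("x"))
            Ts.append(fit.T("x"))
        assert np.mean(hr0s) == pytest.approx(2.0, rel=0.12)
        assert np.mean(Ts) == pytest.approx(0.9, rel=0.05)

    def test_hazard_ratio_at_time_identity(self):
        rng = np.random.default_rng(12)
        df = self._sim(rng, n=300)
        fit = sm.cox_tvc_fit(df, ["x"], tvc_vars="x")
        hr5 = fit.hazard_ratio_at("x", 5.0)
        assert hr5 == pytest.approx(fit.hr_baseline("x") * fit.T("x") ** 5)


class TestModelIC:
    def test_arithmetic(self):
        fit = sm.CoxFit(
            coefficients=pd.Series([0.1, 0.2], index=["a", "b"]),
            covariance=pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"]),
            log_partial_likelihood=-100.0, n=500, n_events=100,
        )
        aic, bic = sm.model_ic(fit)
        assert aic == pytest.approx(204.0)
        assert bic == pytest.approx(200.0 + 2 * np.log(100))
        aic_s, bic_s = sm.model_ic(fit, n_for_bic=500)
        assert bic_s == pytest.approx(200.0 + 2 * np.log(500))

    def test_zero_parameters(self):
        fit = sm.CoxFit(
            coefficients=pd.Series(dtype=float),
            covariance=pd.DataFrame(),
            log_partial_likelihood=-50.0, n=10, n_events=5,
        )
        aic, bic = sm.model_ic(fit)
        assert aic == bic == 100.0


class TestHeterogeneityAndMeta:
    def test_identical_estimates_q_zero(self):
        q, dof, p = sm.subgroup_heterogeneity([0.5, 0.5, 0.5], [0.1, 0.2, 0.3])
        assert q == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_formula_q_125(self):
        q, dof, p = sm.subgroup_heterogeneity([0.0, 0.5], [0.1, 0.1])
        assert q == pytest.approx(12.5, abs=1e-10)
        assert dof == 1

    def test_meta_three_study_hand_arithmetic(self):
        per = {"A": (0.2, 0.1), "B": (0.4, 0.2), "C": (0.1, 0.1)}
        meta = sm.fixed_effect_meta(per)
        w = np.array([100.0, 25.0, 100.0])
        b = np.array([0.2, 0.4, 0.1])
        pooled = np.sum(w * b) / w.sum()
        q = np.sum(w * (b - pooled) ** 2)
        assert meta.pooled_log_hr == pytest.approx(pooled, abs=1e-14)
        assert meta.pooled_se == pytest.approx(np.sqrt(1 / w.sum()), abs=1e-14)
        assert meta.q == pytest.approx(q, abs=1e-10)
        assert meta.i2 == pytest.approx(max(0.0, (q - 2) / q), abs=1e-10)
        lo, hi = min(b), max(b)
        assert lo <= meta.pooled_log_hr <= hi

    def test_common_truth_i2_concentrates_near_zero(self):
        rng = np.random.default_rng(13)
        i2s = []
        for _ in range(100):
            ses = rng.uniform(0.1, 0.3, 6)
            est = rng.normal(0.3, ses)
            i2s.append(sm.fixed_effect_meta(
                {f"S{i}": (est[i], ses[i]) for i in range(6)}).i2)
        assert np.median(i2s) < 0.2

    def test_null_heterogeneity_p_uniform(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(14)
        ps = []
        for _ in range(300):
            ses = rng.uniform(0.1, 0.3, 5)
            est = rng.normal(0.0, ses)
            ps.append(sm.subgroup_heterogeneity(est, ses)[2])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_single_study_degenerates(self):
        meta = sm.fixed_effect_meta({"A": (0.3, 0.1)})
        assert meta.pooled_log_hr == pytest.approx(0.3)
        assert np.isnan(meta.i2)

    def test_bad_se_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            sm.subgroup_heterogeneity([0.1, 0.2], [0.1, 0.0])


class TestAdministrativeCensoring:
    def test_horizon_never_adds_events(self):
        rng = np.random.default_rng(15)
        n = 200
        df = surv_frame(
            np.zeros(n), rng.exponential(8, n), rng.binomial(1, 0.7, n),
            x=rng.binomial(1, 0.5, n).astype(float),
        )
        capped = sm.apply_horizon(df, 10.0)
        assert capped["event"].sum() <= df["event"].sum()
        assert (capped["exit_time"] <= 10.0).all()
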