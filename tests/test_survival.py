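import numpy as np
import pandas as pd
import pytest

import regscore as rs


def _surv(times, events, ids=None, **cov):
    ids = ids or [f"s{i}" for i in range(len(times))]
    df = pd.DataFrame({"time": times, "event": events, **cov}, index=ids)
    return rs.SurvivalTable(df)


def _groups(labels, ids=None):
    ids = ids or [f"s{i}" for i in range(len(labels))]
    return rs.GroupAssignment(pd.Series(labels, index=ids))


class TestKM:
    def test_product_limit_hand_example(self):
        """Times (1,2,3), all events: S = 2/3, 1/3, 0 by hand product-limit."""
        km = rs.km_fit(_surv([1.0, 2.0, 3.0], [1, 1, 1]))
        assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
        assert list(km.at_risk) == [3, 2, 1]
        # median = first time with S(t) <= 0.5 (no interpolation)
        assert km.median_survival == 2.0

    def test_greenwood_variance_hand_formula(self):
        """Greenwood: var(S) = S^2 * sum d_i / (n_i (n_i - d_i)), transcribed
        directly for a censored toy."""
        times = [1.0, 2.0, 2.0, 3.0, 4.0]
        events = [1, 1, 0, 1, 0]
        km = rs.km_fit(_surv(times, events))
        # event times 1, 2, 3 with n=(5,4,2), d=(1,1,1)
        s = np.cumprod([1 - 1 / 5, 1 - 1 / 4, 1 - 1 / 2])
        gw = np.cumsum([1 / (5 * 4), 1 / (4 * 3), 1 / (2 * 1)])
        assert np.allclose(km.survival, s, atol=1e-12)
        assert np.allclose(km.variance, s ** 2 * gw, atol=1e-12)

    def test_no_events_flat_curve(self):
        km = rs.km_fit(_surv([1.0, 2.0], [0, 0]))
        assert len(km.times) == 0
        assert km.median_survival is None

    def test_duplicating_subjects_leaves_curve_unchanged(self):
        t = [1.0, 3.0, 4.0, 7.0]
        e = [1, 0, 1, 1]
        km1 = rs.km_fit(_surv(t, e))
        km2 = rs.km_fit(_surv(t + t, e + e))
        assert np.allclose(km1.survival, km2.survival)

    def test_row_order_invariance(self):
        t = [5.0, 1.0, 3.0, 2.0]
        e = [1, 1, 0, 1]
        km1 = rs.km_fit(_surv(t, e))
        order = [2, 0, 3, 1]
        km2 = rs.km_fit(_surv([t[i] for i in order], [e[i] for i in order]))
        assert np.allclose(km1.survival, km2.survival)

    def test_matches_lifelines(self):
        """Independent cross-check against lifelines' KM estimator."""
        from lifelines import KaplanMeierFitter
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 40).round(1) + 0.1
        e = rng.integers(0, 2, 40)
        km = rs.km_fit(_surv(t, e))
        kmf = KaplanMeierFitter().fit(t, e)
        ours = pd.Series(km.survival, index=km.times)
        theirs = kmf.survival_function_["KM_estimate"]
        for tt in km.times:
            assert ours.loc[tt] == pytest.approx(theirs.loc[tt], abs=1e-10)


class TestLogrank:
    def test_identical_groups_chi2_zero(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 0, 1, 1, 0, 1]
        chi2, df, p = rs.logrank(_surv(t, e), _groups(["A"] * 3 + ["B"] * 3))
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_matches_direct_formula_transcription(self):
        """Two tie-free groups: chi-square equals the O-E/V sums written
        directly from the definition."""
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e = np.array([1, 1, 1, 1, 1, 1])
        member = np.array([0, 0, 0, 1, 1, 1])
        O = E = V = 0.0
        for tt in np.unique(t):
            at = t >= tt
            n_t = at.sum()
            d_t = ((t == tt) & (e == 1)).sum()
            n_0 = (at & (member == 0)).sum()
            O += ((t == tt) & (e == 1) & (member == 0)).sum()
            E += d_t * n_0 / n_t
            if n_t > 1:
                V += d_t * (n_0 / n_t) * (1 - n_0 / n_t) * (n_t - d_t) / (n_t - 1)
        expected = (O - E) ** 2 / V
        chi2, df, p = rs.logrank(_surv(t, e), _groups(["A"] * 3 + ["B"] * 3))
        assert chi2 == pytest.approx(expected, abs=1e-12)
        assert df == 1

    def test_matches_lifelines_three_groups(self):
        from lifelines.statistics import multivariate_logrank_test
        rng = np.random.default_rng(5)
        t = rng.exponential(5, 60).round(2) + 0.1
        e = rng.integers(0, 2, 60)
        g = rng.choice(["A", "B", "C"], 60)
        chi2, df, p = rs.logrank(_surv(t, e), _groups(list(g)))
        ll = multivariate_logrank_test(t, g, e)
        assert chi2 == pytest.approx(ll.test_statistic, abs=1e-8)
        assert df == 2
        assert p == pytest.approx(ll.p_value, abs=1e-10)

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            rs.logrank(_surv([1.0, 2.0], [1, 1]), _groups(["A", "A"]))

    def test_agrees_with_cox_score_test(self):
        """2-group log-rank coincides with the Cox score test at beta=0
        (Breslow ties), computed from the fit's machinery."""
        from regscore.survival import _design_matrix, _partial_loglik
        rng = np.random.default_rng(8)
        t = rng.exponential(5, 50)          # continuous: no ties
        e = rng.integers(0, 2, 50)
        e[0] = 1
        labels = rng.choice(["A", "B"], 50)
        surv = _surv(t, e, group=pd.Categorical(labels))
        X, _ = _design_matrix(surv, ["group"])
        _, U, info = _partial_loglik(np.zeros(1), t, e, X - X.mean(0), "breslow")
        score_chi2 = float(U[0] ** 2 / info[0, 0])
        chi2, _, _ = rs.logrank(surv, _groups(list(labels)))
        assert chi2 == pytest.approx(score_chi2, abs=1e-6)


class TestCox:
    def test_breslow_toy_matches_grid_oracle(self):
        """6-subject toy with tied event times: Newton-Raphson beta equals a
        grid maximization of the Breslow partial likelihood within 1e-3."""
        t = np.array([2.0, 2.0, 3.0, 4.0, 5.0, 5.0])
        e = np.array([1, 1, 1, 0, 1, 1])
        x = np.array([1.0, 0.0, 1.0, 0.0, 1.0, 0.0])

        def breslow_ll(b):
            ll = 0.0
            for tt in np.unique(t[e == 1]):
                risk = t >= tt
                d = (t == tt) & (e == 1)
                ll += b * x[d].sum() - d.sum() * np.log(np.exp(b * x[risk]).sum())
            return ll

        grid = np.arange(-5.0, 5.0, 1e-4)
        beta_grid = grid[np.argmax([breslow_ll(b) for b in grid])]
        fit = rs.cox_fit(_surv(t, e, x=x), ["x"], ties="breslow")
        assert fit.beta[0] == pytest.approx(beta_grid, abs=1e-3)
        assert fit.loglik >= fit.loglik_null

    def test_efron_equals_breslow_without_ties(self):
        rng = np.random.default_rng(11)
        t = rng.exponential(5, 40)
        e = rng.integers(0, 2, 40)
        e[:5] = 1
        x = rng.normal(size=40)
        fe = rs.cox_fit(_surv(t, e, x=x), ["x"], ties="efron")
        fb = rs.cox_fit(_surv(t, e, x=x), ["x"], ties="breslow")
        assert fe.beta[0] == pytest.approx(fb.beta[0], abs=1e-9)
        assert fe.se[0] == pytest.approx(fb.se[0], abs=1e-9)

    def test_matches_lifelines_efron(self):
        """Independent cross-check of beta and SE against lifelines CoxPHFitter
        (Efron ties), including tied event times."""
        from lifelines import CoxPHFitter
        rng = np.random.default_rng(13)
        n = 80
        x = rng.normal(size=n)
        t = np.ceil(rng.exponential(5, n) * np.exp(-0.5 * x))
        e = rng.integers(0, 2, n)
        e[:5] = 1
        df = pd.DataFrame({"T": t, "E": e, "x": x})
        cph = CoxPHFitter().fit(df, "T", "E")
        fit = rs.cox_fit(_surv(t, e, x=x), ["x"])
        # lifelines' own stopping rule is looser than ours (verified against
        # a tighter-tolerance fit); compare at 1e-4
        assert fit.beta[0] == pytest.approx(cph.params_["x"], abs=1e-4)
        assert fit.se[0] == pytest.approx(cph.standard_errors_["x"], abs=1e-4)

    def test_null_covariate_unbiased(self):
        betas = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 300
            x = rng.normal(size=n)
            t = rng.exponential(10, n)
            e = np.ones(n, dtype=int)
            betas.append(rs.cox_fit(_surv(t, e, x=x), ["x"]).beta[0])
        assert abs(np.mean(betas)) < 0.02

    def test_constant_covariate_errors(self):
        with pytest.raises(ValueError, match="constant"):
            rs.cox_fit(_surv([1.0, 2.0, 3.0], [1, 1, 1], x=[1.0, 1.0, 1.0]),
                       ["x"])

    def test_separation_capped_with_warning(self):
        t = [1.0, 2.0, 3.0, 10.0, 11.0, 12.0]
        e = [1, 1, 1, 1, 1, 1]
        x = [1.0, 1.0, 1.0, 0.0, 0.0, 0.0]
        fit = rs.cox_fit(_surv(t, e, x=x), ["x"])
        assert fit.capped
        assert abs(fit.beta[0]) <= 15.0

    def test_categorical_covariate_one_hot(self):
        rng = np.random.default_rng(17)
        n = 60
        g = rng.choice(["wt", "mut"], n)
        t = rng.exponential(5, n) * np.where(g == "mut", 0.5, 1.0)
        e = np.ones(n, dtype=int)
        fit = rs.cox_fit(_surv(t, e, genotype=pd.Categorical(g)), ["genotype"])
        assert fit.terms == ["genotype[wt]"]
        assert fit.beta[0] < 0  # wt has lower hazard than reference 'mut'


class TestForest:
    def test_table_shape_and_order(self):
        t = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        e = [1, 1, 0, 1, 1, 1]
        f1 = rs.cox_fit(_surv(t, e, x=[0.1, 0.9, 0.3, 0.8, 0.2, 0.7]), ["x"])
        tab = rs.forest_table([f1])
        assert list(tab["term"]) == ["x"]
        assert (tab["ci95_low"] <= tab["HR"]).all()
        assert (tab["HR"] <= tab["ci95_high"]).all()
        assert rs.forest_table([]).empty
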