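"""Random-intercept mixed model: likelihood, selection, derived statistics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from pulseval import error_model as em


def simulate(n_subj, n_per, beta, sigma_b, sigma_e, rng, x_cols=("ita", "hr")):
    """Balanced random-intercept data with known generating parameters.

    ``ita`` is a between-subject covariate (pigmentation), ``hr`` varies
    within subject (criterion heart rate).
    """
    subj = np.repeat(np.arange(n_subj), n_per)
    ita = np.repeat(rng.normal(11.9, 39.2, n_subj), n_per)
    hr = rng.normal(120, 25, n_subj * n_per)
    X = pd.DataFrame({"ita": ita, "hr": hr})[list(x_cols)]
    lin = beta[0] + X.to_numpy() @ np.asarray(beta[1:])
    y = lin + np.repeat(rng.normal(0, sigma_b, n_subj), n_per) \
        + rng.normal(0, sigma_e, n_subj * n_per)
    return y, X, subj


class TestFit:
    def test_no_between_subject_variance_recovers_ols(self, rng):
        y, X, subj = simulate(15, 20, [2.0, -0.01, 0.005], 0.0, 1.0, rng)
        fit = em.fit_random_intercept(y, X, subj)
        Z = np.column_stack([np.ones(len(y)), X.to_numpy()])
        ols = np.linalg.lstsq(Z, y, rcond=None)[0]
        assert fit.sigma2_b == pytest.approx(0.0, abs=1e-4)
        assert np.allclose(fit.beta.to_numpy(), ols, atol=1e-5)

    def test_grid_search_oracle_on_small_data(self, rng):
        """The profiled optimum matches a brute-force grid over the variance
        ratio on a small balanced dataset."""
        y, X, subj = simulate(6, 8, [1.0, 0.0, 0.01], 0.8, 1.5, rng)
        fit = em.fit_random_intercept(y, X, subj)

        def loglik_at(lam):
            n = len(y)
            Z = np.column_stack([np.ones(n), X.to_numpy()])
            V = np.eye(n)
            for s in np.unique(subj):
                idx = np.flatnonzero(subj == s)
                V[np.ix_(idx, idx)] += lam
            Vi = np.linalg.inv(V)
            beta = np.linalg.solve(Z.T @ Vi @ Z, Z.T @ Vi @ y)
            r = y - Z @ beta
            s2 = (r @ Vi @ r) / n
            _, logdet = np.linalg.slogdet(V)
            return -0.5 * (n * np.log(2 * np.pi * s2) + logdet + n), beta

        grid = np.exp(np.linspace(-8, 4, 2000))
        lls = [loglik_at(g)[0] for g in grid]
        best = int(np.argmax(lls))
        assert fit.loglik >= lls[best] - 1e-4
        _, beta_ref = loglik_at(grid[best])
        assert np.allclose(fit.beta.to_numpy(), beta_ref, atol=1e-3)

    def test_matches_statsmodels_ml(self):
        rng = np.random.default_rng(17)
        y, X, subj = simulate(20, 25, [3.0, -0.01, -0.02], 1.0, 2.0, rng)
        fit = em.fit_random_intercept(y, X, subj)
        df = X.assign(y=y, subj=subj)
        ref = smf.mixedlm("y ~ ita + hr", df, groups=df["subj"]).fit(reml=False)
        assert ref.converged
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-4)
        assert fit.loglik >= ref.llf - 1e-6  # never worse than the reference
        assert fit.beta["ita"] == pytest.approx(ref.params["ita"], abs=1e-6)
        assert fit.beta["hr"] == pytest.approx(ref.params["hr"], abs=1e-6)
        assert fit.sigma2_e == pytest.approx(ref.scale, rel=1e-3)
        assert fit.beta_se["hr"] == pytest.approx(ref.bse["hr"], rel=5e-2)

    def test_loglik_at_least_ols(self, rng):
        """The mixed fit nests sigma2_b = 0, so its likelihood cannot be
        lower than the OLS likelihood."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            y, X, subj = simulate(8, 6, [1.0, 0.005, 0.0], 0.5, 1.0, r)
            fit = em.fit_random_intercept(y, X, subj)
            n = len(y)
            Z = np.column_stack([np.ones(n), X.to_numpy()])
            res = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
            s2 = res @ res / n
            ll_ols = -0.5 * n * (np.log(2 * np.pi * s2) + 1)
            assert fit.loglik >= ll_ols - 1e-8

    def test_parameter_recovery_at_study_scale(self):
        rng = np.random.default_rng(7)
        y, X, subj = simulate(28, 80, [4.0, -0.011, 0.0], np.sqrt(0.3),
                              2.0, rng)
        fit = em.fit_random_intercept(y, X, subj)
        assert abs(fit.beta["ita"] - (-0.011)) < 2 * fit.beta_se["ita"]
        assert fit.sigma2_e == pytest.approx(4.0, rel=0.25)
        assert fit.sigma2_b == pytest.approx(0.3, rel=0.9)

    def test_one_observation_per_subject_flagged(self, rng):
        y = rng.normal(0, 1, 10)
        with pytest.warns(UserWarning, match="unidentifiable"):
            fit = em.fit_random_intercept(y, None, np.arange(10))
        assert fit.sigma2_b == 0.0

    def test_rank_deficient_design_rejected(self, rng):
        x = rng.normal(size=20)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="rank"):
            em.fit_random_intercept(rng.normal(size=20), X,
                                    np.repeat(np.arange(4), 5))


class TestLRT:
    def test_identical_models(self, rng):
        y, X, subj = simulate(6, 6, [1.0, 0.0, 0.0], 0.5, 1.0, rng)
        fit = em.fit_random_intercept(y, X, subj)
        res = em.lrt(fit, fit)
        assert res.chi2 == 0.0 and res.p == 1.0

    def test_chi2_critical_value(self, rng):
        """A likelihood gap of 1.92 gives chi2 = 3.84 and p ~ 0.05 on 1 df."""
        y, X, subj = simulate(6, 6, [1.0, 0.01, 0.0], 0.5, 1.0, rng)
        reduced = em.fit_random_intercept(y, None, subj)
        full = em.fit_random_intercept(y, X[["ita"]], subj)
        # construct the exact gap by overriding the recorded likelihoods
        reduced.loglik, full.loglik = 0.0, 1.9207
        res = em.lrt(reduced, full)
        assert res.chi2 == pytest.approx(3.8414, abs=1e-4)
        assert res.p == pytest.approx(0.05, abs=1e-3)

    def test_nesting_violation_rejected(self, rng):
        y, X, subj = simulate(6, 6, [1.0, 0.0, 0.0], 0.5, 1.0, rng)
        full = em.fit_random_intercept(y, X[["ita"]], subj)
        reduced = em.fit_random_intercept(y, X[["hr"]], subj)
        with pytest.raises(ValueError, match="nested"):
            em.lrt(reduced, full)

    def test_added_predictor_never_lowers_loglik(self, rng):
        for seed in range(5):
            r = np.random.default_rng(100 + seed)
            y, X, subj = simulate(8, 10, [1.0, 0.0, 0.0], 0.5, 1.0, r)
            base = em.fit_random_intercept(y, None, subj)
            fuller = em.fit_random_intercept(y, X, subj)
            assert em.lrt(base, fuller).chi2 >= 0.0


class TestForwardEntry:
    def test_null_data_keeps_intercept_only(self):
        rng = np.random.default_rng(42)
        y, X, subj = simulate(20, 30, [2.0, 0.0, 0.0], 0.3, 1.5, rng)
        fit, trace = em.forward_entry(y, X, subj)
        assert fit.fe_names == [em.INTERCEPT]
        assert list(trace["kept"]) == [False, False]
        assert list(trace["predictor"]) == ["ita", "hr"]

    def test_hr_only_effect_selects_hr(self):
        rng = np.random.default_rng(43)
        y, X, subj = simulate(20, 40, [5.0, 0.0, -0.02], 0.3, 1.0, rng)
        fit, trace = em.forward_entry(y, X, subj)
        assert "hr" in fit.fe_names and "ita" not in fit.fe_names

    def test_both_effects_selected(self):
        rng = np.random.default_rng(44)
        y, X, subj = simulate(28, 60, [5.0, -0.011, -0.022], 0.2, 1.0, rng)
        fit, trace = em.forward_entry(y, X, subj)
        assert {"ita", "hr"} <= set(fit.fe_names)
        assert trace["kept"].all()


class TestDerivedStats:
    def test_icc_equal_components(self):
        rng = np.random.default_rng(5)
        y = np.repeat(rng.normal(0, 1, 200), 10) + rng.normal(0, 1, 2000)
        icc = em.icc_from_null(y, np.repeat(np.arange(200), 10))
        assert icc == pytest.approx(0.5, abs=0.06)

    def test_icc_zero_when_no_grouping(self, rng):
        y = rng.normal(0, 1, 600)
        icc = em.icc_from_null(y, np.repeat(np.arange(30), 20))
        assert icc < 0.03

    def test_icc_location_scale_invariance(self, rng):
        y = np.repeat(rng.normal(0, 1, 30), 8) + rng.normal(0, 3, 240)
        subj = np.repeat(np.arange(30), 8)
        base = em.icc_from_null(y, subj)
        assert em.icc_from_null(5.0 + y, subj) == pytest.approx(base, abs=1e-6)
        assert em.icc_from_null(3.0 * y, subj) == pytest.approx(base, abs=1e-6)

    def test_marginal_r2_limits(self, rng):
        y, X, subj = simulate(10, 10, [1.0, 0.0, 0.0], 0.5, 1.0, rng)
        null = em.fit_random_intercept(y, None, subj)
        assert em.marginal_r2(null) == 0.0
        # noiseless response: fixed effects explain everything
        x = rng.normal(0, 1, 100)
        y2 = 2.0 + 3.0 * x
        fit = em.fit_random_intercept(y2, pd.DataFrame({"x": x}),
                                      np.repeat(np.arange(10), 10))
        assert em.marginal_r2(fit) == pytest.approx(1.0, abs=1e-6)

    def test_marginal_r2_recovers_generating_share(self):
        rng = np.random.default_rng(8)
        n_subj, n_per = 60, 50
        x = rng.normal(0, 1, n_subj * n_per)
        subj = np.repeat(np.arange(n_subj), n_per)
        # variance shares: fixed 6%, random 4%, residual 90%
        y = np.sqrt(0.06) * x + np.repeat(rng.normal(0, np.sqrt(0.04), n_subj),
                                          n_per) \
            + rng.normal(0, np.sqrt(0.90), n_subj * n_per)
        fit = em.fit_random_intercept(y, pd.DataFrame({"x": x}), subj)
        assert em.marginal_r2(fit) == pytest.approx(0.06, abs=0.015)

    def test_sr2_sums_for_orthogonal_predictors(self):
        rng = np.random.default_rng(9)
        n = 1200
        subj = np.repeat(np.arange(40), 30)
        X = pd.DataFrame({"u": rng.normal(0, 1, n), "v": rng.normal(0, 1, n)})
        y = 0.4 * X["u"].to_numpy() + 0.3 * X["v"].to_numpy() \
            + np.repeat(rng.normal(0, 0.4, 40), 30) + rng.normal(0, 1, n)
        sr2 = em.semipartial_sr2(y, X, ["u", "v"], subj)
        full = em.fit_random_intercept(y, X, subj)
        assert sum(sr2.values()) == pytest.approx(em.marginal_r2(full), abs=0.02)

    def test_sr2_zero_effect_predictor(self):
        rng = np.random.default_rng(10)
        n = 900
        subj = np.repeat(np.arange(30), 30)
        X = pd.DataFrame({"u": rng.normal(0, 1, n), "w": rng.normal(0, 1, n)})
        y = 0.5 * X["u"].to_numpy() + rng.normal(0, 1, n)
        sr2 = em.semipartial_sr2(y, X, ["u", "w"], subj)
        assert sr2["w"] < 0.01

    def test_sr2_unknown_predictor_rejected(self, rng):
        X = pd.DataFrame({"u": rng.normal(size=40)})
        with pytest.raises(ValueError):
            em.semipartial_sr2(rng.normal(size=40), X, ["nope"],
                               np.repeat(np.arange(8), 5))


class TestVIF:
    def test_orthogonal_predictors(self):
        X = pd.DataFrame({"a": [1.0, 1, -1, -1], "b": [1.0, -1, 1, -1]})
        assert np.allclose(em.vif(X), 1.0)

    def test_correlated_pair_oracle(self):
        """Correlation 0.8 between two predictors gives VIF 1/(1-0.64)."""
        rng = np.random.default_rng(3)
        z = rng.normal(0, 1, 60_000)
        a = z
        b = 0.8 * z + np.sqrt(1 - 0.64) * rng.normal(0, 1, 60_000)
        out = em.vif(pd.DataFrame({"a": a, "b": b}))
        assert out["a"] == pytest.approx(1 / (1 - 0.64), rel=0.02)

    def test_single_predictor_is_unity(self, rng):
        assert em.vif(pd.DataFrame({"a": rng.normal(size=10)}))["a"] == 1.0

    def test_perfect_collinearity_flagged(self, rng):
        x = rng.normal(size=30)
        with pytest.warns(UserWarning, match="collinearity"):
            out = em.vif(pd.DataFrame({"a": x, "b": 2 * x}))
        assert np.isinf(out["a"]) and np.isinf(out["b"])
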