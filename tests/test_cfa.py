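"""One-factor CFA: FIML estimation, fit indices and factor scores."""

import numpy as np
import pytest
from scipy import optimize

from netcog.cfa import (
    GFactorSpec,
    baseline_loglik,
    em_saturated,
    factor_scores,
    fiml_loglik,
    fit_g_model,
    fit_indices,
    group_patterns,
    score_reliability,
)


def simulate_battery(rng, n, loadings, missing=0.0, residual_pair=None,
                     residual_cov=0.0):
    lam = np.asarray(loadings)
    g = rng.standard_normal(n)
    X = g[:, None] * lam + rng.standard_normal((n, lam.size)) * np.sqrt(1 - lam**2)
    if residual_pair is not None and residual_cov > 0:
        shared = rng.standard_normal(n) * np.sqrt(residual_cov)
        X[:, residual_pair[0]] += shared
        X[:, residual_pair[1]] += shared
    if missing > 0:
        X[rng.random(X.shape) < missing] = np.nan
    return X, g


LOADINGS = (0.7, 0.6, 0.5, 0.4, 0.3)


class TestFitGModel:
    def test_loading_recovery_with_missingness(self):
        rng = np.random.default_rng(101)
        X, _ = simulate_battery(rng, 5000, LOADINGS, missing=0.10)
        fit = fit_g_model(X, GFactorSpec(("a", "b", "c", "d", "e")))
        assert fit.converged
        assert np.all(np.abs(fit.std_loadings - np.array(LOADINGS)) < 0.05)

    def test_fiml_matches_complete_data_ml(self):
        """With no missing data, FIML equals covariance-structure ML.

        The oracle maximizes the Wishart discrepancy ln|Sigma| +
        tr(S Sigma^-1) over the same parameterization, an entirely
        separate objective computed from the sample moments.
        """
        rng = np.random.default_rng(7)
        X, _ = simulate_battery(rng, 1500, LOADINGS)
        p = X.shape[1]
        S = np.cov(X, rowvar=False, bias=True)

        def discrepancy(v):
            lam, td = v[:p], v[p:]
            Sigma = np.outer(lam, lam) + np.diag(td)
            sign, logdet = np.linalg.slogdet(Sigma)
            if sign <= 0:
                return 1e9
            return logdet + np.trace(np.linalg.solve(Sigma, S))

        v0 = np.concatenate([np.sqrt(np.diag(S) * 0.5), np.diag(S) * 0.5])
        res = optimize.minimize(discrepancy, v0, method="Nelder-Mead",
                                options={"maxiter": 20000, "xatol": 1e-10,
                                         "fatol": 1e-12})
        oracle_lam = np.abs(res.x[:p])
        fit = fit_g_model(X, GFactorSpec(tuple("abcde")))
        assert np.all(np.abs(fit.loadings - oracle_lam) < 1e-4)

    def test_true_model_limit_fits_perfectly(self):
        rng = np.random.default_rng(8)
        X, _ = simulate_battery(rng, 20000, LOADINGS)
        fit = fit_g_model(X, GFactorSpec(tuple("abcde")))
        assert fit.cfi > 0.999
        assert fit.rmsea < 0.01
        assert fit.srmr < 0.01

    def test_loglik_monotone_over_iterations(self):
        rng = np.random.default_rng(9)
        X, _ = simulate_battery(rng, 800, LOADINGS, missing=0.1)
        fit = fit_g_model(X, GFactorSpec(tuple("abcde")))
        path = np.array(fit.loglik_path)
        assert np.all(np.diff(path) > -1e-6 * np.abs(path[:-1]))

    def test_true_residual_covariance_never_decreases_loglik(self):
        rng = np.random.default_rng(10)
        X, _ = simulate_battery(rng, 2000, LOADINGS, residual_pair=(0, 1),
                                residual_cov=0.15)
        plain = fit_g_model(X, GFactorSpec(tuple("abcde")))
        rich = fit_g_model(X, GFactorSpec(tuple("abcde"), ((0, 1),)))
        assert rich.loglik >= plain.loglik - 1e-6
        assert rich.theta[0, 1] == pytest.approx(0.15, abs=0.05)

    def test_identification_requires_three_tests(self):
        with pytest.raises(ValueError):
            GFactorSpec(("a", "b"))


class TestFitIndices:
    def test_perfect_fit(self):
        fi = fit_indices(-100.0, -100.0 + 2.5, -200.0, df_model=5,
                         df_baseline=10, n=100)
        # T_m = 5 = df_m -> RMSEA 0, CFI 1
        assert fi["RMSEA"] == 0.0
        assert fi["CFI"] == 1.0

    def test_no_improvement_over_baseline(self):
        # T_m = T_b = 50 with df_m = df_b = 10 -> CFI = 0
        fi = fit_indices(-125.0, -100.0, -125.0, 10, 10, 50)
        assert fi["CFI"] == 0.0

    def test_hand_computed_example(self):
        # T_m=10, df_m=5, T_b=105, df_b=10, n=100
        fi = fit_indices(-105.0, -100.0, -152.5, 5, 10, 100)
        assert fi["RMSEA"] == pytest.approx(np.sqrt(5 / 500))
        assert fi["CFI"] == pytest.approx(1 - 5 / 95)

    def test_baseline_df_error(self):
        with pytest.raises(ValueError):
            fit_indices(0, 0, 0, 1, 0, 10)


class TestSaturatedAndBaseline:
    def test_em_matches_moments_when_complete(self):
        rng = np.random.default_rng(11)
        X, _ = simulate_battery(rng, 500, LOADINGS)
        mu, Sigma, ll = em_saturated(X)
        assert np.allclose(mu, X.mean(0), atol=1e-8)
        assert np.allclose(Sigma, np.cov(X, rowvar=False, bias=True), atol=1e-8)
        patterns = group_patterns(X)
        assert ll == pytest.approx(fiml_loglik(mu, Sigma, patterns))

    def test_saturated_dominates_structured_model(self):
        rng = np.random.default_rng(12)
        X, _ = simulate_battery(rng, 600, LOADINGS, missing=0.15)
        fit = fit_g_model(X, GFactorSpec(tuple("abcde")))
        assert fit.loglik_saturated >= fit.loglik - 1e-6
        assert fit.loglik >= fit.loglik_baseline - 1e-6

    def test_baseline_closed_form(self):
        rng = np.random.default_rng(13)
        X, _ = simulate_battery(rng, 300, LOADINGS, missing=0.2)
        ll = baseline_loglik(X)
        # equals FIML loglik at the per-variable ML moments
        mu = np.nanmean(X, axis=0)
        var = np.nanmean((X - mu) ** 2, axis=0)
        assert ll == pytest.approx(
            fiml_loglik(mu, np.diag(var), group_patterns(X)), rel=1e-10)


class TestFactorScores:
    def test_recovery_correlation(self):
        rng = np.random.default_rng(14)
        X, g = simulate_battery(rng, 5000, LOADINGS, missing=0.10)
        fit = fit_g_model(X, GFactorSpec(tuple("abcde")))
        s = factor_scores(fit, X)
        ok = ~np.isnan(s)
        r = np.corrcoef(s[ok], g[ok])[0, 1]
        # theoretical ceiling sqrt(lam' Sigma^-1 lam) = 0.826 for this battery
        assert r > 0.78
        assert abs(s[ok].mean()) < 1e-8
        assert s[ok].std(ddof=0) == pytest.approx(1.0)

    def test_all_missing_participant_gets_nan(self):
        rng = np.random.default_rng(15)
        X, _ = simulate_battery(rng, 400, LOADINGS)
        X[0, :] = np.nan
        fit = fit_g_model(X, GFactorSpec(tuple("abcde")))
        s = factor_scores(fit, np.vstack([X[:1], X[1:]]))
        assert np.isnan(s.iloc[0])
        assert (~np.isnan(s.iloc[1:])).all()

    def test_reliability_between_zero_and_one(self):
        rng = np.random.default_rng(16)
        X, _ = simulate_battery(rng, 500, LOADINGS, missing=0.1)
        fit = fit_g_model(X, GFactorSpec(tuple("abcde")))
        rel = score_reliability(fit, X)
        assert 0.3 < rel < 1.0
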