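"""Structural-regression associations: recovery, calibration, invariances."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from netcog.association import (
    associate,
    associate_age_moderation,
    batch_associate,
)
from netcog.cfa import GFactorSpec
from netcog.simulate import default_config, generate_cohort

SPEC5 = GFactorSpec(("test_0", "test_1", "test_2", "test_3", "test_4"), ((0, 1),))


def _covars(rng, n, sites=2, age_range=(45, 80)):
    return pd.DataFrame({
        "age": rng.uniform(*age_range, n),
        "sex": rng.choice(["F", "M"], n),
        "site": rng.choice([f"s{k}" for k in range(sites)], n),
    })


def _tests_from_g(rng, g, loadings=(0.28, 0.45, 0.55, 0.65, 0.73),
                  missing=0.1):
    lam = np.asarray(loadings)
    X = g[:, None] * lam + rng.standard_normal((g.size, 5)) * np.sqrt(1 - lam**2)
    if missing:
        X[rng.random(X.shape) < missing] = np.nan
    return pd.DataFrame(X, columns=SPEC5.test_names)


class TestAssociate:
    def test_recovers_injected_global_effect(self, clean_recovery_cohort):
        c = clean_recovery_cohort
        metric = c.edge_weights["SC"].mean(axis=1)
        r = associate(metric, c.tests, SPEC5, c.covariates,
                      "cohortA", "mean_edge_weight", estimator="sem")
        assert not r.flag
        assert 0.15 <= r.beta <= 0.25

    def test_sem_and_two_stage_agree(self, clean_recovery_cohort):
        c = clean_recovery_cohort
        metric = c.edge_weights["SC"].mean(axis=1)
        r1 = associate(metric, c.tests, SPEC5, c.covariates, estimator="sem")
        r2 = associate(metric, c.tests, SPEC5, c.covariates,
                       estimator="two_stage")
        assert abs(r1.beta - r2.beta) < 0.02

    def test_identity_limit(self):
        """A metric equal to noiseless g approaches beta = 1."""
        rng = np.random.default_rng(30)
        n = 2000
        g = rng.standard_normal(n)
        tests = _tests_from_g(rng, g, loadings=(0.9, 0.9, 0.9, 0.88, 0.92),
                              missing=0.0)
        r = associate(g, tests, SPEC5, _covars(rng, n), estimator="sem")
        assert r.beta > 0.93

    def test_beta_invariant_to_affine_metric_rescaling(self):
        rng = np.random.default_rng(31)
        n = 600
        g = rng.standard_normal(n)
        metric = 0.3 * g + rng.standard_normal(n)
        tests = _tests_from_g(rng, g)
        cov = _covars(rng, n)
        r1 = associate(metric, tests, SPEC5, cov, estimator="two_stage")
        r2 = associate(17.0 * metric - 3.0, tests, SPEC5, cov,
                       estimator="two_stage")
        assert r1.beta == pytest.approx(r2.beta, abs=1e-10)

    def test_type_one_error_calibrated(self):
        """Null metric: rejection rate at alpha=0.05 stays nominal."""
        rng = np.random.default_rng(32)
        n, reps = 300, 200
        rejections = 0
        for _ in range(reps):
            g = rng.standard_normal(n)
            metric = rng.standard_normal(n)  # independent of g
            tests = _tests_from_g(rng, g)
            r = associate(metric, tests, SPEC5, _covars(rng, n),
                          estimator="two_stage")
            rejections += r.p < 0.05
        mc_err = np.sqrt(0.05 * 0.95 / reps)
        assert rejections / reps <= 0.05 + 3 * mc_err

    def test_se_shrinks_like_sqrt_n(self):
        rng = np.random.default_rng(33)
        n_full = 6400
        g = rng.standard_normal(n_full)
        metric = 0.2 * g + rng.standard_normal(n_full)
        tests = _tests_from_g(rng, g)
        cov = _covars(rng, n_full)
        ses, ns = [], [400, 1600, 6400]
        for n in ns:
            r = associate(metric[:n], tests.iloc[:n], SPEC5, cov.iloc[:n],
                          estimator="two_stage")
            ses.append(r.se)
        slope = np.polyfit(np.log(ns), np.log(ses), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.1)

    def test_minimum_sample_size(self):
        rng = np.random.default_rng(34)
        with pytest.raises(ValueError, match="50"):
            associate(np.ones(10), _tests_from_g(rng, rng.standard_normal(10)),
                      SPEC5, _covars(rng, 10))


class TestModeration:
    def test_recovers_injected_interaction(self):
        cfg = dataclasses.replace(
            default_config(seed=41, scale=2.5), beta_edge_map=(),
            beta_age_moderation=0.05)
        c = generate_cohort(cfg, "cohortA", weightings=("SC",))  # n = 5000
        metric = c.edge_weights["SC"].mean(axis=1)
        r = associate_age_moderation(metric, c.tests, SPEC5, c.covariates,
                                     estimator="two_stage")
        assert r.flag == ""
        assert r.beta == pytest.approx(0.05, abs=0.02)

    def test_null_interaction_centered_on_zero(self):
        rng = np.random.default_rng(42)
        betas = []
        for _ in range(30):
            n = 400
            g = rng.standard_normal(n)
            metric = 0.2 * g + rng.standard_normal(n)
            tests = _tests_from_g(rng, g)
            r = associate_age_moderation(metric, tests, SPEC5,
                                         _covars(rng, n),
                                         estimator="two_stage")
            betas.append(r.beta)
        assert abs(np.mean(betas)) < 3 * np.std(betas) / np.sqrt(len(betas)) + 0.01

    def test_narrow_age_cohort_skipped(self):
        rng = np.random.default_rng(43)
        n = 200
        g = rng.standard_normal(n)
        cov = _covars(rng, n, age_range=(71.0, 74.0))
        r = associate_age_moderation(rng.standard_normal(n),
                                     _tests_from_g(rng, g), SPEC5, cov)
        assert r.flag == "skipped"
        assert np.isnan(r.beta)


class TestBatch:
    def test_atlas_ordered_rows_and_flagged_degenerates(self):
        rng = np.random.default_rng(44)
        n = 300
        g = rng.standard_normal(n)
        tests = _tests_from_g(rng, g)
        cov = _covars(rng, n)
        metrics = pd.DataFrame(rng.standard_normal((n, 10)),
                               columns=[f"m{k}" for k in range(10)])
        metrics["m4"] = 1.0  # zero variance
        out = batch_associate(metrics, tests, SPEC5, cov, "c")
        assert list(out["metric_id"]) == [f"m{k}" for k in range(10)]
        assert out.loc[4, "flag"] == "zero_variance"
        assert (out.drop(index=4)["flag"] == "").all()

    def test_single_site_dropped_without_error(self):
        rng = np.random.default_rng(45)
        n = 300
        g = rng.standard_normal(n)
        cov = _covars(rng, n, sites=1)
        out = batch_associate(pd.DataFrame({"m": 0.3 * g + rng.standard_normal(n)}),
                              _tests_from_g(rng, g), SPEC5, cov, "c")
        assert out.loc[0, "flag"] == ""
        assert out.loc[0, "beta"] > 0.1
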