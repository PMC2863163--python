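"""Risk-set decomposition, Breslow partial likelihood/score, Cox fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from sepindex import (
    SurvivalDataset,
    breslow_log_partial_likelihood,
    breslow_score,
    decompose_risk_sets,
    fit_cox,
    fit_cox_many,
)


def brute_loglik(time, event, z, beta):
    """Independent Breslow partial log-likelihood from explicit sets."""
    time, event, z = map(np.asarray, (time, event, z))
    ll = 0.0
    for t in np.unique(time):
        D = np.flatnonzero((time == t) & (event == 1))
        if D.size == 0:
            continue
        R = np.flatnonzero(time >= t)
        ll += beta * z[D].sum() - D.size * np.log(np.sum(np.exp(beta * z[R])))
    return ll


class TestDecomposition:
    def test_toy_sets_and_counts(self, toy):
        _, _, d = toy
        assert d.n_distinct == 3 and d.k_failure_times == 2
        np.testing.assert_array_equal(d.distinct_times, [1.0, 2.0, 3.0])
        # t=1: risk set everyone, subject 1 fails, subject 2 censored
        np.testing.assert_array_equal(d.R(0), [0, 1, 2, 3])
        np.testing.assert_array_equal(d.D(0), [1])
        np.testing.assert_array_equal(d.E(0), [1, 2])
        np.testing.assert_array_equal(d.Rstar(0), [0, 2, 3])
        assert (d.d[0], d.n_at_risk[0], d.e[0]) == (1, 4, 2)
        np.testing.assert_array_equal(d.R(1), [0, 3])
        np.testing.assert_array_equal(d.D(1), [0])
        np.testing.assert_array_equal(d.R(2), [3])
        np.testing.assert_array_equal(d.D(2), [])
        # R*(t_1(-2)): risk set at t=1 without subjects leaving at t=2
        np.testing.assert_array_equal(d.rstar_pair(0, 1), [1, 2, 3])

    def test_counts_partition_subjects(self, random_datasets):
        for x, e, _ in random_datasets:
            d = decompose_risk_sets(x, e)
            assert d.e.sum() == len(x)
            assert np.all(np.diff(d.n_at_risk) <= 0)
            assert np.all(d.d <= d.e)
            assert d.k_failure_times <= d.n_distinct <= len(x)

    def test_no_censoring_no_ties_identity(self):
        n = 12
        d = decompose_risk_sets(np.arange(1.0, n + 1), np.ones(n))
        assert d.n_distinct == d.k_failure_times == n
        np.testing.assert_array_equal(d.n_at_risk, np.arange(n, 0, -1))
        np.testing.assert_array_equal(d.d, np.ones(n))
        np.testing.assert_array_equal(d.e, np.ones(n))

    def test_all_censored_rejected(self):
        with pytest.raises(ValueError, match="no failures"):
            decompose_risk_sets([1.0, 2.0], [0, 0])

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            decompose_risk_sets([-1.0, 2.0], [1, 1])


class TestBreslowLikelihood:
    def test_null_closed_form(self, toy):
        _, _, d = toy
        ll0 = breslow_log_partial_likelihood(d, np.array([0.0, 1.0, 0.0, 1.0]), 0.0)
        assert ll0 == pytest.approx(-(np.log(4) + np.log(2)), abs=1e-12)
        # closed form -sum d_j log n_j at beta = 0
        assert ll0 == pytest.approx(-(d.d * np.log(d.n_at_risk)).sum())

    def test_matches_brute_force(self, random_datasets):
        for x, e, z in random_datasets[:10]:
            d = decompose_risk_sets(x, e)
            for beta in (-1.2, 0.0, 0.7):
                assert breslow_log_partial_likelihood(d, z, beta) == pytest.approx(
                    brute_loglik(x, e, z, beta), rel=1e-10
                )

    def test_constant_covariate_flat_after_offset(self, toy):
        _, _, d = toy
        z = np.full(4, 3.0)
        ll0 = breslow_log_partial_likelihood(d, z, 0.0)
        for beta in (-2.0, 1.0, 4.0):
            expected = ll0 + beta * 3.0 * d.d.sum() - (d.d * beta * 3.0).sum()
            assert breslow_log_partial_likelihood(d, z, beta) == pytest.approx(expected)
            assert breslow_score(d, z, beta) == pytest.approx(0.0, abs=1e-10)

    def test_concavity_on_grid(self, random_datasets):
        grid = np.linspace(-2, 2, 21)
        for x, e, z in random_datasets[:6]:
            d = decompose_risk_sets(x, e)
            ll = np.array([breslow_log_partial_likelihood(d, z, b) for b in grid])
            assert np.all(np.diff(ll, 2) <= 1e-8)


class TestBreslowScore:
    def test_toy_hand_value(self, toy):
        _, _, d = toy
        z = np.array([0.0, 1.0, 0.0, 1.0])
        # U_1 = 1 - 1*(2/4) = 0.5 ; U_2 = 0 - 1*(1/2) = -0.5 ; total 0
        assert breslow_score(d, z, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_finite_difference(self, random_datasets):
        h = 1e-6
        for x, e, z in random_datasets:
            d = decompose_risk_sets(x, e)
            for beta in (-0.8, 0.0, 0.5):
                num = (
                    breslow_log_partial_likelihood(d, z, beta + h)
                    - breslow_log_partial_likelihood(d, z, beta - h)
                ) / (2 * h)
                assert breslow_score(d, z, beta) == pytest.approx(num, abs=1e-5)


class TestCoxFit:
    def test_symmetric_groups_give_null_fit(self):
        # two balanced groups with identical failure patterns
        time = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        event = np.ones(6)
        z = np.array([0, 0, 0, 1, 1, 1.0])
        d = decompose_risk_sets(time, event)
        fit = fit_cox(d, z)
        assert fit.beta_hat == pytest.approx(0.0, abs=1e-8)
        assert fit.lr_statistic == pytest.approx(0.0, abs=1e-10)

    def test_matches_bounded_optimizer(self, random_datasets):
        for x, e, z in random_datasets[:8]:
            d = decompose_risk_sets(x, e)
            fit = fit_cox(d, z)
            if not fit.converged:
                continue
            res = optimize.minimize_scalar(
                lambda b: -breslow_log_partial_likelihood(d, z, b),
                bounds=(-10, 10), method="bounded",
                options={"xatol": 1e-10},
            )
            assert fit.beta_hat == pytest.approx(res.x, abs=1e-5)
            assert fit.loglik_hat >= fit.loglik_null - 1e-12
            assert fit.lr_statistic >= -1e-10

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        n = 150
        z = rng.normal(0, 1, n)
        t = rng.exponential(np.exp(-0.5 * z))
        c = rng.exponential(2.0, n)
        x, e = np.minimum(t, c), (t <= c).astype(int)
        d = decompose_risk_sets(x, e)
        fit = fit_cox(d, z)
        cph = lifelines.CoxPHFitter().fit(
            pd.DataFrame({"T": x, "E": e, "z": z}), "T", "E"
        )
        assert fit.beta_hat == pytest.approx(float(cph.params_.iloc[0]), abs=1e-5)
        assert fit.lr_statistic == pytest.approx(
            float(cph.log_likelihood_ratio_test().test_statistic), rel=1e-6
        )

    def test_recovers_beta_on_simulated_data(self, rng):
        betas = []
        for _ in range(20):
            z = (rng.random(1000) < 0.5).astype(float)
            t = rng.exponential(np.exp(-np.log(2) * z))
            d = decompose_risk_sets(t, np.ones(1000))
            betas.append(fit_cox(d, z).beta_hat)
        assert np.mean(betas) == pytest.approx(np.log(2), abs=0.03)

    def test_constant_covariate_rejected(self, toy):
        _, _, d = toy
        with pytest.raises(ValueError, match="constant"):
            fit_cox(d, np.ones(4))

    def test_monotone_likelihood_capped_and_flagged(self):
        # covariate perfectly orders the failures: likelihood is monotone
        time = np.arange(1.0, 9.0)
        event = np.ones(8)
        z = np.arange(8.0, 0.0, -1.0)
        d = decompose_risk_sets(time, event)
        fit = fit_cox(d, z)
        assert not fit.converged
        assert abs(fit.beta_hat) > 1.0

    def test_vectorized_fit_matches_scalar(self, rng):
        n = 80
        x = rng.exponential(1, n)
        e = (rng.random(n) < 0.7).astype(int)
        e[np.argmin(x)] = 1
        Z = rng.normal(0, 1, (5, n))
        d = decompose_risk_sets(x, e)
        fits = fit_cox_many(d, Z)
        for g in range(5):
            single = fit_cox(d, Z[g])
            assert fits[g].beta_hat == pytest.approx(single.beta_hat, abs=1e-8)
            assert fits[g].lr_statistic == pytest.approx(single.lr_statistic, abs=1e-8)


class TestSurvivalDataset:
    def test_validation(self):
        with pytest.raises(ValueError, match="event"):
            SurvivalDataset(time=[1.0, 2.0], event=[0, 2], covariates=[[1.0, 2.0]])
        with pytest.raises(ValueError, match="column"):
            SurvivalDataset(time=[1.0, 2.0], event=[0, 1],
                            covariates=np.ones((1, 3)))
        with pytest.raises(ValueError, match="negative"):
            SurvivalDataset(time=[-1.0, 2.0], event=[1, 1], covariates=[[1.0, 2.0]])

    def test_gene_lookup(self):
        ds = SurvivalDataset(time=[1.0, 2.0], event=[1, 1],
                             covariates=[[1.0, 2.0], [3.0, 4.0]],
                             gene_ids=["a", "b"])
        np.testing.assert_array_equal(ds.gene("b"), [3.0, 4.0])
        with pytest.raises(KeyError):
            ds.gene("zz")
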