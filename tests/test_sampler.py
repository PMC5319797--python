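"""Metropolis-Hastings sampler and single-chain convergence diagnostics."""

import numpy as np
import pytest
from scipy import stats

from pwsasa.sampler import (convergence_report, geweke_z,
                            lag1_autocorrelation, metropolis, run_mcmc)


def gaussian_logpdf(mu, sigma):
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)

    def f(x):
        return float(-0.5 * np.sum(((x - mu) / sigma) ** 2))
    return f


class TestMetropolis:
    def test_gaussian_stub_moments(self):
        """Sample means of an independent 2-D Gaussian land within 3 Monte
        Carlo standard errors of the target means."""
        mu = np.array([1.5, -2.0])
        sigma = np.array([1.0, 2.0])
        draws, acc = metropolis(gaussian_logpdf(mu, sigma), np.zeros(2),
                                60_000, seed=42, burn_frac=0.25, thin=5)
        assert 0.1 < acc < 0.7
        for j in range(2):
            ess = len(draws) / (1 + 2 * max(lag1_autocorrelation(draws[:, j]), 0)
                                / max(1 - lag1_autocorrelation(draws[:, j]), 1e-3))
            se = sigma[j] / np.sqrt(ess)
            assert abs(draws[:, j].mean() - mu[j]) < 3 * se

    def test_retention_arithmetic(self):
        draws, _ = metropolis(gaussian_logpdf(0.0, 1.0), np.zeros(1),
                              10_000, seed=0, burn_frac=0.10, thin=10)
        assert draws.shape == (900, 1)

    def test_seeded_reproducibility_is_bitwise(self):
        a, acc_a = metropolis(gaussian_logpdf(0.0, 1.0), np.zeros(3),
                              20_000, seed=7, burn_frac=0.2, thin=4)
        b, acc_b = metropolis(gaussian_logpdf(0.0, 1.0), np.zeros(3),
                              20_000, seed=7, burn_frac=0.2, thin=4)
        assert acc_a == acc_b
        np.testing.assert_array_equal(a, b)

    def test_infeasible_start_rejected(self):
        def f(x):
            return -np.inf
        with pytest.raises(ValueError, match="mode"):
            metropolis(f, np.zeros(2), 1000, seed=0)

    def test_stationary_distribution_gamma_target(self):
        """Discretised 1-D check of detailed balance: decile occupancy of a
        Gamma(3) target matches the exact CDF."""
        def logpdf(x):
            v = x[0]
            return float(2.0 * np.log(v) - v) if v > 0 else -np.inf
        draws, _ = metropolis(logpdf, np.array([3.0]), 100_000, seed=3,
                              burn_frac=0.2, thin=4)
        edges = stats.gamma.ppf(np.linspace(0, 1, 11), a=3)
        freq, _ = np.histogram(draws[:, 0], bins=edges)
        freq = freq / freq.sum()
        assert np.max(np.abs(freq - 0.1)) < 0.02

    def test_run_mcmc_wraps_metadata(self):
        chain = run_mcmc(gaussian_logpdf(0.0, 1.0), np.zeros(2), 5000,
                         burn_frac=0.2, thin=4, seed=1)
        assert chain.n_draws == 1000
        assert chain.meta["seed"] == 1
        assert 0 < chain.meta["acceptance"] <= 1


class TestGeweke:
    def test_null_calibration(self):
        """For iid normal series the statistic is ~N(0,1): |z| < 1.96 in at
        least 94% of seeded replicates."""
        rng = np.random.default_rng(2024)
        hits = sum(abs(geweke_z(rng.standard_normal(10_000))) < 1.96
                   for _ in range(100))
        assert hits >= 94

    def test_mean_step_change_detected(self):
        x = np.concatenate([np.zeros(5000), np.full(5000, 5.0)])
        x += np.random.default_rng(0).standard_normal(10_000)
        assert abs(geweke_z(x)) > 10

    def test_constant_series_is_degenerate(self):
        assert np.isnan(geweke_z(np.ones(1000)))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            geweke_z(np.ones(10))


class TestConvergenceReport:
    def test_iid_chain_passes(self):
        rng = np.random.default_rng(5)
        draws = rng.standard_normal((2000, 3))
        rep = convergence_report(draws)
        assert rep.passed
        assert np.all(np.abs(rep.lag1) < 0.10)

    def test_sticky_ar1_fails_autocorrelation_gate(self):
        """An unthinned AR(1) with rho = 0.99 has lag-1 autocorrelation far
        above the 0.10 gate."""
        rng = np.random.default_rng(6)
        n = 5000
        x = np.zeros(n)
        for t in range(1, n):
            x[t] = 0.99 * x[t - 1] + rng.standard_normal()
        draws = np.column_stack([x, rng.standard_normal(n)])
        rep = convergence_report(draws)
        assert not rep.passed
        assert rep.lag1[0] > 0.9

    def test_single_bad_parameter_fails_overall(self):
        rng = np.random.default_rng(7)
        good = rng.standard_normal((2000, 2))
        bad = np.concatenate([np.zeros(1000), np.full(1000, 4.0)])
        bad += 0.1 * rng.standard_normal(2000)
        rep = convergence_report(np.column_stack([good, bad]))
        assert not rep.passed

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            convergence_report(np.zeros((50, 2)))


class TestAssessmentFit:
    def test_chain_reproducibility(self, obs_data, scenario, flat_ess):
        from pwsasa.sampler import fit_assessment
        a = fit_assessment(obs_data, scenario.constants, flat_ess,
                           n_iter=4000, burn_frac=0.5, thin=20, seed=9)
        b = fit_assessment(obs_data, scenario.constants, flat_ess,
                           n_iter=4000, burn_frac=0.5, thin=20, seed=9)
        np.testing.assert_array_equal(a.draws, b.draws)
        np.testing.assert_array_equal(a.derived["forecast_biomass"],
                                      b.derived["forecast_biomass"])

    def test_draws_respect_prior_bounds(self, small_chain, scenario):
        layout = scenario.params.layout()
        assert np.all(small_chain.draws > layout.lower)
        assert np.all(small_chain.draws < layout.upper)
        assert small_chain.derived["run_biomass"].shape == \
            (small_chain.n_draws, 33)
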