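"""OLS and Bayesian fitting: hand-checked densities, recovery, diagnostics."""

import math

import numpy as np
import pytest
from scipy import stats

from densvar import (
    GompertzParams,
    MCMCSettings,
    RickerParams,
    fit_gompertz_bayes,
    fit_gompertz_ols,
    fit_ricker_bayes,
    gelman_rubin,
    log_posterior_gompertz,
    log_posterior_ricker,
    simulate_gompertz,
    simulate_ricker,
)


class TestOLS:
    def test_perfect_linear_trend_gives_slope_one(self):
        fit = fit_gompertz_ols([1.0, 2.0, 3.0, 4.0, 5.0])
        assert fit.beta == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_four_point_hand_least_squares(self):
        # pairs {(0,1),(1,0),(0,1)}: xbar=1/3, ybar=2/3
        # slope = sum((x-xbar)(y-ybar)) / sum((x-xbar)^2) = (-2/3)/(2/3) = -1
        fit = fit_gompertz_ols([0.0, 1.0, 0.0, 1.0])
        assert fit.beta == pytest.approx(-1.0)
        assert fit.intercept == pytest.approx(1.0)
        # residuals are all zero; dof = 4 - 1 - 2 = 1
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-20)

    def test_parameter_recovery_large_n(self):
        p = GompertzParams(r=0.4, k=1.0, sigma2=0.10)
        y = simulate_gompertz(p, 1.0, 10_000, seed=21).values
        fit = fit_gompertz_ols(y)
        assert abs(fit.intercept - 0.4) < 3 * fit.se_intercept
        assert abs(fit.beta - 0.6) < 3 * fit.se_beta
        assert fit.sigma2 == pytest.approx(0.10, rel=0.05)

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_gompertz_ols([2.0, 2.0, 2.0, 2.0])
        with pytest.raises(ValueError):
            fit_gompertz_ols([1.0, 2.0])  # too short


class TestLogPosteriorGompertz:
    def test_outside_prior_support_is_minus_inf(self):
        y = [1.0, 1.2, 0.9]
        assert log_posterior_gompertz(y, -0.1, 0.5, 0.1) == -math.inf
        assert log_posterior_gompertz(y, 0.0, 0.5, 0.1) == -math.inf
        assert log_posterior_gompertz(y, 0.4, 0.5, -0.1) == -math.inf

    def test_two_point_hand_evaluation(self):
        y0, y1 = 1.0, 1.3
        r, beta, s2 = 0.4, 0.6, 0.1
        expected = (
            stats.gamma.logpdf(r, 1.0, scale=1.0)
            + stats.norm.logpdf(beta)
            + stats.invgamma.logpdf(s2, 0.1, scale=0.1)
            + stats.norm.logpdf(y1, loc=r + beta * y0, scale=math.sqrt(s2))
        )
        assert log_posterior_gompertz([y0, y1], r, beta, s2) == pytest.approx(expected)

    def test_doubling_sigma2_at_zero_residuals(self):
        # residuals identically zero: likelihood term is -(n/2) log(2 pi s2),
        # so doubling s2 lowers it by (n/2) log 2 (priors change too; compare
        # likelihood-only difference by subtracting the prior difference)
        y = [1.0, 1.0, 1.0, 1.0, 1.0]
        r, beta = 0.5, 0.5  # r + beta*1 = 1: perfect fit
        n = len(y) - 1
        s2 = 0.2
        prior = lambda s: stats.invgamma.logpdf(s, 0.1, scale=0.1)
        diff = log_posterior_gompertz(y, r, beta, s2) - log_posterior_gompertz(
            y, r, beta, 2 * s2
        )
        assert diff - (prior(s2) - prior(2 * s2)) == pytest.approx(
            (n / 2) * math.log(2)
        )


class TestGelmanRubin:
    def test_identical_chains(self):
        chain = np.sin(np.arange(200.0))
        assert gelman_rubin([chain, chain.copy()]) <= 1.0 + 1e-9

    def test_well_mixed_independent_chains(self):
        rng = np.random.default_rng(0)
        chains = rng.standard_normal((2, 10_000))
        assert gelman_rubin(chains) < 1.01

    def test_offset_chains_flagged(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(1_000)
        b = rng.standard_normal(1_000) + 10.0
        assert gelman_rubin([a, b]) > 1.5

    def test_agrees_with_arviz_for_mixed_chains(self):
        import arviz as az

        rng = np.random.default_rng(2)
        chains = rng.standard_normal((4, 2_000))
        mine = gelman_rubin(chains)
        theirs = float(az.rhat(chains))
        assert abs(mine - theirs) < 0.01

    def test_validation(self):
        with pytest.raises(ValueError):
            gelman_rubin([np.ones(50)])
        with pytest.raises(ValueError):
            gelman_rubin([np.ones(50), np.ones(40)])
        with pytest.raises(ValueError):
            gelman_rubin([np.ones(5), np.ones(5)])


class TestMCMCSettings:
    def test_validation(self):
        with pytest.raises(ValueError):
            MCMCSettings(n_chains=1)
        with pytest.raises(ValueError):
            MCMCSettings(n_iter=1000, n_burn=1000)
        with pytest.raises(ValueError):
            MCMCSettings(n_iter=1050, n_burn=1000)  # < 100 retained
        s = MCMCSettings(n_iter=2000, n_burn=1000, thin=5)
        assert s.n_retained == 200


class TestGompertzBayes:
    def test_determinism(self, stationary_series, fast_mcmc):
        a = fit_gompertz_bayes(stationary_series, fast_mcmc)
        b = fit_gompertz_bayes(stationary_series, fast_mcmc)
        assert a.to_dict() == b.to_dict()

    def test_recovery_and_ols_agreement_large_n(self):
        p = GompertzParams(r=0.4, k=1.0, sigma2=0.10)
        y = simulate_gompertz(p, 1.0, 10_000, seed=33).values
        post = fit_gompertz_bayes(y, MCMCSettings(seed=1))
        ols = fit_gompertz_ols(y)
        assert post.converged
        truths = {"r": 0.4, "beta": 0.6, "sigma2": 0.10, "k": 1.0}
        for name, truth in truths.items():
            ps = post.parameters[name]
            assert abs(ps.mean - truth) < 3 * ps.sd, name
        # with n = 1e4 the weak priors wash out: Bayes ~ OLS
        for name, ols_val in (
            ("r", ols.intercept),
            ("beta", ols.beta),
            ("sigma2", ols.sigma2),
        ):
            ps = post.parameters[name]
            assert abs(ps.mean - ols_val) < 0.5 * ps.sd, name

    def test_summary_shape_and_quantile_ordering(self, stationary_series, fast_mcmc):
        post = fit_gompertz_bayes(stationary_series, fast_mcmc)
        assert set(post.parameters) == {"r", "beta", "sigma2", "k"}
        for name, ps in post.parameters.items():
            assert ps.q2_5 <= ps.median <= ps.q97_5, name
            assert ps.sd >= 0
            # PSRF can undershoot 1 by at most the (n-1)/n finite-sample factor
            assert ps.rhat >= 1.0 - 1.0 / fast_mcmc.n_retained
        assert post.draws["beta"].shape == (
            fast_mcmc.n_chains,
            fast_mcmc.n_retained,
        )

    def test_short_series_rejected(self, fast_mcmc):
        with pytest.raises(ValueError):
            fit_gompertz_bayes(np.ones(5), fast_mcmc)

    def test_retained_draws_follow_log_posterior(self, stationary_series, fast_mcmc):
        """The sampler's stationary draws should score near the mode of the
        reference log posterior, and moving far from the posterior mean
        should lower the reference density."""
        post = fit_gompertz_bayes(stationary_series, fast_mcmc)
        pm = post.point_estimates()
        lp_mode = log_posterior_gompertz(
            stationary_series, pm["r"], pm["beta"], pm["sigma2"]
        )
        lp_far = log_posterior_gompertz(
            stationary_series, pm["r"] + 1.0, pm["beta"] - 0.5, pm["sigma2"] * 4
        )
        assert lp_mode > lp_far


class TestRickerBayes:
    def test_recovery_from_ricker_data(self):
        p = RickerParams(r=0.4, K=math.e, sigma2=0.10)
        Y = simulate_ricker(p, math.e, 500, seed=8).values
        post = fit_ricker_bayes(Y, MCMCSettings(seed=2))
        assert post.converged
        for name, truth in (("r", 0.4), ("K", math.e), ("sigma2", 0.10)):
            ps = post.parameters[name]
            assert abs(ps.mean - truth) < 3 * ps.sd, name

    def test_determinism(self, stationary_series, fast_mcmc):
        Y = np.exp(stationary_series)
        a = fit_ricker_bayes(Y, fast_mcmc)
        b = fit_ricker_bayes(Y, fast_mcmc)
        assert a.to_dict() == b.to_dict()

    def test_nonpositive_series_rejected(self, fast_mcmc):
        with pytest.raises(ValueError):
            fit_ricker_bayes(np.linspace(-1, 1, 50), fast_mcmc)

    def test_log_posterior_hand_evaluation(self):
        Y = [1.0, 1.5, 1.2]
        r, K, s2 = 0.4, 1.3, 0.1
        w = np.diff(np.log(Y))
        expected = (
            stats.gamma.logpdf(r, 1.0, scale=1.0)
            + stats.gamma.logpdf(K, 0.1, scale=10.0)
            + stats.gamma.logpdf(s2, 0.1, scale=10.0)
            + np.sum(
                stats.norm.logpdf(
                    w, loc=r * (1 - np.array(Y[:-1]) / K), scale=math.sqrt(s2)
                )
            )
        )
        assert log_posterior_ricker(Y, r, K, s2) == pytest.approx(float(expected))
        assert log_posterior_ricker(Y, -0.1, K, s2) == -math.inf


def test_ols_and_bayes_bias_decrease_with_n():
    """Absolute estimation error for (beta, sigma2) shrinks as the series
    grows, for both estimators (averaged over seeded replicates)."""
    p = GompertzParams(r=0.4, k=1.0, sigma2=0.10)
    sizes = (100, 1_000, 10_000)
    ols_err = {"beta": [], "sigma2": []}
    bayes_err = {"beta": [], "sigma2": []}
    settings = MCMCSettings(n_iter=4_000, n_burn=1_500, seed=0)
    for n in sizes:
        oe_b = oe_s = be_b = be_s = 0.0
        reps = 5
        for rep in range(reps):
            y = simulate_gompertz(p, 1.0, n, seed=(777, n, rep)).values
            ols = fit_gompertz_ols(y)
            oe_b += abs(ols.beta - 0.6) / reps
            oe_s += abs(ols.sigma2 - 0.10) / reps
            post = fit_gompertz_bayes(y, settings)
            be_b += abs(post.parameters["beta"].mean - 0.6) / reps
            be_s += abs(post.parameters["sigma2"].mean - 0.10) / reps
        ols_err["beta"].append(oe_b)
        ols_err["sigma2"].append(oe_s)
        bayes_err["beta"].append(be_b)
        bayes_err["sigma2"].append(be_s)
    for d in (ols_err, bayes_err):
        for param, errs in d.items():
            assert errs[0] > errs[-1], (param, errs)
            assert sorted(errs, reverse=True) == errs, (param, errs)
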