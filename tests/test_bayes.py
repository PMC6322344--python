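"""Posterior densities, sampler determinism, and summary statistics."""

import math

import numpy as np
import pytest
from scipy import stats

import dentalrisk as dr
from dentalrisk.bayes import batch_means_mc_error, hpd_interval
from dentalrisk.cohort import DesignMatrix


def _design(y, X, names=None):
    names = tuple(names or (f"x{j}" for j in range(X.shape[1])))
    return DesignMatrix(X=np.asarray(X, float), y=np.asarray(y, float), columns=names)


class TestLogDensities:
    def test_single_record_half_probability(self):
        d = _design([1.0], np.ones((1, 1)))
        assert dr.log_likelihood(np.zeros(1), d) == pytest.approx(math.log(0.5))

    def test_zero_beta_gives_n_log_half(self):
        rng = np.random.default_rng(2)
        d = _design(rng.integers(0, 2, 37), rng.normal(size=(37, 3)))
        assert dr.log_likelihood(np.zeros(3), d) == pytest.approx(37 * math.log(0.5))

    def test_softplus_keeps_extreme_eta_finite(self):
        d = _design([1.0], np.array([[1.0]]))
        val = dr.log_likelihood(np.array([50.0]), d)
        assert val == pytest.approx(-math.exp(-50.0), rel=1e-6)
        assert np.isfinite(dr.log_likelihood(np.array([500.0]), d))
        assert np.isfinite(dr.log_likelihood(np.array([-500.0]), d))

    def test_nonfinite_beta_rejected(self):
        d = _design([1.0], np.ones((1, 1)))
        with pytest.raises(ValueError):
            dr.log_likelihood(np.array([np.nan]), d)

    def test_prior_mode_value(self):
        prior = dr.PriorSpec(mean=0.0, variance=1000.0)
        expected = -0.5 * 8 * math.log(2 * math.pi * 1000.0)
        assert dr.log_prior(np.zeros(8), prior) == pytest.approx(expected)

    def test_prior_one_sd_identity(self):
        prior = dr.PriorSpec(mean=2.0, variance=9.0)
        mode = dr.log_prior(np.array([2.0]), prior)
        assert dr.log_prior(np.array([5.0]), prior) == pytest.approx(mode - 0.5)

    def test_prior_matches_scipy_normal_product(self):
        rng = np.random.default_rng(3)
        beta = rng.normal(size=5)
        mu = rng.normal(size=5)
        var = rng.uniform(0.5, 4.0, size=5)
        prior = dr.PriorSpec(mean=mu, variance=var)
        oracle = stats.norm.logpdf(beta, loc=mu, scale=np.sqrt(var)).sum()
        assert dr.log_prior(beta, prior) == pytest.approx(oracle)

    def test_nonpositive_prior_variance_rejected(self):
        with pytest.raises(ValueError):
            dr.log_prior(np.zeros(2), dr.PriorSpec(variance=0.0))

    def test_posterior_is_likelihood_plus_prior(self):
        rng = np.random.default_rng(4)
        d = _design(rng.integers(0, 2, 20), rng.normal(size=(20, 2)))
        prior = dr.PriorSpec()
        beta = rng.normal(size=2)
        assert dr.log_posterior(beta, d, prior) == pytest.approx(
            dr.log_likelihood(beta, d) + dr.log_prior(beta, prior)
        )

    def test_vague_prior_posterior_mode_near_mle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=200)
        y = (rng.random(200) < 1 / (1 + np.exp(-x))).astype(float)
        d = _design(y, x[:, None])
        mle = dr.LogisticModel(y, x[:, None]).fit().params.iloc[0]
        grid = np.linspace(mle - 1, mle + 1, 4001)
        vague = dr.PriorSpec(variance=1e6)
        post = [dr.log_posterior(np.array([b]), d, vague) for b in grid]
        assert grid[int(np.argmax(post))] == pytest.approx(mle, abs=1e-3)

    def test_degenerate_prior_pins_mode_at_prior_mean(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=50)
        y = (rng.random(50) < 0.5).astype(float)
        d = _design(y, x[:, None])
        tight = dr.PriorSpec(mean=0.7, variance=1e-8)
        grid = np.linspace(0.5, 0.9, 4001)
        post = [dr.log_posterior(np.array([b]), d, tight) for b in grid]
        assert grid[int(np.argmax(post))] == pytest.approx(0.7, abs=1e-3)


class TestSampler:
    def test_same_seed_identical_draws(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=120)
        y = (rng.random(120) < 0.5).astype(float)
        d = _design(y, np.column_stack([np.ones(120), x]))
        cfg = dr.ChainConfig(n_chains=2, iterations=400, burn_in=100, thin=4, seed=9)
        a = dr.bayes.run_chains(d, config=cfg)
        b = dr.bayes.run_chains(d, config=cfg)
        np.testing.assert_array_equal(a.draws, b.draws)

    def test_chains_with_distinct_seeds_differ(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=120)
        y = (rng.random(120) < 0.5).astype(float)
        d = _design(y, np.column_stack([np.ones(120), x]))
        cfg = dr.ChainConfig(n_chains=2, iterations=400, burn_in=100, thin=4, seed=9)
        samples = dr.bayes.run_chains(d, config=cfg)
        assert not np.array_equal(samples.draws[0], samples.draws[1])

    def test_intercept_only_posterior_matches_closed_form_mle(
        self, intercept_only_design
    ):
        y, X = intercept_only_design
        model = dr.BayesianLogit(y, X, names=["intercept"])
        cfg = dr.ChainConfig(
            n_chains=2, iterations=3000, burn_in=1000, thin=10, seed=13
        )
        res = model.fit(cfg)
        summ = res.summary()
        mle = math.log(5229 / 778)
        mle_se = math.sqrt(1 / 5229 + 1 / 778)
        assert abs(summ["mean"].iloc[0] - mle) < 3 * summ["mc_error"].iloc[0]
        assert summ["sd"].iloc[0] == pytest.approx(mle_se, rel=0.10)

    def test_acceptance_rates_interior_after_adaptation(self, default_posterior):
        acc = default_posterior.samples.acceptance
        assert ((acc > 0.1) & (acc < 0.8)).all()

    def test_invalid_chain_configs_rejected(self):
        with pytest.raises(ValueError):
            dr.ChainConfig(n_chains=1)
        with pytest.raises(ValueError):
            dr.ChainConfig(iterations=101, thin=50)
        with pytest.raises(ValueError):
            dr.ChainConfig(thin=0)


class TestSummaries:
    def test_constant_samples_degenerate_summary(self):
        draws = np.full((2, 60, 1), 3.25)
        samples = dr.PosteriorSamples(
            draws=draws,
            acceptance=np.full((2, 1), 0.4),
            names=("c",),
            config=dr.ChainConfig(n_chains=2, iterations=60, burn_in=0, thin=1),
        )
        summ = dr.summarize(samples)
        row = summ.loc["c"]
        assert row["mean"] == row["median"] == 3.25
        assert row["sd"] == 0.0
        assert (row["hpd_lower"], row["hpd_upper"]) == (3.25, 3.25)

    def test_too_few_draws_rejected(self):
        draws = np.zeros((2, 10, 1))
        samples = dr.PosteriorSamples(
            draws=draws,
            acceptance=np.full((2, 1), 0.4),
            names=("c",),
            config=dr.ChainConfig(n_chains=2, iterations=10, burn_in=0, thin=1),
        )
        with pytest.raises(ValueError, match="pooled draws"):
            dr.summarize(samples)

    def test_hpd_matches_brute_force_windows(self):
        rng = np.random.default_rng(21)
        for draw in (rng.normal(size=311), rng.exponential(size=250)):
            lo, hi = hpd_interval(draw, 0.9)
            x = np.sort(draw)
            m = math.ceil(0.9 * len(x))
            best = min(
                ((x[i + m - 1] - x[i], x[i], x[i + m - 1])
                 for i in range(len(x) - m + 1)),
                key=lambda t: t[0],
            )
            assert (lo, hi) == (best[1], best[2])

    def test_hpd_no_longer_than_equal_tail(self):
        rng = np.random.default_rng(22)
        for _ in range(20):
            draw = rng.gamma(shape=rng.uniform(0.5, 5.0), size=400)
            lo, hi = hpd_interval(draw, 0.95)
            ql, qh = np.quantile(draw, [0.025, 0.975])
            assert hi - lo <= (qh - ql) + 1e-12

    def test_mc_error_scales_as_iid_standard_error(self):
        rng = np.random.default_rng(23)
        draws = rng.normal(size=10_000)
        err = batch_means_mc_error(draws)
        assert 0.005 < err < 0.015  # within 50% of sd/sqrt(N) = 0.01

    def test_mc_error_below_sd(self, default_posterior):
        summ = default_posterior.summary()
        assert (summ["mc_error"] < summ["sd"]).all()

    def test_hpd_brackets_median(self, default_posterior):
        summ = default_posterior.summary()
        assert (summ["hpd_lower"] < summ["median"]).all()
        assert (summ["median"] < summ["hpd_upper"]).all()
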