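"""Hierarchical model log densities and posterior sampling."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import expit

from contextfx import (AstParams, PriorSpec, RstEwParams, RstUwParams,
                       SamplerConfig, fit_ast, fit_rst_ew, fit_rst_uw,
                       log_density_ast, log_density_rst_ew, log_density_rst_uw,
                       sample_posterior)
from contextfx.hierarchical import (collapsed_logpost_rst_ew,
                                    collapsed_logpost_rst_uw)

FAST = SamplerConfig(n_chains=3, n_warmup=300, n_kept=400, thin=3)


def _single_hierarchy_oracle(theta, y, N, mu, kappa):
    """Independent re-implementation of one beta-binomial hierarchy."""
    a, b = mu * kappa, (1 - mu) * kappa
    return (stats.binom.logpmf(y, N, theta).sum()
            + stats.beta.logpdf(theta, a, b).sum())


class TestRstUwDensity:
    def test_hand_computed_single_participant(self):
        # y=1 of N=2 at theta=0.5 contributes log(0.5); Beta(0.5 | 1, 1) = 1
        # (mu=0.5, kappa=2); remaining terms are the hyperpriors.
        priors = PriorSpec(mu_beta=(1.0, 1.0), kappa_gamma=(1.0, 1.0))
        params = RstUwParams(mu=0.5, kappa=2.0, theta=np.array([0.5]))
        got = log_density_rst_uw(params, [1], [2], "alternative", priors)
        expected = (np.log(0.5) + 0.0
                    + stats.beta.logpdf(0.5, 1, 1)
                    + stats.gamma.logpdf(2.0, a=1.0, scale=1.0))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_alternative_at_half_equals_null_plus_mean_prior(self):
        y, N = np.array([7, 3, 5]), np.array([10, 10, 10])
        params = RstUwParams(mu=0.5, kappa=4.0, theta=np.array([0.6, 0.4, 0.5]))
        alt = log_density_rst_uw(params, y, N, "alternative")
        null = log_density_rst_uw(params, y, N, "null")
        assert alt == pytest.approx(null + stats.beta.logpdf(0.5, 2, 2),
                                    abs=1e-10)

    @pytest.mark.parametrize("theta", [0.0, 1.0])
    def test_rate_on_support_boundary_gives_neg_inf(self, theta):
        params = RstUwParams(mu=0.5, kappa=2.0, theta=np.array([theta]))
        val = log_density_rst_uw(params, [1], [2])
        assert val == -np.inf and not np.isnan(val)

    def test_invalid_hyperparameters_give_neg_inf_never_nan(self, rng):
        for mu, kappa in [(-0.1, 1.0), (1.5, 1.0), (0.5, 0.0), (0.5, -2.0)]:
            v = log_density_rst_uw(RstUwParams(mu, kappa, np.array([0.5])),
                                   [1], [2])
            assert v == -np.inf


class TestRstEwDensity:
    def test_decomposes_into_independent_context_hierarchies(self, rng):
        n = 6
        y = rng.integers(0, 11, size=(n, 2)).astype(float)
        N = np.full((n, 2), 10.0)
        theta = rng.uniform(0.2, 0.8, size=(n, 2))
        params = RstEwParams(mu=(0.55, 0.45), kappa=(3.0, 6.0), theta=theta)
        got = log_density_rst_ew(params, y, N, "alternative")
        oracle = (_single_hierarchy_oracle(theta[:, 0], y[:, 0], N[:, 0], 0.55, 3.0)
                  + _single_hierarchy_oracle(theta[:, 1], y[:, 1], N[:, 1], 0.45, 6.0)
                  + stats.beta.logpdf(0.55, 2, 2) + stats.beta.logpdf(0.45, 2, 2)
                  + stats.gamma.logpdf(3.0, a=0.001, scale=1000.0)
                  + stats.gamma.logpdf(6.0, a=0.001, scale=1000.0))
        assert got == pytest.approx(oracle, rel=1e-12)

    def test_alternative_at_mirror_mean_reproduces_null_likelihood(self, rng):
        y = rng.integers(0, 11, size=(4, 2)).astype(float)
        N = np.full((4, 2), 10.0)
        theta = rng.uniform(0.2, 0.8, size=(4, 2))
        mu1 = 0.62
        p_alt = RstEwParams(mu=(mu1, 1 - mu1), kappa=(3.0, 5.0), theta=theta)
        alt = log_density_rst_ew(p_alt, y, N, "alternative")
        null = log_density_rst_ew(p_alt, y, N, "null")
        assert alt == pytest.approx(null + stats.beta.logpdf(1 - mu1, 2, 2),
                                    abs=1e-10)

    def test_context_swap_symmetry(self, rng):
        y = rng.integers(0, 11, size=(4, 2)).astype(float)
        N = np.full((4, 2), 10.0)
        theta = rng.uniform(0.2, 0.8, size=(4, 2))
        p = RstEwParams(mu=(0.6, 0.35), kappa=(3.0, 7.0), theta=theta)
        p_sw = RstEwParams(mu=(0.35, 0.6), kappa=(7.0, 3.0), theta=theta[:, ::-1])
        assert log_density_rst_ew(p, y, N) == pytest.approx(
            log_density_rst_ew(p_sw, y[:, ::-1], N[:, ::-1]), rel=1e-12)


class TestAstDensity:
    def test_hand_computed_single_participant(self):
        theta = np.full((1, 2, 3), 1 / 3)
        mu = np.full((2, 3), 1 / 3)
        counts = np.zeros((1, 2, 3))
        counts[0, 0, 0] = 1  # one target choice in context 1, nothing else
        params = AstParams(mu=mu, kappa=(3.0, 3.0), theta=theta)
        got = log_density_ast(params, counts)
        uniform = np.full(3, 1 / 3)
        expected = (np.log(1 / 3)  # multinomial term for the single choice
                    + 2 * stats.dirichlet.logpdf(uniform, 3.0 * uniform)
                    + 2 * stats.dirichlet.logpdf(uniform, [2.0, 2.0, 2.0])
                    + 2 * stats.gamma.logpdf(3.0, a=0.001, scale=1000.0))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_two_identical_contexts_double_the_single_context_terms(self, rng):
        counts1 = rng.multinomial(20, [0.5, 0.3, 0.2], size=5)
        counts = np.stack([counts1, counts1], axis=1)
        theta1 = np.stack([rng.dirichlet([5, 3, 2]) for _ in range(5)])
        theta = np.stack([theta1, theta1], axis=1)
        mu = np.stack([[0.5, 0.3, 0.2]] * 2)
        params = AstParams(mu=mu, kappa=(4.0, 4.0), theta=theta)
        total = log_density_ast(params, counts)
        single = (sum(stats.multinomial.logpmf(counts1[i], 20, theta1[i])
                      for i in range(5))
                  + sum(stats.dirichlet.logpdf(theta1[i], 4.0 * mu[0])
                        for i in range(5))
                  + stats.dirichlet.logpdf(mu[0], [2.0, 2.0, 2.0])
                  + stats.gamma.logpdf(4.0, a=0.001, scale=1000.0))
        assert total == pytest.approx(2 * single, rel=1e-10)

    def test_vanishing_concentration_is_neg_inf_not_nan(self):
        theta = np.full((2, 2, 3), 1 / 3)
        counts = np.ones((2, 2, 3))
        params = AstParams(mu=np.full((2, 3), 1 / 3), kappa=(1e-8, 3.0),
                           theta=theta)
        v = log_density_ast(params, counts)
        assert not np.isnan(v)
        # the kappa floor rules this region out during sampling; the joint
        # density itself stays finite or -inf
        assert v == -np.inf or np.isfinite(v)


class TestCollapsedConsistency:
    """The collapsed hyperparameter posterior must integrate the full joint:
    check it against direct quadrature over theta on a single participant."""

    def test_uw_collapse_matches_quadrature(self):
        from scipy.integrate import quad
        y, N = np.array([7.0]), np.array([10.0])
        mu, kappa = 0.58, 4.2
        a, b = mu * kappa, (1 - mu) * kappa
        like, _ = quad(lambda th: stats.binom.pmf(7, 10, th)
                       * stats.beta.pdf(th, a, b), 0, 1)
        x = np.array([[np.log(mu / (1 - mu)), np.log(kappa)]])
        got = collapsed_logpost_rst_uw(x, y, N, "alternative", PriorSpec())[0]
        expected = (np.log(like) + stats.beta.logpdf(mu, 2, 2)
                    + np.log(mu * (1 - mu))  # logit Jacobian
                    + stats.gamma.logpdf(kappa, a=0.001, scale=1000.0)
                    + np.log(kappa))         # log Jacobian
        assert got == pytest.approx(expected, rel=1e-8)

    def test_ew_null_constraint_ties_the_two_means(self):
        y = np.array([[7.0, 3.0], [5.0, 6.0]])
        N = np.full((2, 2), 10.0)
        x_null = np.array([[0.4, 1.0, 1.2]])
        x_alt = np.array([[0.4, -0.4, 1.0, 1.2]])
        null = collapsed_logpost_rst_ew(x_null, y, N, "null")[0]
        alt = collapsed_logpost_rst_ew(x_alt, y, N, "alternative")[0]
        from scipy.special import betaln
        mu2 = expit(-0.4)
        # the alternative adds the second mean's Beta(2,2) prior plus its
        # logit Jacobian: exponents (2-1)+1 = 2 on mu2 and (1-mu2)
        extra = 2 * np.log(mu2) + 2 * np.log1p(-mu2) - betaln(2.0, 2.0)
        assert alt == pytest.approx(null + extra, abs=1e-10)


class TestSampling:
    def test_conjugate_reduction_recovers_closed_form_rate(self):
        # One participant, hyperparameters pinned at mu=0.5, kappa=4 (i.e. a
        # Beta(2,2) prior on theta): posterior mean must be (7+2)/(10+4).
        pin_kappa = PriorSpec(kappa_gamma=(4e8, 1e8))  # concentrates at 4
        fit = fit_rst_uw([7], [10], "null", priors=pin_kappa, config=FAST,
                         seed=0)
        theta = fit.stacked("theta")[:, 0]
        assert theta.mean() == pytest.approx(9 / 14, abs=0.01)

    def test_zero_data_posterior_returns_the_prior_mean(self):
        fit = fit_rst_uw(np.zeros(5), np.zeros(5), "alternative", config=FAST,
                         seed=3)
        assert fit.stacked("mu").mean() == pytest.approx(0.5, abs=0.05)

    def test_same_seed_reproduces_identical_draws(self):
        y, N = np.array([7, 3, 5, 6]), np.array([10] * 4)
        a = fit_rst_uw(y, N, config=FAST, seed=11)
        b = fit_rst_uw(y, N, config=FAST, seed=11)
        assert np.array_equal(a.stacked("mu"), b.stacked("mu"))
        assert np.array_equal(a.stacked("theta"), b.stacked("theta"))

    def test_dispatcher_covers_all_models(self, rng):
        y = rng.integers(2, 9, size=(6, 2)).astype(float)
        N = np.full((6, 2), 10.0)
        ew = sample_posterior("rst_ew", (y, N), config=FAST, seed=1)
        assert set(ew.posterior) >= {"mu_C1", "mu_C2", "kappa_C1", "kappa_C2"}
        counts = rng.multinomial(20, [0.4, 0.4, 0.2], size=(6, 2))
        ast = sample_posterior("ast", counts, config=FAST, seed=1)
        mu1 = ast.stacked("mu_C1")
        assert np.allclose(mu1.sum(axis=1), 1.0)
        with pytest.raises(ValueError):
            sample_posterior("nope", (y, N))

    def test_alternative_density_dominates_null_at_matched_points(self, rng):
        # the null is nested: at mu=0.5 the alternative density exceeds the
        # null by the (positive) log prior density Beta(0.5 | 2, 2), so the
        # alternative's maximum is never below the null's
        y, N = rng.integers(0, 11, size=8).astype(float), np.full(8, 10.0)
        for _ in range(20):
            params = RstUwParams(mu=0.5, kappa=float(rng.uniform(0.5, 20)),
                                 theta=rng.uniform(0.05, 0.95, size=8))
            alt = log_density_rst_uw(params, y, N, "alternative")
            null = log_density_rst_uw(params, y, N, "null")
            assert alt >= null

    def test_posterior_hdi_width_shrinks_with_sample_size(self):
        # noiseless counts at a shared rate theta=0.6: with no
        # between-participant spread the group-mean posterior keeps
        # sharpening as per-participant trial counts grow
        from contextfx import hdi
        widths = []
        for n in (10, 100, 1000):
            y = np.full(30, round(0.6 * n))
            fit = fit_rst_uw(y, np.full(30, n), config=FAST, seed=5)
            lo, hi = hdi(fit.stacked("mu"))
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]
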