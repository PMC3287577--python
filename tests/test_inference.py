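"""Marginalized likelihood, Gamma proposals and the MH sampler."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

import bayesode as bo
from bayesode.inference import log_acceptance, log_marginal_likelihood, log_prior, log_proposal_ratio

pos = st.floats(min_value=1e-3, max_value=1e3)


class TestModelError:
    def test_examples(self):
        assert bo.model_error([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert bo.model_error([1.0, 2.0], [0.0, 0.0]) == 5.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            bo.model_error([1.0], [1.0, 2.0])

    @settings(deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=8),
           st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=8))
    def test_additive_over_concatenation(self, a, b):
        ya, yb = np.array(a), np.array(b)
        total = bo.model_error(np.r_[ya, yb], np.zeros(ya.size + yb.size))
        assert total == pytest.approx(
            bo.model_error(ya, np.zeros(ya.size)) + bo.model_error(yb, np.zeros(yb.size))
        )


def quadrature_log_marginal(me, m, prior):
    """Independent oracle: numerically integrate the Gaussian likelihood
    against the IG(eta2, beta2) density over sigma^2, in a log-stable way."""

    def log_integrand(s2):
        return (
            -0.5 * m * np.log(2 * np.pi * s2)
            - me / (2 * s2)
            + stats.invgamma.logpdf(s2, prior.eta2, scale=prior.beta2)
        )

    # substitute s2 = e^w so the integrand is well scaled; c centers it
    s2_mode = (me / 2 + prior.beta2) / (m / 2 + prior.eta2 + 1)
    w0 = np.log(s2_mode)
    c = log_integrand(s2_mode)
    val, _ = integrate.quad(
        lambda w: np.exp(log_integrand(np.exp(w)) + w - c),
        w0 - 60.0, w0 + 60.0, points=[w0], limit=500,
    )
    return c + np.log(val)


class TestLogMarginalLikelihood:
    @pytest.mark.parametrize("m, me", [(3, 1.0), (3, 0.0), (10, 25.0), (500, 5e3), (50, 1e6)])
    def test_matches_quadrature(self, m, me):
        prior = bo.NoiseVariancePrior(eta2=2.0, beta2=10.0)
        got = log_marginal_likelihood(me, m, prior)
        want = quadrature_log_marginal(me, m, prior)
        assert got == pytest.approx(want, rel=1e-8, abs=1e-8)

    def test_difference_depends_only_on_me_ratio_term(self):
        prior = bo.NoiseVariancePrior(2.0, 10.0)
        m = 42
        me_a, me_b = 3.0, 11.0
        diff = log_marginal_likelihood(me_a, m, prior) - log_marginal_likelihood(me_b, m, prior)
        expected = -(0.5 * m + prior.eta2) * (
            math.log(me_a + 2 * prior.beta2) - math.log(me_b + 2 * prior.beta2)
        )
        assert diff == pytest.approx(expected, rel=1e-12)

    def test_monotone_decreasing_in_me(self):
        prior = bo.NoiseVariancePrior(2.0, 10.0)
        vals = [log_marginal_likelihood(me, 100, prior) for me in (0.0, 1.0, 10.0, 1e4)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_finite_at_extremes(self):
        prior = bo.NoiseVariancePrior(2.0, 10.0)
        assert math.isfinite(log_marginal_likelihood(1e12, 500, prior))
        assert math.isfinite(log_marginal_likelihood(0.0, 500, prior))

    def test_negative_me_rejected(self):
        with pytest.raises(ValueError):
            log_marginal_likelihood(-1.0, 10, bo.NoiseVariancePrior())


class TestLogPrior:
    def test_exponential_case(self):
        prior = bo.GammaPrior(eta=1.0, beta=3.0)
        assert log_prior(3.0, prior) == pytest.approx(-1.0 - math.log(3.0), rel=1e-12)

    @settings(deadline=None)
    @given(theta=pos, eta=st.floats(0.5, 10), beta=st.floats(0.1, 100))
    def test_matches_scipy_gamma(self, theta, eta, beta):
        got = log_prior(theta, bo.GammaPrior(eta, beta))
        assert got == pytest.approx(stats.gamma.logpdf(theta, eta, scale=beta), rel=1e-10, abs=1e-10)

    def test_normalizes_to_one(self):
        prior = bo.GammaPrior(eta=2.0, beta=4.0)
        val, _ = integrate.quad(lambda t: math.exp(log_prior(t, prior)), 0, np.inf)
        assert val == pytest.approx(1.0, rel=1e-8)

    def test_mode_at_stationary_point(self):
        prior = bo.GammaPrior(eta=2.0, beta=4.0)
        mode = (prior.eta - 1) * prior.beta
        eps = 1e-4
        assert log_prior(mode, prior) > log_prior(mode + eps, prior)
        assert log_prior(mode, prior) > log_prior(mode - eps, prior)


class TestPropose:
    def test_moments(self):
        spec = bo.ProposalSpec(eta1=2.0, beta1=0.5)
        rng = np.random.default_rng(11)
        theta_i = 3.0
        draws = np.array([bo.propose(theta_i, spec, rng) for _ in range(100_000)])
        assert np.all(draws > 0)
        mean, var = spec.eta1 * spec.beta1 * theta_i, spec.eta1 * spec.beta1**2 * theta_i**2
        assert abs(draws.mean() - mean) < 3 * math.sqrt(var / draws.size)
        assert var * 0.97 < draws.var() < var * 1.03

    def test_nonpositive_current_rejected(self):
        with pytest.raises(ValueError):
            bo.propose(0.0, bo.ProposalSpec(), np.random.default_rng(0))


class TestLogProposalRatio:
    def test_zero_at_equal_arguments(self):
        assert log_proposal_ratio(2.0, 2.0, bo.ProposalSpec()) == 0.0

    @settings(deadline=None)
    @given(a=pos, b=pos, eta1=st.floats(0.5, 10), beta1=st.floats(0.05, 10))
    def test_antisymmetric(self, a, b, eta1, beta1):
        spec = bo.ProposalSpec(eta1, beta1)
        assert log_proposal_ratio(a, b, spec) == pytest.approx(
            -log_proposal_ratio(b, a, spec), rel=1e-9, abs=1e-9
        )

    @settings(deadline=None)
    @given(a=pos, b=pos)
    def test_matches_gamma_density_ratio(self, a, b):
        """Direct evaluation of the two Gamma log densities is the oracle."""
        spec = bo.ProposalSpec(eta1=2.0, beta1=0.5)
        direct = stats.gamma.logpdf(a, spec.eta1, scale=spec.beta1 * b) - stats.gamma.logpdf(
            b, spec.eta1, scale=spec.beta1 * a
        )
        assert log_proposal_ratio(a, b, spec) == pytest.approx(direct, rel=1e-9, abs=1e-12)


class TestLogAcceptance:
    prior = bo.GammaPrior(2.0, 4.0)
    noise = bo.NoiseVariancePrior(2.0, 10.0)
    spec = bo.ProposalSpec(2.0, 0.5)

    def test_identity_move_has_alpha_one(self):
        la = log_acceptance(3.0, 3.0, 100, 5.0, 5.0, self.prior, self.noise, self.spec)
        assert la == 0.0

    def test_decomposes_into_components(self):
        me_s, me_i, m, th_s, th_i = 7.0, 3.0, 100, 4.0, 5.0
        la = log_acceptance(me_s, me_i, m, th_s, th_i, self.prior, self.noise, self.spec)
        parts = (
            log_marginal_likelihood(me_s, m, self.noise)
            - log_marginal_likelihood(me_i, m, self.noise)
            + log_prior(th_s, self.prior)
            - log_prior(th_i, self.prior)
            + log_proposal_ratio(th_i, th_s, self.spec)
        )
        assert la == pytest.approx(parts, rel=1e-12)

    def test_detailed_balance_on_random_pairs(self):
        """pi(a) q(b|a) min(1, alpha(a->b)) == pi(b) q(a|b) min(1, alpha(b->a))
        for the unnormalized marginal posterior pi over a synthetic model-
        error curve."""
        m = 50

        def me(theta):  # smooth positive stand-in for a model-error surface
            return (theta - 2.0) ** 2 + 1.0

        def log_pi(theta):
            return log_marginal_likelihood(me(theta), m, self.noise) + log_prior(theta, self.prior)

        def log_q(to, frm):
            return stats.gamma.logpdf(to, self.spec.eta1, scale=self.spec.beta1 * frm)

        rng = np.random.default_rng(5)
        for _ in range(25):
            a, b = rng.uniform(0.2, 8.0, size=2)
            la_fwd = log_acceptance(me(b), me(a), m, b, a, self.prior, self.noise, self.spec)
            la_rev = log_acceptance(me(a), me(b), m, a, b, self.prior, self.noise, self.spec)
            lhs = log_pi(a) + log_q(b, a) + min(0.0, la_fwd)
            rhs = log_pi(b) + log_q(a, b) + min(0.0, la_rev)
            assert lhs == pytest.approx(rhs, rel=1e-10, abs=1e-10)

    def test_finite_for_huge_model_error(self):
        la = log_acceptance(1e12, 1.0, 500, 4.0, 5.0, self.prior, self.noise, self.spec)
        assert math.isfinite(la)


def batch_means_se(x, n_batches=20):
    """Monte-Carlo standard error of the mean of a correlated chain."""
    n = len(x) // n_batches
    means = np.array([x[i * n:(i + 1) * n].mean() for i in range(n_batches)])
    return means.std(ddof=1) / math.sqrt(n_batches)


class TestRunChain:
    def _quick_setup(self, small_grid):
        data = bo.generate_dataset({"V": 5.0, "K": 2.0}, grid=small_grid,
                                   noise=bo.NoiseSpec(0.5, seed=9))
        model = bo.tgf_beta_model(("V",), K=2.0)
        inputs = (bo.profile_function(bo.IL10_DEFAULT), bo.profile_function(bo.MACROPHAGE_DEFAULT))
        return model, data, inputs

    def test_seed_determinism_bitwise(self, small_grid):
        model, data, inputs = self._quick_setup(small_grid)
        cfg = bo.MCMCConfig(n_iter=300, burn_in=100, seed=123)
        c1 = bo.run_chain(model, data, inputs, bo.GammaPrior(2, 4), config=cfg)
        c2 = bo.run_chain(model, data, inputs, bo.GammaPrior(2, 4), config=cfg)
        assert np.array_equal(c1.samples, c2.samples)
        assert np.array_equal(c1.accepted, c2.accepted)

    def test_acceptance_fraction_strictly_between_zero_and_one(self, small_grid):
        model, data, inputs = self._quick_setup(small_grid)
        chain = bo.run_chain(
            model, data, inputs, bo.GammaPrior(2, 4),
            config=bo.MCMCConfig(n_iter=800, burn_in=400, seed=2),
        )
        rate = chain.accept_rate["V"]
        assert 0.0 < rate < 1.0
        assert np.all(chain.samples > 0)

    def test_prior_recovery_with_constant_likelihood(self):
        """With the likelihood forced constant the chain must sample the
        Gamma prior; mean and variance agree within 3 MC standard errors."""
        prior = bo.GammaPrior(eta=2.0, beta=4.0)
        model = bo.tgf_beta_model(("V",), K=2.0)
        chain = bo.run_chain(
            model, None, None, prior,
            config=bo.MCMCConfig(n_iter=120_000, burn_in=10_000, seed=7),
            log_likelihood=lambda theta: 0.0,
        )
        kept = chain.retained()[:, 0]
        se_mean = batch_means_se(kept)
        assert abs(kept.mean() - prior.mean) < 3 * se_mean
        sq_se = batch_means_se((kept - prior.mean) ** 2)
        assert abs(kept.var() - prior.variance) < 3 * sq_se + 0.05 * prior.variance

    def test_occupation_matches_grid_posterior(self):
        """Long-run bin occupancies match brute-force normalization of the
        unnormalized 1-parameter posterior (total-variation check)."""
        prior = bo.GammaPrior(2.0, 4.0)
        noise = bo.NoiseVariancePrior(2.0, 10.0)
        m = 20

        def loglik(theta):
            me = 5.0 * (theta[0] - 3.0) ** 2 + 2.0
            return -(0.5 * m + noise.eta2) * math.log(me + 2 * noise.beta2)

        model = bo.tgf_beta_model(("V",), K=2.0)
        chain = bo.run_chain(
            model, None, None, prior,
            config=bo.MCMCConfig(n_iter=100_000, burn_in=5_000, seed=3),
            log_likelihood=loglik,
        )
        kept = chain.retained()[:, 0]
        edges = np.linspace(0.0, 12.0, 25)
        grid = np.linspace(1e-4, 40.0, 40_001)
        dens = np.exp([loglik([t]) + log_prior(t, prior) for t in grid])
        dens /= np.trapezoid(dens, grid)
        cdf_vals = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))])
        target = np.interp(edges, grid, cdf_vals)
        p_target = np.diff(np.r_[target, cdf_vals[-1]])
        counts, _ = np.histogram(kept, bins=np.r_[edges, np.inf])
        p_chain = counts / counts.sum()
        tv = 0.5 * np.abs(p_chain - p_target).sum()
        assert tv < 0.05, tv

    def test_componentwise_updates_both_parameters(self, small_grid, default_inputs):
        data = bo.generate_dataset({"V": 5.0, "K": 2.0}, grid=small_grid,
                                   noise=bo.NoiseSpec(0.1, seed=4))
        model = bo.tgf_beta_model(("V", "K"))
        chain = bo.run_chain(
            model, data, default_inputs,
            {"V": bo.GammaPrior(2, 4), "K": bo.GammaPrior(2, 2000)},
            config=bo.MCMCConfig(n_iter=400, burn_in=200, seed=6),
        )
        assert chain.samples.shape == (400, 2)
        assert chain.accepted[:, 0].sum() > 0 and chain.accepted[:, 1].sum() > 0

    def test_missing_prior_is_an_error(self, small_grid, default_inputs):
        data = bo.generate_dataset({"V": 5.0, "K": 2.0}, grid=small_grid)
        model = bo.tgf_beta_model(("V", "K"))
        with pytest.raises(ValueError, match="prior"):
            bo.run_chain(model, data, default_inputs, {"V": bo.GammaPrior(2, 4)})


class TestMMSE:
    def _chain(self, samples, burn_in=0):
        arr = np.asarray(samples, float).reshape(-1, 1)
        return bo.Chain(
            param_names=("V",),
            samples=arr,
            accepted=np.ones_like(arr, dtype=bool),
            config=bo.MCMCConfig(n_iter=arr.shape[0], burn_in=burn_in, seed=0),
        )

    def test_constant_chain(self):
        assert bo.mmse(self._chain([2.0, 2.0, 2.0])).mmse["V"] == 2.0

    def test_burn_in_discarded(self):
        assert bo.mmse(self._chain([1.0, 2.0, 3.0, 4.0], burn_in=2)).mmse["V"] == 3.5

    def test_mean_within_retained_range(self):
        rng = np.random.default_rng(1)
        chain = self._chain(rng.uniform(1, 9, 100), burn_in=20)
        out = bo.mmse(chain)
        kept = chain.retained()
        assert kept.min() <= out.mmse["V"] <= kept.max()
        lo, hi = out.quantiles["V"]
        assert kept.min() <= lo <= hi <= kept.max()
        assert out.n_retained == 80

    def test_empty_retained_set_rejected(self):
        with pytest.raises(ValueError):
            bo.mmse(self._chain([1.0, 2.0]), burn_in=2)
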