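"""Gaussian-mixture machinery against closed forms and quadrature oracles."""

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import ks_1samp, norm

from bipsda.gmm import (
    GaussianMixture,
    PriorSpec,
    build_prior,
    gmm_logpdf,
    gmm_sample,
    linear_gaussian_posterior,
    noisy_marginal,
    noisy_score,
    noisy_score_jacobian,
)


class TestBuildPrior:
    def test_component2_covariance_is_linspace_diagonal(self):
        prior = build_prior(PriorSpec(seed=5))
        assert np.allclose(np.diag(prior.covariances[1]), np.linspace(1, 2, 10))
        off = prior.covariances[1] - np.diag(np.diag(prior.covariances[1]))
        assert np.all(off == 0)

    def test_component3_shares_component2_eigenvalues(self):
        prior = build_prior(PriorSpec(seed=5))
        ev2 = np.sort(np.linalg.eigvalsh(prior.covariances[1]))
        ev3 = np.sort(np.linalg.eigvalsh(prior.covariances[2]))
        assert np.allclose(ev2, ev3, atol=1e-10)

    def test_means_and_weights(self):
        prior = build_prior(PriorSpec(seed=5))
        assert np.allclose(prior.means[0], -5.0)
        assert np.allclose(prior.means[1], 0.0)
        assert np.allclose(prior.means[2], 5.0)
        assert np.allclose(prior.weights, [0.4, 0.3, 0.3])

    def test_deterministic_given_seed(self):
        a, b = build_prior(PriorSpec(seed=7)), build_prior(PriorSpec(seed=7))
        assert np.array_equal(a.covariances, b.covariances)
        c = build_prior(PriorSpec(seed=8))
        assert not np.allclose(a.covariances[2], c.covariances[2])

    def test_invalid_seed_type_rejected(self):
        with pytest.raises(TypeError):
            PriorSpec(seed=0.5)


class TestInvariants:
    def test_weights_must_be_positive_and_normalized(self):
        with pytest.raises(ValueError):
            GaussianMixture([0.5, 0.6], np.zeros((2, 1)), np.ones((2, 1, 1)))
        with pytest.raises(ValueError):
            GaussianMixture([1.2, -0.2], np.zeros((2, 1)), np.ones((2, 1, 1)))

    def test_non_spd_covariance_rejected(self):
        with pytest.raises(ValueError):
            GaussianMixture([1.0], np.zeros((1, 2)), -np.eye(2)[None])

    def test_serialization_roundtrip(self, prior):
        again = GaussianMixture.from_json(prior.to_json())
        assert np.allclose(again.covariances, prior.covariances)
        assert np.allclose(again.weights, prior.weights)


class TestLogpdf:
    def test_standard_normal_at_origin(self):
        g = GaussianMixture([1.0], np.zeros((1, 10)), np.eye(10)[None])
        assert np.isclose(g.logpdf(np.zeros(10)), -5 * np.log(2 * np.pi))

    def test_component_permutation_invariance(self, mix2d):
        flipped = GaussianMixture(
            mix2d.weights[::-1], mix2d.means[::-1], mix2d.covariances[::-1]
        )
        x = np.array([0.3, -0.7])
        assert np.isclose(mix2d.logpdf(x), flipped.logpdf(x), rtol=1e-14)

    def test_matches_direct_summation_1d(self, mix1d):
        pts = np.array([-3.0, -1.0, 0.0, 1.0, 2.5])
        direct = np.log(
            0.3 * norm.pdf(pts, -2.0, np.sqrt(0.5))
            + 0.7 * norm.pdf(pts, 1.5, np.sqrt(1.2))
        )
        ours = mix1d.logpdf(pts[:, None])
        assert np.allclose(ours, direct, rtol=1e-12)

    def test_no_underflow_far_from_modes(self, prior):
        # naive density evaluation underflows here; log-sum-exp must not
        val = prior.logpdf(np.full(10, 40.0))
        assert np.isfinite(val) and val < -1000


class TestSampling:
    def test_law_of_large_numbers_single_component(self, rng):
        g = GaussianMixture([1.0], np.zeros((1, 10)), np.eye(10)[None])
        s = gmm_sample(g, 100_000, rng)
        assert np.linalg.norm(s.mean(axis=0)) < 4 * np.sqrt(10 / 1e5)

    def test_component_assignment_frequency(self, prior, rng):
        s = gmm_sample(prior, 100_000, rng)
        frac = np.mean(s.sum(axis=1) < -20)  # component 1 sits at -5*1
        assert abs(frac - 0.4) < 0.01

    def test_ks_against_quadrature_cdf(self, mix1d, rng):
        s = gmm_sample(mix1d, 100_000, rng)[:, 0]

        def cdf(x):
            return 0.3 * norm.cdf(x, -2.0, np.sqrt(0.5)) + 0.7 * norm.cdf(
                x, 1.5, np.sqrt(1.2)
            )

        assert ks_1samp(s, cdf).statistic < 0.01


class TestNoisyMarginal:
    def test_sigma_zero_is_identity(self, prior):
        nm = noisy_marginal(prior, 0.0)
        assert np.array_equal(nm.covariances, prior.covariances)

    def test_weights_unchanged(self, prior):
        assert np.allclose(noisy_marginal(prior, 3.7).weights, prior.weights)

    def test_negative_sigma_rejected(self, prior):
        with pytest.raises(ValueError):
            noisy_marginal(prior, -1.0)

    def test_density_matches_numerical_convolution_1d(self, mix1d):
        sigma = 0.8
        nm = noisy_marginal(mix1d, sigma)
        for x in [-4.0, -2.0, -1.0, 0.0, 1.0, 2.0, 4.0]:
            conv, _ = integrate.quad(
                lambda u: np.exp(mix1d.logpdf(np.array([u])))
                * norm.pdf(x - u, 0, sigma),
                -15,
                15,
                limit=200,
            )
            assert np.isclose(np.exp(nm.logpdf(np.array([x]))), conv, rtol=1e-8)


class TestNoisyScore:
    def test_single_gaussian_closed_form(self, rng):
        cov = np.array([[2.0, 0.5], [0.5, 1.0]])
        mu = np.array([1.0, -1.0])
        g = GaussianMixture([1.0], mu[None], cov[None])
        sigma = 1.3
        m = rng.standard_normal(2)
        expected = -np.linalg.solve(cov + sigma**2 * np.eye(2), m - mu)
        assert np.allclose(noisy_score(g, m, sigma), expected, atol=1e-12)

    def test_zero_at_symmetric_point(self):
        g = GaussianMixture(
            [0.5, 0.5], np.array([[-1.0], [1.0]]), np.array([[[0.7]], [[0.7]]])
        )
        assert abs(noisy_score(g, np.array([0.0]), 0.9)[0]) < 1e-12

    def test_matches_finite_differences(self, prior, rng):
        sigma = 1.7
        nm = noisy_marginal(prior, sigma)
        pts = prior.sample(20, rng) + sigma * rng.standard_normal((20, 10))
        s = noisy_score(prior, pts, sigma)
        eps = 1e-5
        for i in range(20):
            fd = np.empty(10)
            for k in range(10):
                e = np.zeros(10)
                e[k] = eps
                fd[k] = (nm.logpdf(pts[i] + e) - nm.logpdf(pts[i] - e)) / (2 * eps)
            assert np.allclose(s[i], fd, rtol=1e-5, atol=1e-7)


class TestScoreJacobian:
    def test_single_gaussian_constant(self, rng):
        cov = np.diag([2.0, 0.5])
        g = GaussianMixture([1.0], np.zeros((1, 2)), cov[None])
        sigma = 0.6
        j = noisy_score_jacobian(g, rng.standard_normal(2), sigma)
        assert np.allclose(j, -np.linalg.inv(cov + sigma**2 * np.eye(2)), atol=1e-12)

    def test_symmetry(self, prior, rng):
        pts = prior.sample(5, rng)
        j = noisy_score_jacobian(prior, pts, 2.0)
        assert np.max(np.abs(j - np.swapaxes(j, 1, 2))) < 1e-10

    def test_matches_finite_differences(self, prior, rng):
        sigma = 1.1
        pts = prior.sample(5, rng)
        j = noisy_score_jacobian(prior, pts, sigma)
        eps = 1e-6
        for i in range(5):
            for k in range(10):
                e = np.zeros(10)
                e[k] = eps
                fd = (
                    noisy_score(prior, pts[i] + e, sigma)
                    - noisy_score(prior, pts[i] - e, sigma)
                ) / (2 * eps)
                assert np.allclose(j[i][:, k], fd, atol=1e-4)


class TestLinearGaussianPosterior:
    def test_no_information_recovers_prior(self, prior):
        post = linear_gaussian_posterior(prior, np.zeros((8, 10)), 1.0, np.zeros(8))
        assert np.allclose(post.weights, prior.weights)
        assert np.allclose(post.means, prior.means)
        assert np.allclose(post.covariances, prior.covariances)

    def test_conjugate_identity(self):
        g = GaussianMixture([1.0], np.zeros((1, 4)), np.eye(4)[None])
        post = linear_gaussian_posterior(g, np.eye(4), 1.0, np.zeros(4))
        assert np.allclose(post.covariances[0], np.eye(4) / 2, atol=1e-12)

    def test_matches_quadrature_1d(self, mix1d):
        a = np.array([[1.0]])
        tau, y = 0.9, np.array([0.4])
        post = linear_gaussian_posterior(mix1d, a, tau, y)

        def unnorm(u):
            return np.exp(mix1d.logpdf(np.array([u]))) * norm.pdf(y[0], u, tau)

        z, _ = integrate.quad(unnorm, -12, 12, limit=300)
        mean_q, _ = integrate.quad(lambda u: u * unnorm(u) / z, -12, 12, limit=300)
        var_q, _ = integrate.quad(
            lambda u: (u - mean_q) ** 2 * unnorm(u) / z, -12, 12, limit=300
        )
        assert abs(post.mean()[0] - mean_q) < 1e-6
        assert abs(post.cov()[0, 0] - var_q) < 1e-6

    def test_weights_revert_to_prior_as_tau_grows(self, prior, rng):
        y = rng.standard_normal(8)
        a = np.zeros((8, 10))
        a[np.arange(8), np.arange(8)] = 1.0
        post = linear_gaussian_posterior(prior, a, 1e5, y)
        assert np.allclose(post.weights, prior.weights, atol=1e-4)
        assert np.isclose(post.weights.sum(), 1.0)


def test_noisy_samples_match_noisy_marginal_distribution(prior, rng):
    """Samples of the noisy marginal and noised prior samples agree (moments)."""
    sigma = 2.5
    n = 10_000
    s1 = noisy_marginal(prior, sigma).sample(n, rng)
    s2 = prior.sample(n, rng) + sigma * rng.standard_normal((n, 10))
    se = np.sqrt(np.diag(prior.cov()).max() + sigma**2) / np.sqrt(n)
    assert np.linalg.norm(s1.mean(0) - s2.mean(0)) < 4 * se * np.sqrt(10)
    assert np.allclose(s1.var(0), s2.var(0), rtol=0.15)
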