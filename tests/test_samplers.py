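"""Prediction samplers: Langevin stationary laws, MAP identities, RTO
exactness, Gauss-Newton preconditioning."""

import numpy as np
import pytest

from bipsda.gmm import GaussianMixture
from bipsda.problems import LinearGaussianLikelihood, make_problem, simulate_measurement
from bipsda.samplers import (
    DenoisingApprox,
    LangevinConfig,
    MapConfig,
    gauss_newton_preconditioner,
    sample_langevin,
    sample_map,
    sample_rto,
)


def _no_data_likelihood(dim=2, n_obs=1):
    """A likelihood that carries no information (zero forward map)."""
    return LinearGaussianLikelihood(np.zeros((n_obs, dim)), tau=1.0)


class TestLangevin:
    def test_ula_stationary_variance_closed_form(self, rng):
        # For a N(0, s^2) target, the unadjusted chain x <- x(1 - eta/s^2)
        # + sqrt(2 eta) z has stationary variance 2 s^2 / (2 - eta/s^2).
        s2 = 1.0
        eta = 1e-2
        like = _no_data_likelihood()
        n = 4000
        approx = DenoisingApprox(np.zeros((n, 2)), beta=np.sqrt(s2))
        cfg = LangevinConfig(step_size=eta, n_subiters=10_000)
        out, div = sample_langevin(like, np.zeros(1), approx, cfg, seed=rng)
        assert not div.any()
        expected = 2 * s2 / (2 - eta / s2)
        assert np.allclose(out.var(axis=0), expected, rtol=0.05)

    def test_mala_targets_exactly(self, rng):
        like = _no_data_likelihood()
        n = 4000
        approx = DenoisingApprox(np.zeros((n, 2)), beta=1.0)
        cfg = LangevinConfig(step_size=0.5, n_subiters=3000, metropolis=True)
        out, div = sample_langevin(like, np.zeros(1), approx, cfg, seed=rng)
        assert not div.any()
        assert np.abs(out.mean(axis=0)).max() < 4 / np.sqrt(n)
        assert np.allclose(out.var(axis=0), 1.0, rtol=0.1)

    def test_divergent_chains_flagged_not_poisoned(self, rng):
        like = LinearGaussianLikelihood(np.eye(2), tau=1e-3)
        n = 50
        approx = DenoisingApprox(np.zeros((n, 2)), beta=1.0)
        # enormous step on a stiff target: chains explode
        cfg = LangevinConfig(step_size=10.0, n_subiters=200)
        out, div = sample_langevin(like, np.zeros(2), approx, cfg, seed=rng)
        assert np.all(np.isfinite(out))
        assert div.all()


class TestMap:
    def test_equal_precision_average(self):
        like = LinearGaussianLikelihood(np.eye(3), tau=1.0)
        approx = DenoisingApprox(np.zeros((1, 3)), beta=1.0)
        out = sample_map(like, 2.0 * np.ones(3), approx, MapConfig("closed_form"))
        assert np.allclose(out, 1.0, atol=1e-12)

    def test_closed_form_matches_quasi_newton(self, rng):
        like = make_problem("inpaint_high")
        n = 6
        approx = DenoisingApprox(rng.standard_normal((n, 10)), beta=1.3)
        y = rng.standard_normal(8)
        a = sample_map(like, y, approx, MapConfig("closed_form"))
        b = sample_map(like, y, approx, MapConfig("quasi_newton", max_iters=200))
        assert np.allclose(a, b, atol=1e-5)

    def test_closed_form_matches_gauss_newton_full_cov(self, rng):
        like = make_problem("inpaint_low")
        n = 5
        w = rng.standard_normal((n, 10, 10)) * 0.1
        cov = np.einsum("nij,nkj->nik", w, w) + np.eye(10)[None]
        approx = DenoisingApprox(rng.standard_normal((n, 10)), cov=cov)
        y = rng.standard_normal(8)
        a = sample_map(like, y, approx, MapConfig("closed_form"))
        b = sample_map(like, y, approx, MapConfig("gauss_newton"))
        assert np.allclose(a, b, atol=1e-6)

    def test_nonlinear_stationarity(self, rng):
        like = make_problem("xray", 3)
        m_star = rng.standard_normal(10) * 0.3
        y = simulate_measurement(like, m_star, rng).y
        n = 40
        approx = DenoisingApprox(
            m_star + 0.5 * rng.standard_normal((n, 10)), beta=0.7
        )
        out = sample_map(like, y, approx, MapConfig("gauss_newton"))
        g = like.loglike_grad(out, y) + approx.gauss_grad(out)
        assert np.linalg.norm(g, axis=1).max() < 1e-4

    def test_degenerate_prior_returns_mean(self, rng):
        like = make_problem("inpaint_low")
        mean = rng.standard_normal((4, 10))
        approx = DenoisingApprox(mean, beta=0.0)
        out = sample_map(like, rng.standard_normal(8), approx, MapConfig("closed_form"))
        assert np.array_equal(out, mean)


class TestRto:
    def test_linear_gaussian_exactness(self, rng):
        """RTO draws match the exact Gaussian prediction posterior moments."""
        like = make_problem("inpaint_low")
        n = 100_000
        m_aprx = rng.standard_normal(10)
        beta = 0.5
        approx = DenoisingApprox(np.tile(m_aprx, (n, 1)), beta=beta)
        y = rng.standard_normal(8)
        out = sample_rto(like, y, approx, MapConfig("closed_form"), seed=rng)
        h = like.a.T @ like.a / like.tau**2 + np.eye(10) / beta**2
        cov = np.linalg.inv(h)
        mu = cov @ (like.a.T @ y / like.tau**2 + m_aprx / beta**2)
        se_mean = np.sqrt(np.diag(cov) / n)
        assert np.all(np.abs(out.mean(axis=0) - mu) < 3 * se_mean)
        emp_cov = np.cov(out.T)
        se_var = np.sqrt(2.0 / n) * np.outer(
            np.sqrt(np.diag(cov)), np.sqrt(np.diag(cov))
        )
        assert np.all(np.abs(emp_cov - cov) < 4 * se_var + 1e-12)

    def test_uninformative_data_limit(self, rng):
        like = _no_data_likelihood(dim=3)
        n = 50_000
        approx = DenoisingApprox(np.ones((n, 3)), beta=2.0)
        out = sample_rto(like, np.zeros(1), approx, MapConfig("closed_form"), seed=rng)
        assert np.allclose(out.mean(axis=0), 1.0, atol=0.05)
        assert np.allclose(out.var(axis=0), 4.0, rtol=0.05)

    def test_degenerate_cov_limit(self, rng):
        like = make_problem("inpaint_low")
        mean = rng.standard_normal((10, 10))
        approx = DenoisingApprox(mean, beta=0.0)
        out = sample_rto(like, rng.standard_normal(8), approx, seed=rng)
        assert np.array_equal(out, mean)


class TestPreconditioner:
    def test_linear_case_exact(self, rng):
        like = make_problem("inpaint_low")
        approx = DenoisingApprox(np.zeros((4, 10)), beta=0.8)
        p = gauss_newton_preconditioner(like, approx, rng.standard_normal((8, 10)))
        expected = np.linalg.inv(
            like.a.T @ like.a / like.tau**2 + np.eye(10) / 0.64 + 1e-8 * np.eye(10)
        )
        assert np.allclose(p, expected, atol=1e-10)

    def test_spd_for_any_anchors(self, rng):
        like = make_problem("phase", 4)
        approx = DenoisingApprox(np.zeros((4, 10)), beta=1.5)
        p = gauss_newton_preconditioner(like, approx, 5 * rng.standard_normal((8, 10)))
        ev = np.linalg.eigvalsh(p)
        assert np.all(ev > 0)
        assert np.allclose(p, p.T)

    def test_preconditioned_mala_fixes_bad_scaling(self, rng):
        # target N(0, diag(100, 0.01)): isotropic MALA at step 0.2 stalls,
        # the Gauss-Newton preconditioned version accepts happily
        cov = np.diag([100.0, 0.01])
        like = LinearGaussianLikelihood(np.eye(2), tau=1.0)
        n = 400
        approx = DenoisingApprox(np.zeros((n, 2)), cov=np.broadcast_to(cov, (n, 2, 2)).copy())
        y = np.zeros(2)

        def acc_rate(precond):
            cfg = LangevinConfig(
                step_size=0.2, n_subiters=200, metropolis=True, preconditioner=precond
            )
            out, _ = sample_langevin(like, y, approx, cfg, seed=np.random.default_rng(0))
            # proxy for acceptance: fraction of chains that moved at the end
            cfg2 = LangevinConfig(
                step_size=0.2, n_subiters=1, metropolis=True, preconditioner=precond
            )
            moved, _ = sample_langevin(like, y, approx, cfg2, init=out, seed=np.random.default_rng(1))
            return np.mean(np.any(moved != out, axis=1))

        p = gauss_newton_preconditioner(like, approx, np.zeros((1, 2)))
        assert acc_rate(p) > 0.4
        assert acc_rate(None) < acc_rate(p)
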