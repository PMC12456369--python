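"""Samplers for the prediction distribution.

At each annealing step the loop must draw m(0) from the prediction
distribution

    pi(m | y, m(t))  propto  pi_like(y | m) * N(m; m_aprx, C_aprx),

where (m_aprx, C_aprx) is the Gaussian denoising approximation. Three
samplers are provided:

* ``sample_langevin`` -- unadjusted (Euler-Maruyama) Langevin dynamics, or
  Metropolis-adjusted Langevin with a fixed preconditioner;
* ``sample_map`` -- the MAP point of the prediction distribution (closed
  form for masking likelihoods, quasi-Newton or batched Gauss-Newton
  otherwise);
* ``sample_rto`` -- randomize-then-optimize: perturb the data and the
  Gaussian mean by their own noise, then solve the perturbed MAP problem.
  In the linear-Gaussian case this is exact sampling from the prediction
  distribution.

All samplers are vectorized over chains: means, states and (optionally)
measurements carry a leading chain axis of size n.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.optimize

from .problems import LinearGaussianLikelihood, PoissonCTLikelihood

__all__ = [
    "DenoisingApprox",
    "LangevinConfig",
    "MapConfig",
    "sample_langevin",
    "sample_map",
    "sample_rto",
    "gauss_newton_preconditioner",
]


@dataclass
class DenoisingApprox:
    """Per-chain Gaussian approximation N(m; mean, C) of the denoising
    distribution. ``C`` is either isotropic (scalar ``beta``, C = beta^2 I,
    shared across chains) or a full per-chain SPD matrix of shape (n, D, D).
    """

    mean: np.ndarray  # (n, D)
    beta: Optional[float] = None
    cov: Optional[np.ndarray] = None  # (n, D, D)
    _chol: np.ndarray = field(default=None, repr=False)
    _prec: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.mean = np.atleast_2d(np.asarray(self.mean, dtype=float))
        if (self.beta is None) == (self.cov is None):
            raise ValueError("provide exactly one of beta or cov")
        if self.beta is not None and self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.cov is not None:
            self.cov = np.asarray(self.cov, dtype=float)
            if self.cov.ndim == 2:
                self.cov = np.broadcast_to(
                    self.cov, (self.mean.shape[0],) + self.cov.shape
                ).copy()

    @property
    def isotropic(self) -> bool:
        return self.beta is not None

    @property
    def dim(self) -> int:
        return self.mean.shape[1]

    def chol(self) -> np.ndarray:
        if self._chol is None:
            self._chol = np.linalg.cholesky(self.cov)
        return self._chol

    def prec(self) -> np.ndarray:
        if self._prec is None:
            self._prec = np.linalg.inv(self.cov)
            self._prec = 0.5 * (self._prec + np.swapaxes(self._prec, 1, 2))
        return self._prec

    def gauss_grad(self, m: np.ndarray) -> np.ndarray:
        """Gradient of log N(m; mean, C) wrt m, batched."""
        r = m - self.mean
        if self.isotropic:
            return -r / self.beta**2
        return -np.einsum("nij,nj->ni", self.prec(), r)

    def gauss_logpdf(self, m: np.ndarray) -> np.ndarray:
        """log N(m; mean, C) up to a per-chain constant (constant in m)."""
        r = m - self.mean
        if self.isotropic:
            return -0.5 * np.sum(r**2, axis=1) / self.beta**2
        return -0.5 * np.einsum("ni,nij,nj->n", r, self.prec(), r)

    def perturb_mean(self, rng: np.random.Generator) -> np.ndarray:
        """Draw m' ~ N(mean, C), per chain."""
        z = rng.standard_normal(self.mean.shape)
        if self.isotropic:
            return self.mean + self.beta * z
        return self.mean + np.einsum("nij,nj->ni", self.chol(), z)


@dataclass
class LangevinConfig:
    step_size: float = 5e-5
    n_subiters: int = 100
    metropolis: bool = False
    preconditioner: Optional[np.ndarray] = None  # (D, D) SPD, shared

    def __post_init__(self):
        if self.step_size <= 0 or self.n_subiters < 1:
            raise ValueError("step_size must be > 0 and n_subiters >= 1")


@dataclass
class MapConfig:
    method: str = "closed_form"  # closed_form | quasi_newton | gauss_newton
    max_iters: int = 40
    line_search: bool = True  # strong-Wolfe for quasi_newton, backtracking for GN
    gtol: float = 1e-5


def _target_grad(like, y, approx, m):
    return like.loglike_grad(m, y) + approx.gauss_grad(m)


def _target_logp(like, y, approx, m):
    return like.loglike(m, y) + approx.gauss_logpdf(m)


def sample_langevin(
    like,
    y: np.ndarray,
    approx: DenoisingApprox,
    cfg: LangevinConfig,
    init: Optional[np.ndarray] = None,
    seed=0,
):
    """Langevin dynamics targeting pi_like(y|m) N(m; m_aprx, C_aprx).

    Unadjusted update (drift coefficient eta, not eta/2):

        m <- m + eta * P grad log pi(m) + sqrt(2 eta) * P^{1/2} z

    With ``metropolis=True`` each proposal is accepted or rejected by the
    Metropolis-Hastings ratio of the preconditioned proposal kernel. Chains
    that become non-finite are frozen at their last finite state and flagged
    as diverged.

    Returns ``(values, diverged)`` with shapes (n, D) and (n,).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = np.array(approx.mean if init is None else np.atleast_2d(init), dtype=float)
    p = cfg.preconditioner
    lp_chol = None
    if p is not None:
        p = np.asarray(p, float)
        lp_chol = np.linalg.cholesky(p)
    with np.errstate(over="ignore", invalid="ignore"):
        return _langevin_loop(like, y, approx, cfg, m, rng, p, lp_chol)


def _langevin_loop(like, y, approx, cfg, m, rng, p, lp_chol):
    n, d = m.shape
    eta = cfg.step_size
    lp = lp_chol
    diverged = np.zeros(n, dtype=bool)
    if cfg.metropolis:
        logp = _target_logp(like, y, approx, m)
        g = _target_grad(like, y, approx, m)
    check_every = 16  # divergence scan interval; diverged chains are frozen
    safe = m.copy()
    sq2eta = np.sqrt(2 * eta)
    for it in range(cfg.n_subiters):
        z = rng.standard_normal((n, d))
        if not cfg.metropolis:
            g = _target_grad(like, y, approx, m)
            if p is None:
                m = m + eta * g + sq2eta * z
            else:
                m = m + eta * (g @ p.T) + sq2eta * (z @ lp.T)
            if (it + 1) % check_every == 0 or it + 1 == cfg.n_subiters:
                bad = ~np.all(np.isfinite(m), axis=1)
                if bad.any():
                    diverged |= bad
                    m[bad] = safe[bad]
                safe = m.copy()
        else:
            if p is None:
                drift = eta * g
                prop = m + drift + np.sqrt(2 * eta) * z
            else:
                drift = eta * (g @ p.T)
                prop = m + drift + np.sqrt(2 * eta) * (z @ lp.T)
            logp_prop = _target_logp(like, y, approx, prop)
            g_prop = _target_grad(like, y, approx, prop)
            if p is None:
                fwd = -np.sum((prop - m - eta * g) ** 2, axis=1) / (4 * eta)
                rev = -np.sum((m - prop - eta * g_prop) ** 2, axis=1) / (4 * eta)
            else:
                p_inv = np.linalg.inv(p)
                r_f = prop - m - eta * (g @ p.T)
                r_b = m - prop - eta * (g_prop @ p.T)
                fwd = -np.einsum("ni,ij,nj->n", r_f, p_inv, r_f) / (4 * eta)
                rev = -np.einsum("ni,ij,nj->n", r_b, p_inv, r_b) / (4 * eta)
            log_alpha = logp_prop - logp + rev - fwd
            ok = np.isfinite(log_alpha)
            accept = ok & (np.log(rng.uniform(size=n)) < log_alpha)
            m = np.where(accept[:, None], prop, m)
            logp = np.where(accept, logp_prop, logp)
            g = np.where(accept[:, None], g_prop, g)
            diverged |= ~np.all(np.isfinite(m), axis=1)
    return m, diverged


def _closed_form_map(like: LinearGaussianLikelihood, y, approx: DenoisingApprox):
    """MAP of the linear-Gaussian prediction distribution, batched.

    Isotropic C: solve (A^T A / tau^2 + I / beta^2) m = A^T y / tau^2 + mean / beta^2
    (a single shared SPD system). Full per-chain C: solve the equivalent
    (C A^T A / tau^2 + I) m = C A^T y / tau^2 + mean, avoiding explicit C^-1.
    """
    a, tau = like.a, like.tau
    n, d = approx.mean.shape
    y2 = np.broadcast_to(np.atleast_2d(y), (n, like.n_obs))
    aty = y2 @ a / tau**2  # (n, D)
    ata = a.T @ a / tau**2
    if approx.isotropic:
        if approx.beta == 0:
            return approx.mean.copy()
        h = ata + np.eye(d) / approx.beta**2
        rhs = aty + approx.mean / approx.beta**2
        return np.linalg.solve(h, rhs.T).T
    h = np.einsum("nij,jk->nik", approx.cov, ata) + np.eye(d)
    rhs = np.einsum("nij,nj->ni", approx.cov, aty) + approx.mean
    return np.linalg.solve(h, rhs[..., None])[..., 0]


def _gauss_newton_map(like, y, approx: DenoisingApprox, cfg: MapConfig):
    """Batched Gauss-Newton solver for the (negative log) prediction MAP.

    The Gauss-Newton Hessian J^T Sigma_z^-1 J + C^-1 is SPD for any
    likelihood with a differentiable forward map; for the Poisson likelihood
    with Sigma_z = diag(lambda) it coincides with the exact Hessian, and the
    objective is convex. Backtracking line search guards the nonconvex
    (phase retrieval) case.
    """
    m = approx.mean.copy()
    n, d = m.shape
    y_full = np.broadcast_to(np.atleast_2d(y), (n, like.n_obs))
    if approx.isotropic and approx.beta == 0:
        return m

    def neg_logp(mm, yy, sub):
        return -(like.loglike(mm, yy) + sub.gauss_logpdf(mm))

    def neg_grad(mm, yy, sub):
        return -(like.loglike_grad(mm, yy) + sub.gauss_grad(mm))

    active = np.arange(n)
    x = m
    sub = approx
    yy = y_full
    f = neg_logp(x, yy, sub)
    for _ in range(cfg.max_iters):
        g = neg_grad(x, yy, sub)
        still = np.linalg.norm(g, axis=1) > cfg.gtol
        if not np.all(still):  # retire converged chains from the working set
            m[active] = x
            active = active[still]
            if len(active) == 0:
                break
            x, g, f = x[still], g[still], f[still]
            yy = y_full[active]
            sub = _slice_approx(approx, active)
        na = len(active)
        j = like.jacobian(x)  # (na, K, D)
        if isinstance(like, PoissonCTLikelihood):
            w = 1.0 / np.maximum(like.forward(x), 1e-12)  # Sigma_z = diag(lambda)
        else:
            w = np.broadcast_to(1.0 / like.noise_cov_diag(yy[0]), (na, like.n_obs))
        h = np.einsum("nki,nk,nkj->nij", j, w, j)
        if approx.isotropic:
            h = h + (np.eye(d) / approx.beta**2)
        else:
            h = h + sub.prec()
        delta = np.linalg.solve(h, -g[..., None])[..., 0]
        slope = np.sum(g * delta, axis=1)  # < 0: GN direction is descent
        # Newton-decrement stop: further progress is below round-off of f
        tiny = -slope <= 1e-15 * (1.0 + np.abs(f))
        if np.any(tiny):
            keep = ~tiny
            m[active[tiny]] = x[tiny]
            active = active[keep]
            if len(active) == 0:
                break
            x, g, f, delta, slope = x[keep], g[keep], f[keep], delta[keep], slope[keep]
            yy = y_full[active]
            sub = _slice_approx(approx, active)
        if cfg.line_search:
            t = np.ones(len(active))
            cand = x + delta
            f_new = neg_logp(cand, yy, sub)
            need = f_new > f + 1e-4 * t * slope
            for _bt in range(15):
                if not np.any(need):
                    break
                t[need] *= 0.5
                cand[need] = x[need] + t[need, None] * delta[need]
                f_new[need] = neg_logp(cand[need], yy[need], _slice_approx(sub, need))
                need = need & (f_new > f + 1e-4 * t * slope)
        else:
            cand = x + delta
            f_new = neg_logp(cand, yy, sub)
        improved = f_new <= f
        x = np.where(improved[:, None], cand, x)
        f = np.where(improved, f_new, f)
        if not np.any(improved):
            break
    if len(active):
        m[active] = x
    return m


def _slice_approx(approx: DenoisingApprox, idx) -> DenoisingApprox:
    return DenoisingApprox(
        approx.mean[idx],
        beta=approx.beta,
        cov=None if approx.isotropic else approx.cov[idx],
    )


def _quasi_newton_map(like, y, approx: DenoisingApprox, cfg: MapConfig):
    """Per-chain scipy L-BFGS-B (Wolfe line search) from init = m_aprx."""
    n, d = approx.mean.shape
    y2 = np.broadcast_to(np.atleast_2d(y), (n, like.n_obs))
    out = np.empty_like(approx.mean)
    for i in range(n):
        sub = DenoisingApprox(
            approx.mean[i : i + 1],
            beta=approx.beta,
            cov=None if approx.isotropic else approx.cov[i : i + 1],
        )

        def fun(x):
            xm = x[None, :]
            return float(-_target_logp(like, y2[i : i + 1], sub, xm)[0])

        def jac(x):
            xm = x[None, :]
            return -_target_grad(like, y2[i : i + 1], sub, xm)[0]

        res = scipy.optimize.minimize(
            fun,
            approx.mean[i],
            jac=jac,
            method="L-BFGS-B",
            options={"maxiter": cfg.max_iters},
        )
        out[i] = res.x
    return out


def sample_map(like, y, approx: DenoisingApprox, cfg: MapConfig = MapConfig()):
    """MAP point of the prediction distribution, batched over chains."""
    if cfg.method == "closed_form":
        if not isinstance(like, LinearGaussianLikelihood):
            raise ValueError("closed_form MAP requires a linear-Gaussian likelihood")
        return _closed_form_map(like, y, approx)
    if cfg.method == "gauss_newton":
        return _gauss_newton_map(like, y, approx, cfg)
    if cfg.method == "quasi_newton":
        return _quasi_newton_map(like, y, approx, cfg)
    raise ValueError(f"unknown MAP method {cfg.method!r}")


def sample_rto(
    like, y, approx: DenoisingApprox, cfg: MapConfig = MapConfig(), seed=0
):
    """Randomize-then-optimize sample from the prediction distribution.

    Draws m'_aprx ~ N(m_aprx, C_aprx) and a noise-perturbed measurement
    (Gaussian likelihoods: y' ~ N(y, tau^2 I); Poisson likelihood: the
    variance-matched Gaussian surrogate y'_k ~ N(y_k, max(y_k, 1))), then
    returns the MAP of the perturbed problem. Exact in the linear-Gaussian
    case.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = approx.mean.shape[0]
    mean_pert = approx.perturb_mean(rng)
    y2 = np.broadcast_to(np.atleast_2d(y), (n, like.n_obs))
    noise_sd = np.sqrt(like.noise_cov_diag(np.asarray(y, float)))
    y_pert = y2 + noise_sd * rng.standard_normal(y2.shape)
    approx_pert = DenoisingApprox(
        mean_pert, beta=approx.beta, cov=None if approx.isotropic else approx.cov
    )
    return sample_map(like, y_pert, approx_pert, cfg)


def gauss_newton_preconditioner(
    like, approx: DenoisingApprox, anchor_points: np.ndarray, reg: float = 1e-8
) -> np.ndarray:
    """Average Gauss-Newton Hessian over anchor points, inverted.

    P^-1 = mean_a [ J(a)^T Sigma_z^-1 J(a) + C_aprx^-1 ]; the returned P is
    symmetrized and regularized by ``reg * I`` before inversion.
    """
    anchors = np.atleast_2d(np.asarray(anchor_points, float))
    d = anchors.shape[1]
    j = like.jacobian(anchors)  # (A, K, D)
    w = 1.0 / like.noise_cov_diag(np.zeros(like.n_obs))
    h = np.einsum("aki,k,akj->ij", j, w, j) / anchors.shape[0]
    if approx.isotropic:
        if approx.beta > 0:
            h += np.eye(d) / approx.beta**2
    else:
        h += approx.prec().mean(axis=0)
    h = 0.5 * (h + h.T) + reg * np.eye(d)
    p = np.linalg.inv(h)
    return 0.5 * (p + p.T)
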