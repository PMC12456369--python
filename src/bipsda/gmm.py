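"""Exact Gaussian-mixture machinery.

A Gaussian mixture serves three roles in this package: it is the prior of
every benchmark problem, the marginal of the variance-exploding noising
process applied to that prior (convolving each component with isotropic
Gaussian noise keeps the mixture form), and -- under a linear forward model
with additive Gaussian noise -- the exact posterior. All densities, scores,
score Jacobians and conditional updates are available in closed form, which
is what makes the benchmark suite analytically tractable.

All point-wise operations accept batched inputs: an ``m`` of shape ``(n, D)``
is treated as ``n`` independent evaluation points.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import logsumexp

__all__ = [
    "GaussianMixture",
    "PriorSpec",
    "build_prior",
    "gmm_sample",
    "gmm_logpdf",
    "noisy_marginal",
    "noisy_score",
    "noisy_score_jacobian",
    "linear_gaussian_posterior",
]


def _as_batch(m: np.ndarray, dim: int) -> tuple[np.ndarray, bool]:
    m = np.asarray(m, dtype=float)
    if m.ndim == 1:
        if m.shape[0] != dim:
            raise ValueError(f"point has dimension {m.shape[0]}, expected {dim}")
        return m[None, :], True
    if m.ndim != 2 or m.shape[1] != dim:
        raise ValueError(f"batch must have shape (n, {dim}), got {m.shape}")
    return m, False


@dataclass
class GaussianMixture:
    """A finite mixture of multivariate Gaussians.

    Parameters
    ----------
    weights
        Strictly positive component weights summing to one, shape ``(N,)``.
    means
        Component means, shape ``(N, D)``.
    covariances
        Symmetric positive-definite component covariances, shape ``(N, D, D)``.
    """

    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    _chol: list = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.covariances.ndim == 2:
            self.covariances = self.covariances[None, :, :]
        n = self.weights.shape[0]
        if self.means.shape[0] != n or self.covariances.shape[0] != n:
            raise ValueError("weights, means and covariances disagree on N")
        if not np.all(self.weights > 0):
            raise ValueError("weights must be strictly positive")
        if abs(self.weights.sum() - 1.0) > 1e-8:
            raise ValueError("weights must sum to 1")
        d = self.dim
        if self.covariances.shape[1:] != (d, d):
            raise ValueError("covariance shape mismatch")
        sym_err = np.max(np.abs(self.covariances - np.swapaxes(self.covariances, 1, 2)))
        if sym_err > 1e-8:
            raise ValueError("covariances must be symmetric")
        self._chol = []
        for k in range(n):
            try:
                self._chol.append(cho_factor(self.covariances[k], lower=True))
            except np.linalg.LinAlgError as exc:  # pragma: no cover
                raise ValueError(f"component {k} covariance is not SPD") from exc
        # cached per-component precisions and log-determinants: evaluation is
        # faster via precision products than repeated triangular solves
        self._prec = np.stack(
            [cho_solve(c, np.eye(d)) for c in self._chol]
        )
        self._prec = 0.5 * (self._prec + np.swapaxes(self._prec, 1, 2))
        self._logdet = np.array(
            [2.0 * np.sum(np.log(np.diag(c[0]))) for c in self._chol]
        )
        self._logw = np.log(self.weights)

    # -- basic descriptors -------------------------------------------------
    @property
    def n_components(self) -> int:
        return self.weights.shape[0]

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    def _component_logpdf(self, m: np.ndarray) -> np.ndarray:
        """Per-component Gaussian log-densities, shape (n, N)."""
        cst = self.dim * np.log(2.0 * np.pi)
        r = m[None, :, :] - self.means[:, None, :]  # (N, n, D)
        maha = np.einsum("knd,kde,kne->kn", r, self._prec, r)
        return (-0.5 * (cst + self._logdet[:, None] + maha)).T

    def logpdf(self, m: np.ndarray) -> np.ndarray | float:
        """Stable mixture log-density (log-sum-exp over components)."""
        mb, single = _as_batch(m, self.dim)
        lw = self._component_logpdf(mb) + self._logw
        if self.n_components == 1:
            lp = lw[:, 0]
        else:
            peak = lw.max(axis=1)
            lp = peak + np.log(np.sum(np.exp(lw - peak[:, None]), axis=1))
        return float(lp[0]) if single else lp

    def responsibilities(self, m: np.ndarray) -> np.ndarray:
        """Posterior component probabilities gamma_k(m), shape (n, N)."""
        mb, single = _as_batch(m, self.dim)
        lw = self._component_logpdf(mb) + self._logw
        lw -= lw.max(axis=1, keepdims=True)
        g = np.exp(lw)
        g /= g.sum(axis=1, keepdims=True)
        return g[0] if single else g

    def score(self, m: np.ndarray) -> np.ndarray:
        """Gradient of the mixture log-density at ``m``."""
        mb, single = _as_batch(m, self.dim)
        r = mb[None, :, :] - self.means[:, None, :]  # (N, n, D)
        g_all = -np.einsum("kde,kne->knd", self._prec, r)  # (N, n, D)
        if self.n_components == 1:
            s = g_all[0]
        else:
            gamma = self.responsibilities(mb)  # (n, N)
            s = np.einsum("nk,knd->nd", gamma, g_all)
        return s[0] if single else s

    def score_jacobian(self, m: np.ndarray) -> np.ndarray:
        """Jacobian of :meth:`score`; symmetric since the score is a gradient.

        For responsibilities gamma_k and per-component gradients
        g_k = -P_k (m - mu_k) with precision P_k, the Jacobian is

            J = sum_k gamma_k (g_k g_k^T - P_k) - s s^T,   s = sum_k gamma_k g_k.
        """
        mb, single = _as_batch(m, self.dim)
        n, d = mb.shape
        gamma = self.responsibilities(mb).reshape(n, self.n_components)
        r = mb[None, :, :] - self.means[:, None, :]
        g_all = -np.einsum("kde,kne->knd", self._prec, r)  # (N, n, D)
        s = np.einsum("nk,knd->nd", gamma, g_all)
        j = np.einsum("nk,knd,kne->nde", gamma, g_all, g_all)
        j -= np.einsum("nk,kde->nde", gamma, self._prec)
        j -= s[:, :, None] * s[:, None, :]
        j = 0.5 * (j + np.swapaxes(j, 1, 2))
        return j[0] if single else j

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Ancestral sampling: component ~ Categorical(weights), then Gaussian."""
        if n < 1:
            raise ValueError("n must be >= 1")
        comp = rng.choice(self.n_components, size=n, p=self.weights)
        z = rng.standard_normal((n, self.dim))
        out = np.empty((n, self.dim))
        for k in range(self.n_components):
            idx = comp == k
            if not np.any(idx):
                continue
            c, _ = self._chol[k]
            l_k = np.tril(c)
            out[idx] = self.means[k] + z[idx] @ l_k.T
        return out

    def mean(self) -> np.ndarray:
        return self.weights @ self.means

    def cov(self) -> np.ndarray:
        mu = self.mean()
        c = np.einsum("k,kij->ij", self.weights, self.covariances)
        dm = self.means - mu
        c += np.einsum("k,ki,kj->ij", self.weights, dm, dm)
        return c

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "covariances": self.covariances.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GaussianMixture":
        return cls(
            np.asarray(d["weights"]),
            np.asarray(d["means"]),
            np.asarray(d["covariances"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "GaussianMixture":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class PriorSpec:
    """Construction recipe for the benchmark prior.

    The default instance is the ten-dimensional three-component mixture used
    by every benchmark study: component 1 at ``-5*1`` with identity
    covariance, component 2 at the origin with diagonal covariance whose
    entries are linearly spaced on [1, 2], component 3 at ``+5*1`` sharing
    component 2's eigenvalue spectrum but with seeded random orthonormal
    eigenvectors, and weights (0.4, 0.3, 0.3).
    """

    dim: int = 10
    weights: tuple = (0.4, 0.3, 0.3)
    seed: int = 0

    def __post_init__(self):
        if not isinstance(self.seed, (int, np.integer)):
            raise TypeError("seed must be an integer")


def build_prior(spec: PriorSpec = PriorSpec()) -> GaussianMixture:
    """Build the three-component benchmark prior from its spec.

    Component 3's eigenvectors are the orthogonal factor of a QR
    decomposition of a seeded standard-Gaussian matrix, which makes the
    "randomly chosen eigenvectors" reproducible given the seed.
    """
    d = spec.dim
    rng = np.random.default_rng(spec.seed)
    eigvals = np.linspace(1.0, 2.0, d)
    q, r = np.linalg.qr(rng.standard_normal((d, d)))
    q *= np.sign(np.diag(r))  # fix the sign convention so Q is unique given seed
    means = np.stack([np.full(d, -5.0), np.zeros(d), np.full(d, 5.0)])
    covs = np.stack([np.eye(d), np.diag(eigvals), (q * eigvals) @ q.T])
    covs[2] = 0.5 * (covs[2] + covs[2].T)
    return GaussianMixture(np.asarray(spec.weights, float), means, covs)


# -- functional wrappers (batched semantics identical to the methods) -------


def gmm_sample(gmm: GaussianMixture, n: int, seed) -> np.ndarray:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return gmm.sample(n, rng)


def gmm_logpdf(gmm: GaussianMixture, m: np.ndarray):
    return gmm.logpdf(m)


def noisy_marginal(gmm: GaussianMixture, sigma: float) -> GaussianMixture:
    """Marginal of m + sigma*z under the mixture: each Sigma_k -> Sigma_k + sigma^2 I."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return gmm
    covs = gmm.covariances + sigma**2 * np.eye(gmm.dim)
    return GaussianMixture(gmm.weights, gmm.means, covs)


def noisy_score(gmm: GaussianMixture, m: np.ndarray, sigma: float) -> np.ndarray:
    return noisy_marginal(gmm, sigma).score(m)


def noisy_score_jacobian(gmm: GaussianMixture, m: np.ndarray, sigma: float) -> np.ndarray:
    return noisy_marginal(gmm, sigma).score_jacobian(m)


def linear_gaussian_posterior(
    gmm: GaussianMixture, a: np.ndarray, tau: float, y: np.ndarray
) -> GaussianMixture:
    """Exact posterior mixture under y = A m + N(0, tau^2 I).

    Component k of the posterior is the standard conjugate update

        Sigma'_k = (Sigma_k^-1 + A^T A / tau^2)^-1
        mu'_k    = Sigma'_k (Sigma_k^-1 mu_k + A^T y / tau^2)

    with weight proportional to w_k N(y; A mu_k, A Sigma_k A^T + tau^2 I),
    renormalized in log space.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    a = np.asarray(a, float)
    y = np.asarray(y, float)
    k_obs, d = a.shape
    if d != gmm.dim or y.shape != (k_obs,):
        raise ValueError("shape mismatch between A, y and the mixture")
    ata = a.T @ a / tau**2
    aty = a.T @ y / tau**2
    new_means = np.empty_like(gmm.means)
    new_covs = np.empty_like(gmm.covariances)
    logw = np.empty(gmm.n_components)
    cst = k_obs * np.log(2.0 * np.pi)
    for k in range(gmm.n_components):
        sig = gmm.covariances[k]
        prec = np.linalg.inv(sig)
        post_cov = np.linalg.inv(prec + ata)
        post_cov = 0.5 * (post_cov + post_cov.T)
        new_covs[k] = post_cov
        new_means[k] = post_cov @ (prec @ gmm.means[k] + aty)
        evid_cov = a @ sig @ a.T + tau**2 * np.eye(k_obs)
        c, lower = cho_factor(evid_cov, lower=True)
        r = y - a @ gmm.means[k]
        maha = r @ cho_solve((c, lower), r)
        logdet = 2.0 * np.sum(np.log(np.diag(c)))
        logw[k] = np.log(gmm.weights[k]) - 0.5 * (cst + logdet + maha)
    logw -= logsumexp(logw)
    return GaussianMixture(np.exp(logw), new_means, new_covs)
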