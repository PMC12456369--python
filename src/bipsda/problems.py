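"""The four stylized inverse problems.

Each study pairs the shared ten-dimensional Gaussian-mixture prior with a
different likelihood:

* ``inpaint_low`` / ``inpaint_high`` -- a binary subsampling (masking)
  forward model ``f(m) = A m`` with ``A`` an 8-of-10 coordinate selector and
  additive white Gaussian noise of standard deviation ``tau = 0.1`` or ``5``.
* ``xray`` -- a Beer-Lambert style attenuation model ``f(m) = I0 exp(-C m)``
  with Poisson counting noise, ``C`` a seeded 15x10 matrix with entries
  uniform on [0.01, 0.05] and source intensity ``I0 = 1000``.
* ``phase`` -- a squared linear map ``f(m) = (B m)^2`` with ``B`` a seeded
  5x10 standard-normal matrix and Gaussian noise ``tau = 25``.

Likelihood objects expose batched ``forward``, ``loglike`` and
``loglike_grad`` (additive constants are dropped, consistently so), plus the
forward-map Jacobian used by Gauss-Newton machinery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

__all__ = [
    "LinearGaussianLikelihood",
    "PhaseRetrievalLikelihood",
    "PoissonCTLikelihood",
    "Measurement",
    "STUDIES",
    "make_problem",
    "simulate_measurement",
    "loglike",
    "loglike_grad",
    "report_snr",
]

STUDIES = ("inpaint_low", "inpaint_high", "xray", "phase")


def _batch(m: np.ndarray) -> tuple[np.ndarray, bool]:
    m = np.asarray(m, dtype=float)
    if m.ndim == 1:
        return m[None, :], True
    return m, False


@dataclass
class LinearGaussianLikelihood:
    """Masking forward model A m with white Gaussian noise N(0, tau^2 I)."""

    a: np.ndarray
    tau: float

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=float)
        if self.tau <= 0:
            raise ValueError("tau must be > 0")
        row_sums = self.a.sum(axis=1)
        binary = np.all((self.a == 0) | (self.a == 1))
        if binary and np.any(self.a != 0) and not (
            np.all(row_sums == 1) and np.all(self.a.sum(axis=0) <= 1)
        ):  # the all-zero (no-data) operator is allowed for limiting cases
            raise ValueError("binary mask rows must each select one distinct coordinate")

    @property
    def dim(self) -> int:
        return self.a.shape[1]

    @property
    def n_obs(self) -> int:
        return self.a.shape[0]

    def _mask_indices(self):
        # fast path when A is a pure coordinate selector
        if not hasattr(self, "_mask_idx"):
            binary = np.all((self.a == 0) | (self.a == 1))
            if binary and np.all(self.a.sum(axis=1) == 1):
                self._mask_idx = np.argmax(self.a, axis=1)
            else:
                self._mask_idx = None
        return self._mask_idx

    def forward(self, m):
        mb, single = _batch(m)
        idx = self._mask_indices()
        f = mb[:, idx] if idx is not None else mb @ self.a.T
        return f[0] if single else f

    def jacobian(self, m):
        mb, single = _batch(m)
        j = np.broadcast_to(self.a, (mb.shape[0],) + self.a.shape)
        return j[0] if single else j

    def noise_cov_diag(self, y):
        return np.full(self.n_obs, self.tau**2)

    def loglike(self, m, y):
        mb, single = _batch(m)
        idx = self._mask_indices()
        r = (mb[:, idx] if idx is not None else mb @ self.a.T) - y
        val = -0.5 * np.sum(r**2, axis=1) / self.tau**2
        return float(val[0]) if single else val

    def loglike_grad(self, m, y):
        mb, single = _batch(m)
        idx = self._mask_indices()
        if idx is not None:
            g = np.zeros_like(mb)
            g[:, idx] = (y - mb[:, idx]) / self.tau**2
        else:
            g = (y - mb @ self.a.T) @ self.a / self.tau**2
        return g[0] if single else g


@dataclass
class PhaseRetrievalLikelihood:
    """Squared linear forward model (B m)^2 with Gaussian noise N(0, tau^2 I).

    f(-m) = f(m) exactly, so the likelihood is invariant under point
    reflection — samplers may exploit this (``sign_symmetric``).
    """

    b: np.ndarray
    tau: float
    sign_symmetric = True

    def __post_init__(self):
        self.b = np.asarray(self.b, dtype=float)
        if self.tau <= 0:
            raise ValueError("tau must be > 0")

    @property
    def dim(self) -> int:
        return self.b.shape[1]

    @property
    def n_obs(self) -> int:
        return self.b.shape[0]

    def forward(self, m):
        mb, single = _batch(m)
        f = (mb @ self.b.T) ** 2
        return f[0] if single else f

    def jacobian(self, m):
        """J = 2 diag(B m) B, batched to shape (n, K, D)."""
        mb, single = _batch(m)
        bm = mb @ self.b.T  # (n, K)
        j = 2.0 * bm[:, :, None] * self.b[None, :, :]
        return j[0] if single else j

    def noise_cov_diag(self, y):
        return np.full(self.n_obs, self.tau**2)

    def loglike(self, m, y):
        mb, single = _batch(m)
        r = (mb @ self.b.T) ** 2 - y
        val = -0.5 * np.sum(r**2, axis=1) / self.tau**2
        return float(val[0]) if single else val

    def loglike_grad(self, m, y):
        mb, single = _batch(m)
        bm = mb @ self.b.T
        r = y - bm**2
        g = (2.0 * r * bm) @ self.b / self.tau**2
        return g[0] if single else g


@dataclass
class PoissonCTLikelihood:
    """Attenuation forward model I0*exp(-C m) with per-ray Poisson counts.

    The log-factorial constant of the Poisson pmf is dropped: it cancels in
    every posterior and sampler. The log-likelihood formula
    sum_k [y_k log lam_k - lam_k] remains valid (and smooth, convex in m) for
    real-valued y, which is what the Gaussian-surrogate RTO perturbation
    produces.
    """

    c: np.ndarray
    i0: float = 1000.0
    _EXP_CAP = 700.0  # saturate exp argument; keeps lam finite for wild m

    def __post_init__(self):
        self.c = np.asarray(self.c, dtype=float)
        if self.i0 <= 0:
            raise ValueError("I0 must be > 0")

    @property
    def dim(self) -> int:
        return self.c.shape[1]

    @property
    def n_obs(self) -> int:
        return self.c.shape[0]

    def forward(self, m):
        mb, single = _batch(m)
        lam = self.i0 * np.exp(np.clip(-(mb @ self.c.T), -self._EXP_CAP, self._EXP_CAP))
        return lam[0] if single else lam

    def jacobian(self, m):
        mb, single = _batch(m)
        lam = self.forward(mb)  # (n, K)
        j = -lam[:, :, None] * self.c[None, :, :]
        return j[0] if single else j

    def noise_cov_diag(self, y):
        # Poisson variance equals the mean; the observed counts are the
        # variance-matched Gaussian surrogate used by RTO.
        return np.maximum(np.asarray(y, float), 1.0)

    def loglike(self, m, y):
        mb, single = _batch(m)
        cm = np.clip(mb @ self.c.T, -self._EXP_CAP, self._EXP_CAP)
        lam = self.i0 * np.exp(-cm)
        val = np.sum(y * (np.log(self.i0) - cm) - lam, axis=1)
        return float(val[0]) if single else val

    def loglike_grad(self, m, y):
        mb, single = _batch(m)
        lam = self.forward(mb)
        g = (lam - y) @ self.c
        return g[0] if single else g


@dataclass
class Measurement:
    """A simulated measurement together with its generating ground truth."""

    y: np.ndarray
    m_true: np.ndarray
    seed: int | None = None


def make_problem(study: str, seed: int = 0):
    """Construct the likelihood object for one of the four studies.

    The operators are pure functions of the seed; the constants
    (tau = 0.1 / 5 / 25, I0 = 1000) are the study definitions.
    """
    rng = np.random.default_rng(seed)
    if study == "inpaint_low" or study == "inpaint_high":
        a = np.zeros((8, 10))
        a[np.arange(8), np.arange(8)] = 1.0  # observe coordinates 1..8
        return LinearGaussianLikelihood(a, tau=0.1 if study == "inpaint_low" else 5.0)
    if study == "xray":
        c = rng.uniform(0.01, 0.05, size=(15, 10))
        return PoissonCTLikelihood(c, i0=1000.0)
    if study == "phase":
        b = rng.standard_normal((5, 10))
        return PhaseRetrievalLikelihood(b, tau=25.0)
    raise ValueError(f"unknown study {study!r}; expected one of {STUDIES}")


def simulate_measurement(like, m, seed) -> Measurement:
    """Draw y from the likelihood's noise model at parameter m."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    m = np.asarray(m, dtype=float)
    f = like.forward(m)
    if isinstance(like, PoissonCTLikelihood):
        y = rng.poisson(f).astype(float)
    else:
        y = f + like.tau * rng.standard_normal(f.shape)
    return Measurement(y=y, m_true=m, seed=None if isinstance(seed, np.random.Generator) else seed)


def loglike(like, m, y):
    return like.loglike(m, y)


def loglike_grad(like, m, y):
    return like.loglike_grad(m, y)


def report_snr(like, prior, n_mc: int = 100_000, seed: int = 0) -> float:
    """Monte Carlo signal-to-noise ratio in dB under the prior.

    One possible convention: 10*log10( E||f(m)||^2 / E||noise||^2 ) with m
    drawn from the prior. Informational only -- the published SNR figures do
    not state their convention, so this number is reported, never gated.
    """
    if n_mc < 1000:
        raise ValueError("n_mc must be >= 1000")
    rng = np.random.default_rng(seed)
    m = prior.sample(n_mc, rng)
    f = like.forward(m)
    sig = np.mean(np.sum(f**2, axis=1))
    if isinstance(like, PoissonCTLikelihood):
        noise = np.mean(np.sum(f, axis=1))  # Poisson variance = mean
    else:
        noise = like.n_obs * like.tau**2
    if sig == 0:
        return -np.inf
    return 10.0 * np.log10(sig / noise)


def problem_to_json(like, extra: dict | None = None) -> str:
    d = {"type": type(like).__name__}
    if isinstance(like, LinearGaussianLikelihood):
        d.update(a=like.a.tolist(), tau=like.tau)
    elif isinstance(like, PhaseRetrievalLikelihood):
        d.update(b=like.b.tolist(), tau=like.tau)
    elif isinstance(like, PoissonCTLikelihood):
        d.update(c=like.c.tolist(), i0=like.i0)
    else:
        raise TypeError(f"cannot serialize {type(like)}")
    if extra:
        d.update(extra)
    return json.dumps(d)


def problem_from_json(s: str):
    d = json.loads(s)
    t = d["type"]
    if t == "LinearGaussianLikelihood":
        return LinearGaussianLikelihood(np.asarray(d["a"]), d["tau"])
    if t == "PhaseRetrievalLikelihood":
        return PhaseRetrievalLikelihood(np.asarray(d["b"]), d["tau"])
    if t == "PoissonCTLikelihood":
        return PoissonCTLikelihood(np.asarray(d["c"]), d["i0"])
    raise ValueError(f"unknown problem type {t!r}")
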