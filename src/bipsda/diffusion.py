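"""Variance-exploding diffusion machinery.

The noising process is m(t) = m(0) + sigma(t) z with sigma(0) = 0 and, by
default, sigma(t) = t on [0, T], T = 10. This module provides the annealing
time grid, Tweedie's formula for the conditional mean of the denoising
distribution, its generalized form for the conditional covariance, and an
Euler solver for the probability-flow ODE used by the 'ODE' denoising
variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "NoiseSchedule",
    "TimeGrid",
    "make_time_grid",
    "AnalyticScore",
    "tweedie_mean",
    "tweedie_cov",
    "pf_ode_denoise",
]


@dataclass(frozen=True)
class NoiseSchedule:
    """Noise level sigma(t) and its derivative; default sigma(t) = t."""

    sigma: Callable[[float], float] = lambda t: t
    sigma_dot: Callable[[float], float] = lambda t: 1.0
    T: float = 10.0
    t_min: float = 0.01

    def __post_init__(self):
        if abs(self.sigma(0.0)) > 1e-12:
            raise ValueError("schedule must satisfy sigma(0) = 0")


@dataclass(frozen=True)
class TimeGrid:
    """Strictly decreasing annealing times t_N > ... > t_1 > t_0 = 0."""

    times: np.ndarray  # descending, length N+1

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        if np.any(np.diff(t) >= 0):
            raise ValueError("times must be strictly decreasing")
        if t[-1] != 0.0:
            raise ValueError("grid must end at t = 0")
        object.__setattr__(self, "times", t)

    @property
    def n_steps(self) -> int:
        return len(self.times) - 1


def make_time_grid(
    n_steps: int = 200, T: float = 10.0, rho: float = 7.0, t_min: float = 0.01
) -> TimeGrid:
    """Polynomial interpolation of annealing times between T and 0.

    Times interpolate linearly in the rho-th-root domain,

        t_i = ( (i/N) * T^(1/rho) + (1 - i/N) * t_min^(1/rho) )^rho,  i = N..1,

    with t_0 = 0 — the discretization convention of Karras-style diffusion
    samplers, which spaces steps densely near the noise floor while keeping
    good coverage of intermediate noise levels. For rho = 1 and t_min = 0
    this is the uniform grid T*i/N. The positive default floor keeps the
    smallest nonzero noise level at a scale where the prediction samplers
    remain numerically stable at their published step sizes (it mirrors the
    training-time noise floor).
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if T <= 0:
        raise ValueError("T must be > 0")
    if rho < 1:
        raise ValueError("rho must be >= 1")
    if not 0 <= t_min < T:
        raise ValueError("t_min must lie in [0, T)")
    frac = np.arange(n_steps, 0, -1, dtype=float) / n_steps
    t = (frac * T ** (1.0 / rho) + (1.0 - frac) * t_min ** (1.0 / rho)) ** rho
    t[0] = T  # guard the root-then-power round trip
    return TimeGrid(np.concatenate([t, [0.0]]))


class AnalyticScore:
    """Exact noisy-prior score of a Gaussian-mixture prior.

    Callable as ``score(m, sigma)``; also exposes the score Jacobian, which
    the Tweedie-Correlated denoising approximation needs.
    """

    analytic = True

    def __init__(self, prior):
        self.prior = prior

    def __call__(self, m: np.ndarray, sigma: float) -> np.ndarray:
        from .gmm import noisy_score

        return noisy_score(self.prior, m, sigma)

    def jacobian(self, m: np.ndarray, sigma: float) -> np.ndarray:
        from .gmm import noisy_score_jacobian

        return noisy_score_jacobian(self.prior, m, sigma)


def tweedie_mean(score, m: np.ndarray, sigma: float) -> np.ndarray:
    """Tweedie's formula: E[m(0) | m(t)] = m(t) + sigma^2 * score(m(t), sigma)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    m = np.asarray(m, dtype=float)
    if sigma == 0:
        return m.copy()
    return m + sigma**2 * score(m, sigma)


def tweedie_cov(
    score_jacobian, m: np.ndarray, sigma: float, floor: float = 1e-10
) -> np.ndarray:
    """Generalized Tweedie formula for the denoising covariance.

    Cov[m(0) | m(t)] = sigma^2 (I + sigma^2 * J(m(t), sigma)) with J the
    noisy-score Jacobian. The result is symmetrized and its eigenvalues are
    clipped at a small positive floor; with an exact score the matrix is PSD
    by construction and clipping only guards round-off.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    m = np.asarray(m, dtype=float)
    single = m.ndim == 1
    d = m.shape[-1]
    if sigma == 0:
        z = np.zeros((d, d)) if single else np.zeros((m.shape[0], d, d))
        return z
    j = score_jacobian(m, sigma)
    c = sigma**2 * (np.eye(d) + sigma**2 * j)
    c = 0.5 * (c + np.swapaxes(c, -1, -2))
    w, v = np.linalg.eigh(c)
    if np.any(w < floor):
        w = np.maximum(w, floor)
        c = (v * w[..., None, :]) @ np.swapaxes(v, -1, -2)
        c = 0.5 * (c + np.swapaxes(c, -1, -2))
    return c


def pf_ode_denoise(
    score,
    m: np.ndarray,
    t: float,
    n_steps: int = 5,
    schedule: NoiseSchedule = NoiseSchedule(),
    rho: float = 7.0,
) -> np.ndarray:
    """Integrate the probability-flow ODE from time t down to 0.

    The ODE dm = -sigma'(s) sigma(s) score(m, sigma(s)) ds is discretized by
    the Euler method on an internal sub-grid with the same polynomial
    interpolation as the outer annealing grid (between t and a small floor,
    with a final step to 0), so steps concentrate where the flow stiffens
    (sigma -> 0). With a single step the update is
    m + sigma(t)^2 * score(m, sigma(t)): Tweedie's formula (for sigma(t)=t).
    """
    if t <= 0:
        raise ValueError("t must be > 0")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    m = np.asarray(m, dtype=float).copy()
    if n_steps == 1:
        sub = np.array([t, 0.0])
    else:
        floor = min(schedule.t_min, t / 10.0)
        frac = np.arange(n_steps - 1, -1, -1, dtype=float) / (n_steps - 1)
        sub = (frac * t ** (1.0 / rho) + (1.0 - frac) * floor ** (1.0 / rho)) ** rho
        sub = np.concatenate([sub, [0.0]])
    for j in range(n_steps):
        s = sub[j]
        ds = sub[j + 1] - s  # negative
        drift = -schedule.sigma_dot(s) * schedule.sigma(s) * score(m, schedule.sigma(s))
        m = m + ds * drift
        if not np.all(np.isfinite(m)):
            raise FloatingPointError("probability-flow ODE state diverged")
    return m
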