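"""The decoupled-noise-annealing outer loop.

Starting from m(T) ~ N(0, sigma(T)^2 I), each of the N_A iterations
(i) builds a Gaussian approximation of the denoising distribution
pi(m(0) | m(t_i)) from the prior score (ODE / Tweedie-Uncorrelated /
Tweedie-Correlated), (ii) samples the prediction distribution
pi_like(y|m) N(m; m_aprx, C_aprx) with a Langevin / MAP / RTO sampler, and
(iii) re-corrupts the prediction to the next, lower noise level
m(t_{i-1}) = m(0) + sigma(t_{i-1}) z. The grid ends at t_0 = 0, so the final
iteration is prediction-only. Nine variants arise from crossing the three
approximations with the three samplers; Lang-ODE and MAP-TU recover the
DAPS and DiffPIR algorithms respectively.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .diffusion import (
    NoiseSchedule,
    TimeGrid,
    make_time_grid,
    pf_ode_denoise,
    tweedie_cov,
    tweedie_mean,
)
from .samplers import (
    DenoisingApprox,
    LangevinConfig,
    MapConfig,
    gauss_newton_preconditioner,
    sample_langevin,
    sample_map,
    sample_rto,
)

__all__ = ["BIPSDAConfig", "SampleBatch", "approx_denoising", "bipsda_sample"]

_APPROXES = ("ode", "tu", "tc")
_SAMPLERS = ("lang", "map", "rto")


@dataclass
class BIPSDAConfig:
    """Configuration of one annealing run (one variant on one problem)."""

    approx: str = "tu"
    sampler: str = "rto"
    n_chains: int = 10_000
    n_steps: int = 200
    schedule: NoiseSchedule = field(default_factory=NoiseSchedule)
    rho: float = 7.0
    ode_steps: int = 5
    langevin: LangevinConfig = field(default_factory=LangevinConfig)
    map: MapConfig = field(default_factory=MapConfig)
    precondition: bool = False  # refresh a Gauss-Newton Langevin preconditioner
    n_precond_anchors: int = 8
    force_learned_tc: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.approx not in _APPROXES:
            raise ValueError(f"approx must be one of {_APPROXES}")
        if self.sampler not in _SAMPLERS:
            raise ValueError(f"sampler must be one of {_SAMPLERS}")

    @property
    def variant(self) -> str:
        return f"{self.sampler}-{self.approx}"


@dataclass
class SampleBatch:
    """n x D posterior draws plus provenance."""

    values: np.ndarray
    diverged: np.ndarray
    variant: str = ""
    seed: Optional[int] = None

    @property
    def clean(self) -> np.ndarray:
        """Draws from non-diverged chains only."""
        return self.values[~self.diverged]

    @property
    def n_diverged(self) -> int:
        return int(self.diverged.sum())


def approx_denoising(
    approx: str,
    score,
    m: np.ndarray,
    t: float,
    schedule: NoiseSchedule = NoiseSchedule(),
    ode_steps: int = 5,
    rho: float = 7.0,
    force_learned_tc: bool = False,
) -> DenoisingApprox:
    """Gaussian approximation of the denoising distribution at time t.

    * ``ode``: mean from the probability-flow ODE, C = sigma(t)^2 I;
    * ``tu``: mean from Tweedie's formula, C = sigma(t)^2 I;
    * ``tc``: Tweedie mean plus the generalized-Tweedie covariance
      sigma^2 (I + sigma^2 J). Refused for learned scores unless forced: the
      Jacobian of a learned score is not a reliable covariance estimate.
    """
    sigma = schedule.sigma(t)
    m = np.atleast_2d(np.asarray(m, float))
    if approx == "ode":
        mean = pf_ode_denoise(score, m, t, n_steps=ode_steps, schedule=schedule, rho=rho)
        return DenoisingApprox(mean, beta=sigma)
    if approx == "tu":
        return DenoisingApprox(tweedie_mean(score, m, sigma), beta=sigma)
    if approx == "tc":
        if not getattr(score, "analytic", False) and not force_learned_tc:
            raise ValueError(
                "Tweedie-Correlated approximation requires an analytic score "
                "(pass force_learned_tc=True to override)"
            )
        mean = tweedie_mean(score, m, sigma)
        cov = tweedie_cov(score.jacobian, m, sigma)
        return DenoisingApprox(mean, cov=cov)
    raise ValueError(f"unknown approximation {approx!r}")


def bipsda_sample(like, score, y: np.ndarray, cfg: BIPSDAConfig) -> SampleBatch:
    """Run the annealing loop and return the terminal sample batch.

    Chains are vectorized; each chain evolves independently. Chains that
    produce non-finite values at any point are frozen and flagged; a run
    with more than 1% diverged chains emits a RuntimeWarning.
    """
    rng = np.random.default_rng(cfg.seed)
    grid: TimeGrid = make_time_grid(
        cfg.n_steps, cfg.schedule.T, cfg.rho, cfg.schedule.t_min
    )
    times = grid.times  # descending, t_N .. t_0 = 0
    d = like.dim
    sigma_top = cfg.schedule.sigma(times[0])
    m = sigma_top * rng.standard_normal((cfg.n_chains, d))
    diverged = np.zeros(cfg.n_chains, dtype=bool)

    for i in range(cfg.n_steps):
        t_i, t_next = times[i], times[i + 1]
        approx = approx_denoising(
            cfg.approx,
            score,
            m,
            t_i,
            schedule=cfg.schedule,
            ode_steps=cfg.ode_steps,
            rho=cfg.rho,
            force_learned_tc=cfg.force_learned_tc,
        )
        if cfg.sampler == "lang":
            lcfg = cfg.langevin
            if cfg.precondition:
                anchors = approx.mean[
                    rng.choice(
                        cfg.n_chains,
                        size=min(cfg.n_precond_anchors, cfg.n_chains),
                        replace=False,
                    )
                ]
                lcfg = replace(
                    lcfg, preconditioner=gauss_newton_preconditioner(like, approx, anchors)
                )
            m0, div = sample_langevin(like, y, approx, lcfg, seed=rng)
            diverged |= div
        elif cfg.sampler == "map":
            m0 = sample_map(like, y, approx, cfg.map)
        else:
            m0 = sample_rto(like, y, approx, cfg.map, seed=rng)
        bad = ~np.all(np.isfinite(m0), axis=1)
        diverged |= bad
        m0 = np.where(bad[:, None], m, m0)
        sigma_next = cfg.schedule.sigma(t_next)
        if sigma_next > 0:
            m = m0 + sigma_next * rng.standard_normal(m0.shape)
        else:
            m = m0
    if diverged.mean() > 0.01:
        import warnings

        warnings.warn(
            f"{diverged.sum()} of {cfg.n_chains} chains diverged", RuntimeWarning
        )
    return SampleBatch(values=m, diverged=diverged, variant=cfg.variant, seed=cfg.seed)
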