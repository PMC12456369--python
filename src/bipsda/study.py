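"""Study orchestration: run annealing variants against reference posteriors
over repeated measurement trials and aggregate the four metrics.

A study fixes one problem instance (operator + noise constants + prior) and
repeats over i.i.d. trials: draw a ground truth from the prior, simulate a
measurement, draw reference posterior samples (exact for the masking
studies, gated MCMC otherwise) and one batch per requested variant, then
score each batch against the reference with mean error, variance error,
CMD and MMD. Aggregates are means and empirical interdecile (10th-90th
percentile) ranges across trials. A "reference" row compares two
independent reference batches and gives the resolution floor of the
protocol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .annealing import BIPSDAConfig, bipsda_sample
from .diffusion import AnalyticScore
from .gmm import PriorSpec, build_prior
from .metrics import (
    MMDConfig,
    _central_moments,
    mean_error,
    mmd,
    variance_error,
)
from .problems import make_problem, simulate_measurement
from .reference import (
    ComponentwiseConfig,
    ReferenceConvergenceError,
    componentwise_reference,
    exact_reference,
    mcmc_reference,
)
from .samplers import LangevinConfig, MapConfig

__all__ = ["StudyConfig", "MetricsReport", "run_study", "default_variant_config"]

ALL_VARIANTS = (
    "lang-tu", "lang-tc", "lang-ode",
    "map-tu", "map-tc", "map-ode",
    "rto-tu", "rto-tc", "rto-ode",
)


def default_variant_config(study: str, variant: str, n_chains: int) -> BIPSDAConfig:
    """Published per-study sampler settings for one annealing variant.

    Masking studies: Langevin step 5e-5 with 100 subiterations, closed-form
    MAP. X-ray: 1000 Langevin subiterations, Gauss-Newton MAP solves (40
    iterations with line search). Phase retrieval: Metropolis-adjusted,
    preconditioned Langevin with step 0.2 and 1000 subiterations,
    Gauss-Newton MAP solves.
    """
    sampler, approx = variant.split("-")
    if study in ("inpaint_low", "inpaint_high"):
        lang = LangevinConfig(step_size=5e-5, n_subiters=100)
        map_cfg = MapConfig(method="closed_form")
        precond = False
    elif study == "xray":
        lang = LangevinConfig(step_size=5e-5, n_subiters=1000)
        map_cfg = MapConfig(method="gauss_newton", max_iters=40)
        precond = False
    elif study == "phase":
        lang = LangevinConfig(step_size=0.2, n_subiters=1000, metropolis=True)
        map_cfg = MapConfig(method="gauss_newton", max_iters=40)
        precond = True
    else:
        raise ValueError(f"unknown study {study!r}")
    return BIPSDAConfig(
        approx=approx,
        sampler=sampler,
        n_chains=n_chains,
        langevin=lang,
        map=map_cfg,
        precondition=precond,
    )


@dataclass
class StudyConfig:
    study: str = "inpaint_low"
    variants: Sequence[str] = ("rto-tu",)
    n_trials: int = 100
    n_samples: int = 10_000
    seed: int = 0
    score: str = "analytic"  # analytic | learned (learned requires a model)
    problem_seed: int = 1234
    prior_seed: int = 99
    include_reference_row: bool = True
    mmd_max_n: int = 2000
    mcmc_chains: int = 10
    mcmc_iters: int = 20_000
    componentwise: ComponentwiseConfig = field(default_factory=ComponentwiseConfig)
    score_model: object = None  # a trained score model when score == "learned"


@dataclass
class MetricsReport:
    """Per-trial and aggregated metric values for each variant row."""

    study: str
    rows: dict  # name -> {metric -> np.ndarray of per-trial values}
    alpha: float
    divergence_counts: dict
    n_trials: int
    n_samples: int

    METRICS = ("mean_error", "variance_error", "cmd", "mmd")

    def aggregate(self) -> dict:
        out = {}
        for name, metrics in self.rows.items():
            out[name] = {}
            for metric, vals in metrics.items():
                v = np.asarray(vals, float)
                out[name][metric] = {
                    "mean": float(v.mean()),
                    "p10": float(np.percentile(v, 10)),
                    "p90": float(np.percentile(v, 90)),
                }
        return out

    def to_frame(self) -> pd.DataFrame:
        agg = self.aggregate()
        records = []
        for name, metrics in agg.items():
            rec = {"variant": name}
            for metric, stats in metrics.items():
                rec[metric] = stats["mean"]
                rec[f"{metric}_idr"] = (stats["p10"], stats["p90"])
            records.append(rec)
        return pd.DataFrame.from_records(records)

    def to_dict(self) -> dict:
        return {
            "study": self.study,
            "alpha": self.alpha,
            "n_trials": self.n_trials,
            "n_samples": self.n_samples,
            "divergence_counts": self.divergence_counts,
            "rows": {
                name: {m: np.asarray(v, float).tolist() for m, v in metrics.items()}
                for name, metrics in self.rows.items()
            },
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "MetricsReport":
        d = json.loads(s)
        return cls(
            study=d["study"],
            rows={
                name: {m: np.asarray(v) for m, v in metrics.items()}
                for name, metrics in d["rows"].items()
            },
            alpha=d["alpha"],
            divergence_counts=d["divergence_counts"],
            n_trials=d["n_trials"],
            n_samples=d["n_samples"],
        )


def _draw_reference(study, prior, like, y, n, rng, cfg: StudyConfig):
    if study in ("inpaint_low", "inpaint_high"):
        return exact_reference(prior, like, y, n, rng).values
    if study == "xray":
        n_iter = cfg.mcmc_iters
        for attempt in range(3):
            try:
                cs, _ = mcmc_reference(
                    prior,
                    like,
                    y,
                    n_chains=cfg.mcmc_chains,
                    n_iter=n_iter,
                    seed=rng,
                    min_ess=float(n),
                )
                break
            except ReferenceConvergenceError:
                if attempt == 2:
                    raise
                n_iter *= 2  # longer chains, then re-gate
        pool = cs.pooled()
        return pool[rng.choice(len(pool), size=n, replace=n > len(pool))]
    if study == "phase":
        cw = replace(cfg.componentwise, n_samples=n)
        batch, _ = componentwise_reference(prior, like, y, cw, rng)
        return batch.values
    raise ValueError(f"unknown study {study!r}")


def run_study(cfg: StudyConfig) -> MetricsReport:
    """Run one benchmark study and return its metrics report."""
    if cfg.n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    like = make_problem(cfg.study, cfg.problem_seed)
    prior = build_prior(PriorSpec(seed=cfg.prior_seed))
    if cfg.score == "analytic":
        score = AnalyticScore(prior)
    elif cfg.score == "learned":
        if cfg.score_model is None:
            raise ValueError("score='learned' requires cfg.score_model")
        score = cfg.score_model
    else:
        raise ValueError("score must be 'analytic' or 'learned'")

    names = list(cfg.variants) + (["reference"] if cfg.include_reference_row else [])
    rows = {name: {m: [] for m in MetricsReport.METRICS} for name in names}
    moment_store = {name: [] for name in names}  # (batch, ref) pairs for CMD
    divergence = {name: 0 for name in cfg.variants}
    ref_stds = []

    ss = np.random.SeedSequence(cfg.seed)
    trial_seeds = ss.spawn(cfg.n_trials)
    for trial, tseed in enumerate(trial_seeds):
        rng = np.random.default_rng(tseed)
        m_true = prior.sample(1, rng)[0]
        y = simulate_measurement(like, m_true, rng).y
        ref = _draw_reference(cfg.study, prior, like, y, cfg.n_samples, rng, cfg)
        ref_stds.append(np.sqrt(ref.var(axis=0, ddof=1)).max())
        mmd_cfg = MMDConfig(max_reference_for_eps=cfg.mmd_max_n)

        def score_batch(name, values):
            sub1, sub2 = values, ref
            if len(sub1) > cfg.mmd_max_n:
                sub1 = sub1[rng.choice(len(sub1), cfg.mmd_max_n, replace=False)]
            if len(sub2) > cfg.mmd_max_n:
                sub2 = sub2[rng.choice(len(sub2), cfg.mmd_max_n, replace=False)]
            rows[name]["mean_error"].append(mean_error(values, ref))
            rows[name]["variance_error"].append(variance_error(values, ref))
            rows[name]["mmd"].append(mmd(sub1, sub2, mmd_cfg))
            # keep only the moment summaries needed for CMD (alpha is known
            # only after all trials' reference spreads have been seen)
            moment_store[name].append(
                (
                    (values.mean(axis=0), _central_moments(values, 5)),
                    (ref.mean(axis=0), _central_moments(ref, 5)),
                )
            )

        for variant in cfg.variants:
            vcfg = default_variant_config(cfg.study, variant, cfg.n_samples)
            vcfg = replace(vcfg, seed=int(rng.integers(2**31)))
            if cfg.score == "learned" and vcfg.approx == "tc":
                raise ValueError("TC variants are not run with learned scores")
            batch = bipsda_sample(like, score, y, vcfg)
            divergence[variant] += batch.n_diverged
            score_batch(variant, batch.clean)
        if cfg.include_reference_row:
            ref2 = _draw_reference(cfg.study, prior, like, y, cfg.n_samples, rng, cfg)
            score_batch("reference", ref2)

    alpha = 4.0 * float(np.mean(ref_stds))
    for name in names:
        for (mu1, c1), (mu2, c2) in moment_store[name]:
            val = np.linalg.norm(mu1 - mu2) / alpha
            for k, (a, b) in enumerate(zip(c1, c2), start=2):
                val += np.linalg.norm(a - b) / alpha**k
            rows[name]["cmd"].append(float(val))

    return MetricsReport(
        study=cfg.study,
        rows={n: {m: np.asarray(v) for m, v in r.items()} for n, r in rows.items()},
        alpha=alpha,
        divergence_counts=divergence,
        n_trials=cfg.n_trials,
        n_samples=cfg.n_samples,
    )
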