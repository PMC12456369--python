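# bipsda

Diffusion-annealing Bayesian inverse problem solvers, with analytically
tractable Gaussian-mixture benchmarks for judging how well they sample the
posterior — not just how pretty their point estimates are.

## The problem

Given measurements `y = f(m) + noise` and a prior `π_pr(m)` represented by a
(variance-exploding) diffusion model, we want samples from the posterior
`π(m|y) ∝ π_like(y|m) π_pr(m)`. Decoupled-noise-annealing solvers run a
sequence of noise levels `σ(t_N) > … > σ(t_1) > 0` and alternate two steps
per level:

1. **Prediction** — sample `m(0)` from the prediction distribution
   `π_like(y|m) · N(m; m_aprx, C_aprx)`, where `N(m_aprx, C_aprx)` is a
   Gaussian approximation of the denoising distribution `π(m(0)|m(t))`;
2. **Corruption** — re-noise: `m(t_{i−1}) = m(0) + σ(t_{i−1}) z`.

The Gaussian approximation can be built three ways:

| | mean `m_aprx` | covariance `C_aprx` |
|---|---|---|
| **ODE** | probability-flow ODE solve (5 Euler steps) | `σ(t)² I` |
| **TU** | Tweedie's formula `m + σ² s_θ(m, t)` | `σ(t)² I` |
| **TC** | Tweedie's formula | `σ²(I + σ² ∇s_θ)` (generalized Tweedie) |

and the prediction distribution can be sampled three ways: unadjusted (or
Metropolis-adjusted, preconditioned) **Langevin** dynamics, the **MAP**
point, or **RTO** (randomize-then-optimize: perturb `y` and `m_aprx` by
their own noise and solve the perturbed MAP problem — exact sampling when
the likelihood is linear-Gaussian). Crossing the two choices gives nine
variants; `lang-ode` and `map-tu` recover the DAPS and DiffPIR algorithms.

## The benchmarks

All four studies share a ten-dimensional three-component Gaussian-mixture
prior (modes at −5·**1**, 0, +5·**1**; weights 0.4/0.3/0.3) for which the
noisy prior score, its Jacobian, and — under linear-Gaussian data — the
exact posterior mixture are available in closed form:

* `inpaint_low` / `inpaint_high` — observe 8 of 10 coordinates through a
  binary mask, Gaussian noise τ = 0.1 / τ = 5;
* `xray` — Poisson counts with mean `1000·exp(−C m)`, `C` a 15×10 matrix
  with entries uniform on [0.01, 0.05];
* `phase` — `f(m) = (B m)²` with `B` 5×10 standard normal, τ = 25.

Reference posterior samples come from exact mixture sampling (masking
studies) or a gated multi-chain differential-evolution MCMC (DE-MC-Z with
snooker moves; split-chain PSRF < 1.01 required, component-wise runs with
evidence-weighted resampling for the multimodal phase-retrieval posterior).
Sampler output is scored against the reference with four metrics: two-norm
errors of the posterior mean and pointwise-variance vectors, central moment
discrepancy (CMD), and multi-bandwidth Gaussian-kernel MMD.

## Worked example

```python
import numpy as np
from bipsda import (
    AnalyticScore, BIPSDAConfig, PriorSpec, bipsda_sample, build_prior,
    exact_reference, make_problem, mean_error, simulate_measurement,
    variance_error,
)

prior = build_prior(PriorSpec(seed=99))          # the benchmark prior
like = make_problem("inpaint_low", seed=1234)    # 8-of-10 mask, tau = 0.1
rng = np.random.default_rng(0)
m_true = prior.sample(1, rng)[0]
y = simulate_measurement(like, m_true, rng).y

score = AnalyticScore(prior)                     # exact noisy prior score
cfg = BIPSDAConfig(approx="tu", sampler="rto", n_chains=10_000, seed=0)
batch = bipsda_sample(like, score, y, cfg)       # 10,000 posterior draws

ref = exact_reference(prior, like, y, 10_000, rng)  # exact mixture draws
print(f"mean error     {mean_error(batch.values, ref.values):.3f}")
print(f"variance error {variance_error(batch.values, ref.values):.3f}")
```

prints (exact values vary with the seed)

```
mean error     0.011
variance error 0.076
```

— i.e. the randomize-then-optimize / Tweedie variant reproduces the
posterior mean to ~0.01 and the ten pointwise variances to ~0.08 in the
two-norm, close to the ~0.02 / ~0.05 resolution floor of two independent
10,000-sample exact draws on this study. A full table for any study comes
from the study runner or the CLI:

```sh
bipsda run --study inpaint_low --variant rto-tu --variant map-tu \
           --trials 20 --samples 2000 --seed 1 --out report.json
```

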