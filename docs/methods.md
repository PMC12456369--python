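# Methods

This note records the models, conventions and numerical choices behind the
package, in the order a reader would meet them: the annealing framework,
the benchmark problems, the samplers, the reference posteriors, and the
evaluation metrics. It also states which problem sizes the test suite and
`scripts/acceptance.py` actually run.

## Diffusion model and annealing loop

The noising process is variance-exploding: `m(t) = m(0) + σ(t) z` with
`σ(t) = t` on `[0, T]`, `T = 10`. The prior is noised, never rescaled, so
the time-`t` marginal of a Gaussian mixture is the same mixture with every
covariance inflated by `σ(t)² I` — this is what makes the analytic score
`∇ log π_t` available exactly, together with its Jacobian.

The annealing loop runs `N_A = 200` noise levels. Each iteration builds a
Gaussian approximation `N(m_aprx, C_aprx)` of the denoising distribution
`π(m(0)|m(t_i))`, samples the prediction distribution
`π_like(y|m)·N(m; m_aprx, C_aprx)` once per chain, and corrupts the result
to the next level. Chains are independent and vectorized; a chain that
ever produces a non-finite value is frozen at its last finite state,
flagged, and excluded from metrics (counts are reported).

**Time grid.** Annealing times interpolate linearly in the ρ-th-root
domain, `t_i = ((i/N)·T^{1/ρ} + (1−i/N)·t_min^{1/ρ})^ρ` for `i = N..1` with
`t_0 = 0`, `ρ = 7` — the discretization convention of Karras-style
diffusion samplers, which the annealing-based solvers this package
implements inherited from their reference implementations. Two properties
of this grid matter. First, it covers intermediate noise levels densely
(a pure power grid `T(i/N)^ρ` with ρ = 7 puts almost all timepoints below
σ ≈ 10⁻⁶, which collapses the inner ODE solve onto a single step and
degrades every variant measurably). Second, the floor `t_min = 0.01` —
the same noise floor used for score-model training — keeps the smallest
prediction subproblem inside the stability region of unadjusted Langevin
dynamics at its fixed published step size: stability requires
`η·(1/β² + L_like) < 2`, and with `η = 5·10⁻⁵`, `β = σ(t) ≥ 0.01` holds
this bound with margin on every study. The probability-flow ODE's internal
5-step sub-grid uses the same interpolation between `t` and
`min(t_min, t/10)` with a final step to zero; a single Euler step
reproduces Tweedie's formula exactly (for σ(t) = t), which is covered by a
unit test.

**Denoising approximations.** `ode` and `tu` use `C_aprx = σ(t)² I`
(β(t) = σ(t)); `tc` uses the generalized Tweedie covariance
`σ²(I + σ² ∇s)`, symmetrized, with eigenvalues floored at 10⁻¹⁰ (with the
analytic score the matrix is PSD up to round-off; the floor only guards
numerics). `tc` refuses learned scores unless explicitly forced: the
Jacobian of a denoising-trained network is not a reliable covariance
estimate, and the package follows the study protocol in not running those
cells.

## Benchmark problems

All four studies share the ten-dimensional three-component mixture prior:
component 1 at −5·**1** with identity covariance; component 2 at the origin
with diagonal covariance linearly spaced on [1, 2]; component 3 at +5·**1**
with the same eigenvalues as component 2 and random orthonormal
eigenvectors, drawn as the Q factor of a seeded QR decomposition of a
standard Gaussian matrix (signs fixed by the R diagonal so the operator is
a pure function of the seed); weights (0.4, 0.3, 0.3). Operator seeds only
fix an instance distributionally equivalent to the published one — exact
operator equality is impossible because the source does not specify its
random-number generation.

* Masking studies: `A` keeps coordinates 1–8 and drops 9–10 (which eight
  coordinates are observed is a free choice; only the two-dimensional null
  space matters), τ = 0.1 or 5.
* X-ray: `λ(m) = 1000·exp(−C m)`, `C ~ U[0.01, 0.05]^{15×10}`, Poisson
  counts. The log-factorial term of the Poisson likelihood is dropped — it
  cancels everywhere. The log-likelihood formula remains valid (and convex
  in `m`) for the real-valued surrogate data RTO produces. The exponent is
  clipped at ±700 so wildly diverged states saturate instead of overflowing.
* Phase retrieval: `f(m) = (Bm)²`, `B` 5×10 standard normal, τ = 25.

`report_snr` implements one SNR convention
(`10·log10(E‖f(m)‖² / E‖noise‖²)` under the prior, with the Poisson noise
second moment equal to the mean); the convention behind the published SNR
figures is not stated, so this number is informational and never gated.

## Prediction samplers

**Langevin.** Drift convention `m ← m + η·P·∇log p + √(2η)·P^{1/2} z`
(coefficient η, not η/2); published step sizes are interpreted in this
convention. Chains start at `m_aprx` — the mode of the Gaussian factor is
the natural warm start. Masking studies: η = 5·10⁻⁵, 100 subiterations,
unadjusted. X-ray: 1000 subiterations. Phase retrieval: Metropolis-adjusted
with η = 0.2, 1000 subiterations, and a fixed preconditioner per annealing
step — the average Gauss-Newton Hessian `Jᵀ Σ_z⁻¹ J + C_aprx⁻¹` over eight
anchor points subsampled from the current denoised means (the anchors are
"representative sample points" of the prediction target; the perturbed
means are where the mass sits), inverted, symmetrized, and regularized by
10⁻⁸·I.

**MAP.** For masking likelihoods the MAP point is closed-form (one shared
SPD solve for isotropic `C_aprx`; per-chain solves of
`(C AᵀA/τ² + I) m = C Aᵀy/τ² + m_aprx` for full covariances, avoiding an
explicit inverse). For the nonlinear likelihoods the public interface
offers scipy's L-BFGS-B per chain (`method="quasi_newton"`, 40 iterations,
Wolfe line search) and a batched Gauss-Newton solver
(`method="gauss_newton"`) that the annealing loop uses: the study protocol
requires hundreds of thousands of 10-dimensional MAP solves, and a
vectorized solver with per-chain retirement is two orders of magnitude
faster than per-chain quasi-Newton while agreeing with it to optimizer
tolerance (cross-checked in tests). For the Poisson likelihood the
Gauss-Newton Hessian with `Σ_z = diag(λ)` equals the exact Hessian and the
objective is convex; for phase retrieval a backtracking Armijo line search
guards nonconvexity. Chains retire from the working set when their
gradient norm falls below `gtol = 10⁻⁵` or their Newton decrement falls
below the round-off floor of the objective (`10⁻¹⁵·(1+|f|)`), whichever
comes first.

**RTO.** Draw `m'_aprx ~ N(m_aprx, C_aprx)` and a noise-perturbed
measurement, then return the MAP of the perturbed problem. Gaussian
likelihoods: `y' ~ N(y, τ² I)`. The Poisson likelihood has no additive
noise to perturb; the package uses the variance-matched Gaussian surrogate
`y'_k ~ N(y_k, max(y_k, 1))` — an interpretation, stated here prominently,
since randomize-then-optimize is defined for Gaussian noise. In the
linear-Gaussian case RTO is exact sampling from the prediction
distribution, which is the module's headline test (10⁵ draws against the
conjugate closed form).

## Score models

The analytic score wraps the noisy prior mixture (responsibilities in log
space with cached per-component precisions; σ spans [0, 10] and naive
evaluation underflows). The learned score is a plain-numpy MLP
`s_θ(m, σ)` — six hidden layers of width 512 at the published training
configuration (80,000 prior samples, w(t) = σ²(t), Adam at 10⁻⁵, batch
8000, 50,000 iterations, t ~ U[0.01, 10]), with σ appended to the input and
re-appended after the fourth hidden layer. It parameterizes the score
directly as a vector field trained by denoising score matching
(per-sample residual `‖σ s + z‖²`), rather than as the gradient of a
scalar potential: a conservative parameterization would require
second-order backpropagation, and nothing downstream uses the learned
score's Jacobian (the TC covariance is analytic-score-only by protocol).
The tests exercise training at a reduced configuration (3×128 network,
4000 Adam steps at 2·10⁻³, 20,000 samples) and assert a ≥10× reduction of
score mean-squared error at σ = 1; learned-score table cells are out of
scope.

## Reference posteriors

Masking studies: the posterior is a Gaussian mixture in closed form
(conjugate per-component updates; weights via the marginal likelihood
`N(y; Aμ_k, AΣ_kAᵀ + τ²I)`, renormalized in log space), sampled exactly.

Nonlinear studies: a multi-chain differential-evolution MCMC with an
archive of past states (DE-MC-Z) and snooker moves. Per iteration all
chains move in one vectorized block; the move type (parallel-direction
vs. snooker) is chosen per iteration, a state-independent kernel mixture.
Ordinary moves use `γ = 2.38/√(2D)` with probability 0.9 and `γ = 1`
(mode-jumping) with probability 0.1, plus 10⁻⁶ jitter; the archive grows
every 10 iterations. For likelihoods with an exact sign symmetry
(`f(−m) = f(m)`, i.e. phase retrieval) one move type in ten proposes the
point reflection `m → −m` with a plain Metropolis correction — a symmetric
involution, valid for any target; it is essential because
difference-vector jumps cannot exchange exactly symmetric modes in ten
dimensions (acceptance ~ 3^(−D/2)), so without it the zero-mean prior
component's chains plateau above the PSRF gate at any chain length. The first half of every chain is discarded as
burn-in. Convergence gates are mandatory: split-chain PSRF < 1.01 in every
dimension (classic split Gelman–Rubin; the implementation is cross-checked
against arviz's split R-hat in tests) and, where a sample count is
requested, ESS at least that count (Geyer initial-positive-sequence
estimator, summed across chains). A reference that fails its gate raises —
it is never silently used; callers may retry with doubled chain length and
re-gate, and the study runner and acceptance script do exactly that.

X-ray reference: DE-MC-Z on the full posterior, chains initialized at
i.i.d. prior draws (over-dispersed; the posterior concentrates on one
prior component at this problem's count levels). Phase-retrieval
reference: the posterior is genuinely multimodal, so each prior component
is sampled separately (Latin-hypercube initialization over the component
mean ± 6 standard deviations per dimension), the per-component evidence is
estimated by reverse (Gelfand–Dey) importance sampling with a Gaussian
fitted to the post-burn-in draws and its covariance shrunk by 0.75, and
the final batch resamples components with probability ∝ weight × evidence.
On the masking studies, where the closed form is available, the estimated
component weights agree with the conjugate posterior weights to well
under 2% — the validation that licenses trusting the machinery on the
nonlinear studies. "Two independent reference sets" (the reference
self-distance rows) means two full independent runs of this procedure:
chains within one run share an archive and are not independent, so
half-splitting one run would understate the self-distance.

## Metrics

* Mean / variance error: two-norms of the differences of empirical means
  and per-dimension unbiased variances.
* CMD with K = 5: `(1/α)‖Δmean‖ + Σ_{k=2..5} α^{-k}‖Δc_k‖` with `c_k` the
  vector of per-coordinate k-th central moments (full moment tensors are
  neither feasible nor implied by the metric's literature). The decay rate
  is calibrated per study as `α = 4·η̂_max`, with `η̂_max` the mean over
  trial measurements of the sup-norm of the reference posterior's
  per-dimension standard deviations, estimated from the reference sample
  batches themselves.
* MMD with a five-bandwidth Gaussian-sum kernel `Σ_i exp(−‖Δ‖²/(2ε_i))`,
  `ε_i = ε̄·2^{i−⌈N_b/2⌉}` (factors ¼…4), `ε̄` the mean squared pairwise
  distance among reference samples (computed on a 2000-point subsample for
  O(n²) cost control). Default estimator: biased V-statistic, square
  root, floored at zero. Both the bandwidth-ladder exponent and the
  kernel-denominator convention are config-exposed because the printed
  notation admits either reading; whether published MMD cells are MMD or
  MMD² is likewise ambiguous, so MMD cells are reported but not used as
  quantitative reproduction surfaces.
* Aggregation: per-trial values, trial mean, and empirical 10th/90th
  percentiles (linear interpolation). The "reference" row scores two
  independent reference batches against each other and is the resolution
  floor of the protocol.

## Problem sizes used by the tests and the acceptance script

The published protocol is 100 trials × 10,000 samples per cell. The
package's own runs scale Monte-Carlo-heavy cells down, a choice made once
and recorded here:

* Exact-sampling reference floors (masking studies): 100 trials × 10,000
  samples in the acceptance script (50 trials in the test suite).
* `rto-tu` low noise: 20 trials × 10,000 (closed-form solves are cheap).
* `lang-tu` high noise: 20 trials × 2,000 — the Langevin failure it
  measures is systematic, not Monte Carlo.
* `lang-ode` low noise: 20 trials × 2,500; at reduced n the sampling floor
  contributes visibly, so checks use the published interdecile range as
  tolerance rather than the mean band.
* X-ray: 5 trials × 2,000 against a 10-chain × 20,000-iteration gated
  reference; the standalone PSRF check runs 10 × 50,000.
* Phase retrieval: 3 trials × two independent component-wise references
  (40 chains × 50,000 iterations per component, gate retries doubling the
  length); trials whose chains cannot pass the gate after retries are
  skipped and reported.

## What the synthetic benchmarks do and do not show

The generator reproduces the study conditions exactly as specified —
dimension, mixture geometry, operators, noise levels, trial protocol — so
passing tests demonstrate correctness of the solvers and estimators under
those conditions. They do not demonstrate behavior on high-dimensional
image priors, learned scores of real data (score error here is isolated
deliberately), non-Gaussian mixture priors, or real CT / optical forward
operators. Runtime behavior (the published timing table) is out of scope.

## Known limitations

* The learned-score path covers training-improvement properties only;
  reproducing learned-score table cells would require the full 50,000
  iteration training run and is seed-sensitive.
* The x-ray RTO perturbation is a Gaussian surrogate for Poisson noise;
  no claim of exactness is made for that study.
* Operator instances match the published ones distributionally, not
  entry-wise; table comparisons inherit instance-level variability.
* Metropolized RTO and Hamiltonian Monte Carlo prediction samplers are not
  implemented.
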