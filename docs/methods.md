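# Methods

## Evidence by thermodynamic integration

For a model `m` with parameters `θ`, prior `p(θ|m)` and likelihood
`p(y|θ,m)`, the package estimates the log model evidence (LME) via the path
of power posteriors `p_β(θ|y,m) ∝ p(y|θ,m)^β p(θ|m)`, `β ∈ [0,1]`.
Writing `A(β) = E[ln p(y|θ,m)]` under `p_β` (the *accuracy*), the LME is
the integral of `A` from 0 to 1. The estimator is the trapezoid rule on a
fixed temperature grid with per-temperature Monte Carlo means
`E_MC(β_j) = K⁻¹ Σ_k ln p(y|θ_k,m)`. Two classical one-sample estimators
are provided for comparison: the prior arithmetic mean
(`log-mean-exp` of log-likelihoods under prior draws; downward biased
because prior draws rarely hit the typical set of the likelihood) and the
posterior harmonic mean (upward biased because the inverse likelihood has
heavy tails under the posterior). Both use max-shifted `log-sum-exp`; they
are reference implementations, not recommended outputs.

The negative free energy along the path decomposes as
`-F_H(β) = β·A(β) − KL[p_β ‖ prior]`; `decompose_free_energy` reports both
terms, with the KL obtained as the difference between the rectangle
`β·A(β)` and the partial trapezoid integral. Up to Monte Carlo error the KL
term is nonnegative and `A` is nondecreasing in `β` (its derivative is the
variance of the log-likelihood under `p_β`); both properties are tested.

**Temperature schedule.** `β_j = (j/(N−1))^5`, the fifth-order power rule,
with N = 16 chains at desk scale (N = 64 reproduces the original studies'
setting). The fifth-order rule concentrates temperatures near `β = 0`,
where `A(β)` changes by orders of magnitude for data-rich models.

**Quadrature error.** For the conjugate regression benchmark the accuracy
curve is available in closed form, which bounds the discretization bias of
the 16-point rule at ≈ 0.4–0.6 nats for p = 16–32 (well inside the 1-nat
benchmark band); 64 points reduce it below 0.04 nats. Simpson's rule is
available behind a flag but the trapezoid rule is the committed default.

**Monte Carlo standard errors** of each `E_MC(β_j)` use an
autocorrelation-aware effective sample size (Geyer's initial positive
sequence on the FFT autocovariance), propagated through the trapezoid
weights assuming independence across temperatures. The in-package ESS is
cross-checked against `arviz.ess` in the test suite.

## Population MCMC

One Metropolis chain per temperature; per sweep each chain performs one
update, then neighbouring chains attempt state swaps (accepted with
probability `min(1, exp((β_i−β_{i+1})(ℓ_{i+1}−ℓ_i)))`, cached
log-likelihoods travelling with their states), alternating even/odd pairs
across sweeps. The `β = 0` chain draws independently from the prior — its
target *is* the prior, so this is exact. Chains are initialized from prior
draws; identical seeds give bit-identical traces (one RNG substream per
chain plus one for swaps, spawned from the master seed).

The within-chain kernel needed care: at the scale used here (16 chains,
2000 + 2000 sweeps) an isotropic random walk leaves per-temperature
split-half R-hat of the log-likelihood as high as 3.4 on DCM inversions.
The production kernel therefore combines

* **adaptive-Metropolis covariance shaping** — each chain accumulates the
  empirical covariance of its history and proposes
  `θ' = θ + s · (2.38/√d) · L z` with `L` the covariance Cholesky factor,
  the global scalar `s` tuned toward 25% acceptance by a Robbins-Monro
  recursion on `log s`;
* **diminishing adaptation** continued through the sampling phase
  (Haario-style; the adaptation magnitude decays as `t^-0.6`, which
  preserves ergodicity; a hard freeze at the end of burn-in is available
  via `SamplerConfig(diminishing_adaptation=False)`);
* **lognormal step-size jitter** (SD 0.3 on the log scale), giving
  occasional long jumps;
* a **10% independence-from-prior proposal mixture** (acceptance
  `min(1, exp(β Δℓ))`): for weakly tempered chains, whose neighbour-swap
  acceptance is essentially zero because `E_MC` gaps between adjacent
  temperatures reach 10⁴–10⁵ nats on DCMs, this provides global
  regeneration;
* an optional model-supplied **Metropolis-within-Gibbs block**
  (`model.gibbs_step`): the DCM model refreshes its per-region noise
  log-precisions from cached residual sums of squares — no ODE work —
  which removes the dominant slow component of the log-likelihood trace.

With all of these, the maximum split-half R-hat over temperatures on the
criterion DCM inversion stayed below 1.09 across ten seeds.

**Convergence reporting.** R-hat over chains at *different* temperatures is
meaningless, so the diagnostic is computed per temperature on the split
halves of the retained log-likelihood trace, and the reported figure is the
maximum over temperatures (threshold 1.1).

## Conjugate linear regression

`y = Xθ + e`, prior `θ ~ N(0, Π_p⁻¹)`, noise `e ~ N(0, Π_e⁻¹)`. The
posterior is `N(Π⁻¹XᵀΠ_e y, Π⁻¹)` with `Π = Π_p + XᵀΠ_e X`, and the LME has
a closed form used as the oracle throughout. All determinants and solves go
through Cholesky factorizations; explicit inverses are never formed. The
benchmark configuration is M = 100 observations, prior variance 16, noise
variance 10, and a one-way-ANOVA block design with `⌊M/p⌋` rows per level
(excess rows assigned to the last level). Datasets are drawn from the
generative model itself — θ from the prior, then y from the likelihood, in
that fixed RNG order — so a seed pins the dataset bit-for-bit.

## DCM forward model

Neuronal dynamics for R regions and J inputs:
`ẋ = (A + Σ_j u_j B⁽ʲ⁾ + Σ_d x_d D⁽ᵈ⁾) x + C u` (all entries in Hz).
Each region's hemodynamics follow the balloon/windkessel model (vasodilatory
signal, inflow, venous volume, deoxyhemoglobin) with constants fixed at
standard prior means: κ = 0.64 s⁻¹, γ = 0.32 s⁻¹, τ = 2 s, α = 0.32,
ρ = 0.32, V₀ = 0.04, output constants k₁ = 7ρ, k₂ = 2, k₃ = 2ρ − 0.2.
Hemodynamic parameters are not sampled: fixing them isolates connectivity
inference. BOLD is reported in percent signal change, sampled at the scan
times.

**Integration.** Fixed-step Euler at the input sampling resolution
(0.5 s for the 2.0-Hz input grid), in a compiled (numba) kernel, because
each model inversion evaluates the likelihood ~50 000 times. An RK4 variant
(`method="rk4"`) is available; it converges to < 10⁻³ RMS under step
halving on all fixture models and is the integrator compared against a
scipy `solve_ivp` reference in the tests. Euler at 0.5 s carries a visible
first-order discretization error (~5% of signal SD), which is immaterial
for inference — simulation and inversion share the same forward map — but
worth knowing when comparing against other implementations.

**Saturation instead of divergence.** Under the wide driving-input prior,
strongly negative sustained neuronal drive pushes the balloon model's flow
state toward zero, where the equations are undefined. Aborting such draws
would make the prior-predictive expected log-likelihood (the `β = 0` end of
the TI path) undefined, so instead the hemodynamic states saturate at wide
physiological bounds (f, v ∈ [10⁻², 10³], q ∈ [10⁻⁴, 10⁴]); these bounds
are never approached on realistic trajectories. A divergence error is
reserved for genuine neuronal blow-up (‖x‖ > 10⁴), which the sampler maps
to log-likelihood −∞ (rejection).

**Likelihood and priors.** Observation noise is iid Gaussian per region
with free log-precision (prior `N(ln 10, 1)`). Connectivity priors:
self-connections are parameterized as `−0.5·exp(a_r)` (always negative,
prior `a_r ~ N(0, 1/16)`); off-diagonal and modulatory (B, D) entries
`N(0, 1/16)`; driving-input weights `N(0, 1)`. The free-parameter layout of
a model is the nonzero pattern of its spec's matrices.

**Fixture models.** Five 3-region, 2-input DCMs share the backbone
u₁→x₁, u₂→x₂, x₁→x₃, x₂→x₃ and differ in what shapes x₃: m₁ nothing else
(linear null model); m₂ a bilinear modulation of x₁→x₃ by u₂; m₃ of x₂→x₃
by u₁; m₄ u₁ on the self-connection of x₃; m₅ nonlinear gating of x₁→x₃ by
x₂'s activity. Acquisition: TR = 2 s, 720 scans, inputs sampled at 2.0 Hz.
The numeric connectivity values (0.3 Hz endogenous/driving, 0.5 Hz
bilinear, 0.4 Hz nonlinear, −0.5 Hz self) are synthetic defaults in the
typical range of fMRI effective-connectivity studies; they are this
package's choice, not transcribed from a published table. Inputs are
off-first boxcars with 40 s (u₁) and 120 s (u₂) periods so that the
u₁×u₂ overlap varies across the run, which is what makes modulatory and
nonlinear effects identifiable.

**Noise at SNR.** `add_noise_at_snr` adds per-region iid Gaussian noise
with SD equal to the region's signal SD divided by the requested SNR
(SNR 1 = equal signal and noise power, the challenging regime used in the
recovery study).

## Synthetic-data generators: what they do and do not emulate

The regression generator produces exactly the model the estimators assume,
so benchmark errors measure estimator quality, nothing else. The BOLD
simulator shares its forward model with the inversion — noise is the only
misspecification-free corruption. Real fMRI adds drifts, physiological
noise, regional hemodynamic variability and model misfit; passing the
desk-scale studies therefore demonstrates correctness of the estimators and
sampler, not field performance on empirical data.

## Scales, defaults and determinism

Desk-scale defaults (library and CLI): 16 chains, order 5, 1500 kept /
500 burn-in sweeps for regression; 2000 kept / 1000 burn-in for recovery
inversions; 2000 kept / 2000 burn-in for the convergence study; AME uses
6000 prior draws; HME consumes the `β = 1` chain of the existing trace.
The original studies' scale (64 chains, 6000–10⁴ samples, 40 noise
realizations per model, p = 2…32) remains reachable through the same
configuration surface. Every run consumes a single master seed; chain
substreams, dataset seeds and repetition seeds are derived through
`SeedSequence` spawning, so results are bit-reproducible and independent of
chain count.

## Known limitations

* Random-walk-based kernels: no gradients, so mixing degrades beyond a few
  dozen parameters; the DCM studies here use 10–11.
* The trapezoid rule inherits a small negative bias from the concavity of
  the free-energy path at coarse schedules.
* Model recovery at desk scale (5 datasets per generator, 2 candidate
  models) bounds sensitivity; the full 5-model × 40-dataset confusion
  structure needs the paper-scale configuration.
* The DCM integrator's Euler default trades accuracy for speed (see above);
  use `method="rk4"` when absolute forward accuracy matters.
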