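# Methods

## Model

The promoter is a three-state continuous-time Markov chain

```
C  --α-->  B  --λ-->  A
C  <--β--  B  <--ν--  A
```

with transcription at rate Κ while in the active state A and first-order
mRNA decay at rate δ. All rates are expressed in units of δ (δ = 1), so
times are in mRNA lifetimes. C is a deep inactive state exchanging slowly
with the primed inactive state B; the B⇌A switching produces bursts.

### Steady-state count distribution (ZINB)

When α, β ≪ δ, a cell is effectively frozen in either the C branch or the
B⇌A branch on the timescale of mRNA turnover. Cells in C show zero counts;
cells in the B⇌A branch follow the classical two-state (telegraph) bursting
limit, which for short active periods (ν ≫ λ) gives a negative binomial
with shape r and success probability p. The mixture is the zero-inflated
negative binomial

- P(0) = ω + (1−ω)(1−p)^r
- P(n) = (1−ω) · C(n+r−1, n) · (1−p)^r · p^n  for n ≥ 1

with mechanistic correspondence

- ω = β/(α+β) — stationary deep-state fraction,
- r = λ/δ — burst frequency (bursts per mRNA lifetime),
- p = Κ/(ν+Κ) — so the mean burst size is p/(1−p) = Κ/ν.

Two conventions for p circulate, p = Κ/(ν+Κ) and p = ν/(ν+Κ); only the
former is consistent with the pmf above (whose mean burst contribution is
r·p/(1−p)) and with the burst size Κ/ν. We adopt it throughout;
`zinb.mechanistic_to_statistical_literal` provides the alternative reading
for comparison.

ω = β/(α+β) is itself an approximation: the exact stationary C-occupancy of
the three-state chain is π_C = β / (β + α(1+λ/ν)). The two agree when
λ ≪ ν. In the validation regime used in the tests (α = β = 0.01, λ = 2,
ν = 50) the exact value is 0.4902 versus the approximate 0.5, a bias of
≈ 0.01 that is visible but within the Monte-Carlo band of a 2×10⁴-cell
snapshot. `simulate.stationary_state_distribution` returns the exact
occupancies.

Closed-form moments, with b = p/(1−p):

- mean = (1−ω) r b
- var  = (1−ω) r b (1+b) + ω(1−ω)(r b)²

Both are verified against truncated-summation oracles; the truncation point
comes from the negative-binomial survival function (not a pmf sum), so the
requested tail mass is met without floating-point cancellation.

## Gillespie simulation

`simulate` implements the exact stochastic simulation algorithm for the
five reactions (state exchanges, transcription, decay). Population
snapshots draw each cell's initial promoter state from the exact stationary
distribution and relax for `t_relax` (default 20·max(1/δ, 1/(α+β))) before
reading out counts, so only the mRNA distribution needs to equilibrate.
Cores are numba-compiled; per-cell seeds are spawned deterministically from
the population seed. In the slow-switching regime (α = β = 0.01, λ = 2,
ν = 50, Κ = 565) the simulated count distribution of 2×10⁴ cells is within
total-variation distance ≈ 0.035–0.04 of the mapped ZINB (threshold 0.05 in
the tests); part of that distance is the genuine ω-approximation bias noted
above, the rest is finite-sample noise and residual non-freezing of C⇌B.

## Summary statistics

Noise is CV² = σ²/μ² and burstiness the Fano factor F = σ²/μ, computed with
the unbiased variance (ddof = 1). Cells with more than 150 counts are
excluded by default (inclusive threshold: 150 is kept); such high-content
cells are treated as segmentation/hybridisation artifacts. Standard errors
come from a nonparametric bootstrap over cells (default 10⁴ resamples);
resamples with zero mean are dropped, with a warning if they exceed 1%.
All-zero conditions are flagged as undefined rather than raising.

## MCMC sampler

The posterior over θ = (ω, r, p) combines the ZINB likelihood (evaluated on
the histogram of unique counts, so cost scales with the number of distinct
values, not cells) with priors ω ~ U(0,1), p ~ U(0,1) and
r ~ half-normal(0, 20) — effectively flat over any plausible burst
frequency while keeping the posterior proper.

- **Proposal.** Component-wise Gaussian random walk with σᵢ =
  max(0.05·θᵢ, 10⁻⁴). The 5% scale adapts step size to parameter magnitude;
  the floor prevents the walk from freezing near zero.
- **Hastings correction.** Because the proposal scale depends on the
  current state, the proposal is asymmetric; the acceptance ratio therefore
  includes the q(θ|θ′)/q(θ′|θ) factor by default. A symmetric-acceptance
  mode (`hastings_correction=False`) is provided for comparison; with a 5%
  scale the
  difference is small but the corrected chain is exactly invariant, which
  the prior-recovery test (KS < 0.02 per marginal against the analytic
  priors) verifies.
- **Defaults.** 500,000 iterations, 100,000 burn-in, thinning 100
  (4,000 retained samples). Initialisation is by method of moments, clipped
  to the prior support. Point estimates are the MAP over retained samples;
  intervals are equal-tailed posterior quantiles (95%). Burst kinetics and
  their intervals are obtained by transforming the retained samples.
- **Diagnostics.** Effective sample size via the initial-positive-sequence
  estimator on FFT autocovariances, and split-R̂; `fit()` warns when
  ESS < 100, R̂ > 1.05 or the acceptance rate leaves (0.01, 0.99).
- **Reproducibility.** The numba core consumes blocks of pre-drawn randoms
  from `numpy.random.default_rng(seed)`; no global RNG state is touched and
  chains are bit-identical across runs and platforms for a given seed.
  `resume()` continues a chain from its final state.

Sampler validation (all in the test suite): prior recovery with no data;
recovery of generating parameters (ω = 0.3, r = 2, p = 0.9) on 2,000
synthetic cells; joint 95%-interval coverage of 43/50 over fifty replicate
datasets (expected joint coverage of three 95% intervals is below 95%, of
order 86–90%); an independent quadrature cross-check of a posterior
functional; and monotonicity of fitted kinetics in the generating values.

## Noise scaling laws

For mean expression ⟨n⟩ varied at fixed capacity Κ (δ = 1):

- **Burst-frequency regulation** (λ varies, ν fixed):
  CV² = 1/⟨n⟩ + (Κ−⟨n⟩)² / (⟨n⟩(νΚ + Κ − ⟨n⟩)), F = ⟨n⟩·CV².
  F ≫ 1 and nearly flat at low expression (max deviation from the mean
  ≈ 12% over ⟨n⟩ ∈ {1, 10, 100} at Κ = 1000, Κ/ν = 11.3).
- **Burst-size regulation** (ν varies, λ fixed):
  CV² = 1/⟨n⟩ + (Κ−⟨n⟩)/(λΚ + ⟨n⟩), F = 1 + ⟨n⟩(Κ−⟨n⟩)/(λΚ + ⟨n⟩).
  F → 1 at low expression and increases with the mean up to
  ⟨n⟩* = Κλ(√(1+1/λ) − 1) ≈ 0.447Κ at λ = 1.89, then declines back to 1
  at ⟨n⟩ = Κ.

Both reduce to the Poisson floor CV² = 1/⟨n⟩ in the fast-switching limits
(ν → ∞, λ → ∞) and satisfy F = CV²·⟨n⟩ identically. At the telegraph
stationary mean ⟨n⟩ = Κλ/(λ+ν), the frequency-regulated expression reduces
algebraically to the classical two-state Fano factor
1 + Κν/((λ+ν)(λ+ν+1)). Defaults: Κ = 1000 with Κ/ν = 11.3 (frequency
regime) and λ = 1.89 (size regime); the formulas require 0 < ⟨n⟩ < Κ.

## Numerical choices

- pmf evaluation in log space with `gammaln`; ω ∈ {0, 1} and n = 0 handled
  explicitly. Non-integer r is supported.
- Seeds: every public sampling function takes an explicit seed; pipeline
  stages derive independent seeds from the global seed by SHA-256 of
  `"{seed}:{stage}"` reduced mod 2³¹.
- numba is a hard dependency: the SSA validation and the long prior-recovery
  chains are far outside pure-Python budgets.
- CSV/TSV I/O is canonical (fixed column order, `\n` line endings) so
  round-trips are byte-identical; parse errors report 1-based file rows.

## Scope and limitations

- Inference assumes steady state and a homogeneous cell population; cell
  size, cell cycle and extrinsic noise are not modelled.
- The ZINB likelihood is exact only in the slow-exchange limit α, β ≪ δ
  with ν ≳ λ; outside it, fitted ω conflates deep-state occupancy with
  other sources of excess zeros (the ω bias above is the mild in-regime
  form of this).
- Technical zeros (detection dropouts) are indistinguishable from
  biological zeros; ω absorbs both.
- Measurement noise in smFISH counting is not modelled; counts are taken
  as exact. Everything upstream of the per-cell count table (imaging,
  segmentation, spot calling) is out of scope.
- The MAP-over-samples estimator inherits thinning granularity; with 4,000
  retained samples it is adequate for the unimodal posteriors seen here
  but is not a numerical optimiser.
- The scaling laws treat the promoter as a two-state system with the
  deep state ignored; they describe regulation regimes, not fits.
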