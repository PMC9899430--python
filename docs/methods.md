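# Methods

## Models

The package works with two discrete-time stochastic population models.

**Gompertz.** On the log-abundance scale,
`y_t = y_{t-1} + r (1 - y_{t-1}/k) + eps_t` with
`eps_t ~ N(0, sigma2)` i.i.d. — algebraically the AR(1) process
`y_t = r + beta * y_{t-1} + eps_t` with `beta = 1 - r/k`. The process
noise is interpreted as environmental stochasticity with constant
variance: demographic stochasticity (which scales inversely with
abundance) and observation error are assumed negligible, which is
appropriate for large populations observed without error and is the
regime the simulators generate. For `|beta| < 1` the stationary
distribution is Normal with mean `k` and variance
`v_inf = sigma2 / (1 - beta^2)`; the identities
`sigma2_dd = v_inf - sigma2 = beta^2 sigma2 / (1 - beta^2)` and
`phi_dd = beta^2` follow directly and are implemented as pure functions
in `densvar.analytic`. `beta = 1` (random walk with drift) and
`|beta| > 1` (explosive) are rejected with distinct error messages
everywhere a stationary quantity is requested; nothing is silently
clipped.

**Ricker.** On the abundance scale,
`Y_t = Y_{t-1} exp{ r (1 - Y_{t-1}/K) + eps_t }`. It has no closed-form
stationary distribution; linearizing about the equilibrium `K` gives a
log-scale AR(1) with coefficient `1 - r`, so
`sigma2 / (1 - (1-r)^2)` is exposed as a *small-noise approximation*
(`ricker_linearized_variance`) and used only as a simulation oracle at
`sigma2 = 0.001`, where a 5% tolerance holds comfortably.

## Simulation

Gompertz trajectories are generated on the log scale with
`scipy.signal.lfilter` (the recursion is a first-order linear filter);
Ricker trajectories by direct iteration, aborting with a diagnostic if
the abundance leaves `(0, inf)` — possible only at noise levels far above
anything the experiment uses. Index 0 of a trajectory is the initial
condition; "n steps" means n post-initial values. Ensembles start each
replicate at the carrying capacity on the model's scale and give
replicate `i` the RNG stream `SeedSequence((base_seed, i))`, making them
reproducible and order-independent. Burn-in bookkeeping travels with the
trajectory: the default design simulates 300 steps and discards the
first 200, so stationary summaries use the final 100 points.

## Estimation

**OLS.** Because the log-scale Gompertz model is a Gaussian linear
model, conditional maximum likelihood equals least squares of `y_t` on
`y_{t-1}` (`scipy.stats.linregress`). The innovation-variance estimate
divides the residual sum of squares by `n - 1 - 2` (pairs minus two
coefficients). Standard errors are reported for the coefficients but,
as the observations are serially dependent, they are used only for
chain initialization and rough scaling, not for confidence intervals.

**Bayesian fits.** Priors: Gompertz — `r ~ Gamma(1,1)`,
`beta ~ N(0,1)` untruncated, `sigma2 ~ InvGamma(0.1, 0.1)`; Ricker —
`r ~ Gamma(1,1)`, `K ~ Gamma(0.1,0.1)`, `sigma2 ~ Gamma(0.1,0.1)`. The
likelihood conditions on the first observation (no stationary-initial
term), matching the regression formulation. The sampler is
Metropolis-within-Gibbs:

* Gompertz: `sigma2` has a conjugate inverse-gamma conditional and is
  Gibbs-updated; `r` and `beta` use random-walk Metropolis (the gamma
  prior on `r` breaks full conjugacy). The conditional sum of squared
  errors is a quadratic form in five sufficient statistics, so each
  update costs O(1) regardless of series length.
* Ricker: the gamma prior on `sigma2` is **not** conjugate to the
  Gaussian likelihood, so all three parameters use random-walk
  Metropolis on the log scale (the prior-density terms absorb the
  Jacobian). The log growth rates are linear in `(r, r/K)`, so the same
  sufficient-statistic trick applies.

Defaults: 3 chains, 14,000 iterations, 4,000 burn-in, thin 1. Proposal
scales adapt toward a 44% acceptance rate during burn-in only and are
frozen afterward, so the retained phase has a fixed kernel. Chain `j`
starts from the OLS estimates jittered by `j` standard errors
(overdispersed starts). Every fit is a pure function of
`(data, settings, seed)`.

Draws with `|beta| >= 1` are retained in the `beta` summaries (the prior
is untruncated by design) but counted and reported; the derived
`k = r/(1-beta)` is summarized over the stationary draws only, since it
is undefined at the random-walk boundary.

**Diagnostics.** The Gelman–Rubin potential scale reduction factor is
computed from the classic between/within-chain variance formula
(`Vhat = (n-1)/n W + (1 + 1/m) B/n`, statistic `sqrt(Vhat/W)`); it can
undershoot 1 by at most the `(n-1)/n` factor for perfectly agreeing
chains. Effective sample sizes are delegated to `arviz.ess`. Fits with
any Rhat above 1.1 are flagged, never discarded.

## The replicated experiment

The default design crosses environmental variance
{0.10, 0.15, 0.20, 0.25} with growth rate {0.8, 0.6, 0.4} at `k = 1`
(hence `beta` in {0.2, 0.4, 0.6}), 100 replicates per cell, 300 steps
with 200 discarded. Per replicate, the empirical stationary variance is
the unbiased sample variance of the retained 100-point segment, and two
decompositions are recorded: against the known generating `sigma2`
("known" pathway) and against an estimate from a fresh MCMC fit of each
requested model to that same segment ("fitted" pathway). Negative
`sigma2_dd` estimates — expected by sampling noise at weak feedback —
are kept and flagged; clipping them would bias the cell means upward.

**Point-estimate functional.** The decomposition subtracts the
*posterior median* of `sigma2`. The variance posterior is right-skewed,
so the posterior mean systematically overshoots, which in turn drags
`phi_dd = 1 - sigma2_hat/v_inf` below `beta^2` — noticeably at
`beta = 0.2`, where the bias is comparable to the entire
density-dependent share. The median functional gives per-cell mean
`phi_dd` values uniformly closer to `beta^2` across all feedback
levels. Posterior means (and full quantiles) remain in every
`PosteriorSummary` for users who prefer them.

Cell summaries report, per (cell x model): median/quartiles and Tukey
whiskers (`Q1 - 1.5 IQR`, `Q3 + 1.5 IQR`) of `v_inf` and `phi_dd`
across replicates, the mean `phi_dd` with its 2.5–97.5 percentile
interval (and a normal-approximation CI of the mean alongside), and the
analytic reference `beta^2`. Per-replicate variances are used
throughout (a pooled alternative would hide the across-replicate spread
the boxplots are meant to show).

## What the synthetic data does and does not emulate

The generator *is* the data-generating process of the study design:
Gaussian environmental shocks with constant variance, no demographic
stochasticity, no observation error, no age structure, no Allee
effects, and a known model family. Passing tests therefore demonstrate
internal consistency of the decomposition and the estimators under
exactly these assumptions — they do not show robustness to observation
error or model misspecification beyond the one cross-model check built
into the design (fitting the Ricker model to Gompertz-generated data,
where the two models' near-equilibrium behavior coincides to first
order).

## Problem sizes and numerical choices

* Long-run moment checks use 1e5-step trajectories with the first 1,000
  points discarded; Monte-Carlo tolerances are 3 asymptotic standard
  errors (for the sample variance of a Gaussian AR(1):
  `v_inf * sqrt(2 (1+beta^2) / ((1-beta^2) n))`).
* The test-suite experiment uses the sigma2 = 0.10 column with 25
  replicates per cell, and 50 replicates for the recovery/coverage
  check, at the full default MCMC budget; the complete 12-cell x
  100-replicate design is available via
  `densvar experiment --full-design`.
* Proposal-scale adaptation clips to [1e-6, 1e3]; chain initializations
  are clipped into the prior support (e.g. `r >= 1e-3`).
* CSV floats are serialized at 17 significant digits and parsed with
  pandas' round-trip parser, so file round trips are bit-faithful.

## Known limitations

* The Ricker stationary variance is only characterized through the
  small-noise linearization; at large `sigma2` or `r` near 2 the
  approximation degrades and the simulator may legitimately abort on
  numerical blow-up.
* Credible intervals are exact posterior quantiles under the stated
  priors, but the coverage statements in the tests are frequentist
  summaries over replicates at one design cell, not a general
  calibration claim.
* No observation-error (state-space) layer: fitting these models to
  real survey data with sampling noise can produce spurious density
  dependence; that extension is out of scope.
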