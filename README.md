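# densvar

Density regulation does not just pull a population back toward its
equilibrium — it also reshapes how environmental noise accumulates into
population variability. `densvar` quantifies that interaction for
discrete-time density-regulated population dynamics: it simulates
stochastic Gompertz and Ricker trajectories, decomposes the stationary
variance of log-abundance into an environmental and a density-dependent
component, and estimates that decomposition from time-series data with
Bayesian MCMC. It is aimed at population ecologists and quantitative
fisheries/wildlife analysts who work with abundance time series.

## The model

On the natural-log scale ($y_t = \ln Y_t$) the stochastic Gompertz model
is a first-order autoregressive process,

$$y_t = r + \beta\, y_{t-1} + \varepsilon_t, \qquad
  \varepsilon_t \sim \mathcal N(0, \sigma^2)\ \text{i.i.d.},$$

where $r > 0$ is the intrinsic growth rate, $k = r/(1-\beta)$ is the log
carrying capacity, $\beta = 1 - r/k$ measures the strength of density
dependence, and $\sigma^2$ is the environmental variance. For
$|\beta| < 1$ the process is stationary with

$$\mu_\infty = \frac{r}{1-\beta} = k, \qquad
  v_\infty = \frac{\sigma^2}{1-\beta^2}.$$

The stationary variance always exceeds the environmental variance when
$\beta \neq 0$; the excess

$$\sigma^2_{dd} = v_\infty - \sigma^2 = \frac{\beta^2 \sigma^2}{1-\beta^2},
\qquad
  \varphi_{dd} = \frac{\sigma^2_{dd}}{v_\infty} = \beta^2$$

is the density-dependent component — density regulation *amplifies*
environmentally induced fluctuations, and the amplified share of the
stationary variance is exactly $\beta^2$. The package verifies this
empirically with a replicated simulation study in which the environmental
variance is re-estimated from each trajectory by MCMC (priors:
$r \sim \Gamma(1,1)$, $\beta \sim \mathcal N(0,1)$,
$\sigma^2 \sim \text{InvGamma}(0.1, 0.1)$), and shows the same pattern
when the nonlinear Ricker model
$Y_t = Y_{t-1}\exp\{r(1 - Y_{t-1}/K) + \varepsilon_t\}$ is fitted to the
same data ($r \sim \Gamma(1,1)$, $K, \sigma^2 \sim \Gamma(0.1,0.1)$).

## Worked example

```python
from densvar import (GompertzParams, MCMCSettings, analytic_decomposition,
                     simulate_gompertz, stationary_segment, fit_gompertz_bayes,
                     decompose_empirical, empirical_stationary_variance)

params = GompertzParams(r=0.4, k=1.0, sigma2=0.10)   # beta = 0.6
print(analytic_decomposition(params.beta, params.sigma2))

traj = simulate_gompertz(params, y0=1.0, n_steps=300, seed=42, n_discard=200)
v_inf = empirical_stationary_variance(traj)
print(f"empirical v_inf = {v_inf:.4f}")

post = fit_gompertz_bayes(stationary_segment(traj), MCMCSettings(seed=7))
s2 = post.parameters["sigma2"]
print(f"sigma2_hat: median={s2.median:.4f}  95% CI=({s2.q2_5:.4f}, {s2.q97_5:.4f})")
print(f"max Rhat = {post.max_rhat:.3f}")

dec = decompose_empirical(v_inf, s2.median)
print(f"sigma2_dd = {dec.sigma2_dd:.4f}   phi_dd = {dec.phi_dd:.4f}")
```

Output:

```
VarianceDecomposition(v_inf=0.15625, sigma2_env=0.1, sigma2_dd=0.056249999999999994, phi_dd=0.36)
empirical v_inf = 0.1566
sigma2_hat: median=0.1093  95% CI=(0.0835, 0.1472)
max Rhat = 1.006
sigma2_dd = 0.0472   phi_dd = 0.3016
```

Reading this: at $\beta = 0.6$ and $\sigma^2 = 0.10$ the analytic
stationary variance is 0.15625, of which 36% ($\beta^2$) is due to
density regulation. One simulated 100-point stationary segment gives an
empirical variance of 0.157; the MCMC fit recovers the environmental
variance (posterior median 0.109, credible interval covering the true
0.10) with well-mixed chains (Gelman–Rubin 1.006), and the resulting
empirical decomposition attributes a share of 0.30 to density
dependence — close to the analytic 0.36, with the shortfall typical of a
single 100-point series.

## Command line

The same pipeline is scriptable:

```bash
densvar simulate --model gompertz --r 0.4 --k 1 --sigma2 0.10 \
        --steps 300 --discard 200 --replicates 2 --seed 7 --out-dir sims
densvar fit sims/trajectory_0000.csv --model gompertz --seed 5 --out-dir fit
densvar decompose --v-inf 0.15625 --sigma2 0.10
densvar experiment --full-design --out-dir results --figures
```

`experiment --full-design` runs the full reference design (environmental
variance 0.10/0.15/0.20/0.25 × β 0.2/0.4/0.6, 100 replicates, both fitted
models) and writes long-format results, per-cell summaries, a manifest and
optional figures. Smaller designs go through `--config experiment.yaml`.

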