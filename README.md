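# bmbands

Adaptive Bayesian credible bands for nonparametric regression under a scaled
Brownian-motion prior — with honest tools for asking whether those bands mean
what they appear to mean.

## The problem

Given noisy observations on the canonical equispaced design,

    Y_i = f(x_i) + eps_i,      x_i = i / (n + 1/2),   eps_i ~ N(0, 1) iid,

a Bayesian places the prior `f = sqrt(c) W` (W standard Brownian motion) and
reports the simultaneous credible band

    C_n(c, L) = { f : sup_{x in J_n} |f(x) - fhat_{n,c}(x)| < L * w_n(c) },

where `fhat_{n,c}` is the posterior mean, `w_n(c)` is the eta-quantile of the
sup-norm of the centered posterior over an interior interval
`J_n = [1/l_n, 1 - 1/l_n]`, and `L` is an inflation constant (L = 1 is the
plain Bayesian band).  A discrete variant restricts the sup to the design
points.  The scale c — the smoothing parameter — is set from the data by

* **likelihood empirical Bayes**: `argmin_c [log det Sigma_{n,c} + Y' Sigma_{n,c}^{-1} Y]`
  over `I_n = [log n / n, n / log n]`, with `Sigma_{n,c} = I + c U_n` and
  `(U_n)_{ik} = x_i ∧ x_k`;
* **risk empirical Bayes**: minimising an unbiased estimate of the quadratic
  risk of the posterior mean; or
* **hierarchical Bayes**: a truncated inverse-gamma hyperprior
  `pi(c) ∝ c^{-1-kappa} e^{-lambda/c}` on `I_n`, with the band taken as the
  union of fixed-c bands over a hyperposterior quantile interval.

The package implements the full pipeline and the simulation harness that
measures the *frequentist* coverage of these bands: for self-similar truths
(every frequency block of the Fourier coefficients carries its share of
energy) the adaptive band covers and its width decays at the near-minimax
rate `sqrt(log n) n^{-beta/(1+2beta)}`; for truths whose Hölder smoothness is
smaller than their self-similarity order — the kink `|x0 - t|^alpha` with
`alpha < 1/2` is the canonical example — the smoothing bias eventually
outgrows the band and coverage degrades.

## What is inside

| module | contents |
| --- | --- |
| `bmbands.design` | canonical grid, discrete sine eigenbasis of `U_n`, O(n log n) coefficient transforms, the aliasing map |
| `bmbands.posterior` | O(n) tridiagonal weight solver, spectral posterior mean/covariance, exact path sampler, bias/noise decomposition |
| `bmbands.scales` | both EB criteria (spectral, O(n) per evaluation), hierarchical-Bayes hyperposterior, D-function machinery and the equaliser |
| `bmbands.bands` | Monte-Carlo sup-norm quantiles, band assembly, union bands, coverage tests |
| `bmbands.functions` | self-similar series, random prior draws, the kink, synthetic data |
| `bmbands.experiments` | coverage and width-rate simulation harness |
| `bmbands.estimators` | `BrownianBandRegressor`, a scikit-learn style front end |
| `bmbands.cli` | `bmbands simulate / fit / band / coverage` |

The numerical core avoids dense n x n algebra throughout: posterior weights
solve a tridiagonal system, the posterior precision at the design points is
tridiagonal (so sampling is O(n) per draw), and coefficient transforms run
through an FFT.  Everything is oracle-tested against dense Gaussian
conditioning at small n.

## Worked example

```python
import numpy as np
from bmbands import BrownianBandRegressor, kink_function, simulate_data, covers

truth = kink_function(x0=0.75, alpha=0.25)
sample = simulate_data(truth, n=500, seed=42)

est = BrownianBandRegressor(method="ml", eta=0.95, L=1.0, random_state=0)
est.fit(None, sample.responses)
band = est.credible_band()

print(f"selected scale  c = {est.c_:.3f}")
print(f"sup-norm quantile  w = {est.w_:.3f}")
print(f"posterior mean at x=0.5: {est.predict([0.5])[0]:.3f}")
print(f"band covers the truth on [0.1, 0.9]: {covers(band, truth)}")
```

prints

```
selected scale  c = 1.725
sup-norm quantile  w = 0.616
posterior mean at x=0.5: 0.683
band covers the truth on [0.1, 0.9]: True
```

The selected scale sits near 1.7: the kink is self-similar of order 1/2, so
empirical Bayes picks an O(1) scale regardless of n.  The 95% band at n = 500
is wide enough to absorb the smoothing bias at the kink; rerunning the same
experiment at growing n (see `ExperimentConfig` and `run_coverage`) shows the
bias-to-width ratio climbing, the mechanism behind the eventual coverage
failure for `alpha < 1/2`.  `band.to_frame()` exports `x, mean, lower, upper`
for plotting.

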