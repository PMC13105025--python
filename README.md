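# cellskew

Tools for analysing how metabolic activity is distributed among individual
microbial cells, and what that inequality means for community-level
function.

Flow cytometry with redox-sensitive dyes yields, for each sample, thousands
of per-cell fluorescence values (RFU) that proxy single-cell metabolic
activity. Across growth regimes (batch, chemostat, environmental) these
distributions are strongly right-skewed: a minority of cells performs most
of the community's metabolism. `cellskew` implements the full analysis
chain around this observation:

- **Distribution fitting** — maximum-likelihood fits of six candidate
  activity models (uniform, bimodal truncated-Gaussian mixture, truncated
  Gaussian, gamma, lognormal, Pareto), compared by AIC/BIC (|ΔIC| > 2),
  Kolmogorov–Smirnov distance, and a quantile–quantile r², plus a pooled
  bootstrap r²m across samples.
- **Inequality statistics** — the share of total activity held by the most
  active 20% of cells (a Lorenz-curve point, 0.2 under perfect equality),
  with the lognormal closed form
  `S(f) = Φ(σ − Φ⁻¹(1 − f))`, where σ is the log-scale standard deviation
  of the fitted lognormal — the single-parameter skew summary used
  throughout.
- **Productivity and ecosystems** — conversion of ³H-leucine incorporation
  counts to bacterial productivity (BP, μM C h⁻¹), an indicator-variable
  regression of σ on log₁₀(BP) across growth conditions, and intraclass
  correlation partitioning of σ variance across ecosystem types.
- **Respiration-bias simulation** — per-cell respiration follows
  Michaelis–Menten kinetics, `R = Rmax·E/(Km + E)`. Because the response is
  concave, Jensen's inequality makes mean-field predictions overestimates.
  The simulator draws mean-matched populations (Gaussian baseline vs
  lognormal with `μ_log = ln μ − σ²/2`, which holds E[E] = μ for every σ)
  and reports the index of respiration bias `IR = R̄_lognormal/R̄_Gaussian`
  over a (Km, σ) grid, with a deterministic Gauss–Hermite quadrature
  oracle.
- **Synthetic data** — seeded generators for every study condition
  (growth-phase series anchored to printed phase medians/means,
  productivity gradients, species mixtures, background controls), so the
  whole pipeline is testable without raw cytometry files.

## Worked example

```python
import numpy as np
from cellskew import (SimConfig, bias_surface, fit_mle, lognormal_top_share,
                      sigma_from_median_mean, top_share)
from cellskew.synthetic import SyntheticSpec, generate_sample

# lag-phase batch culture: median 810 RFU, mean 2,461 RFU
mu_log, sigma = sigma_from_median_mean(810, 2461)
print(f"sigma = {sigma:.3f}")                       # sigma = 1.491
print(f"top-20% share = {lognormal_top_share(sigma):.3f}")   # 0.742

# the empirical statistic agrees on simulated cells
s = generate_sample(SyntheticSpec("lognormal",
                                  {"mu_log": mu_log, "sigma": sigma},
                                  n=100_000, seed=1))
print(f"empirical share = {top_share(s.values):.3f}")        # 0.743
fit = fit_mle(s, "lognormal")
print(f"fitted sigma = {fit.params[1]:.3f}")                 # 1.490

# what this skew does to community respiration at slow saturation
surf = bias_surface(SimConfig(n=100_000, seed=1))
print(f"max mean-field overestimate = {surf.max_pct_bias:.1f}%")  # 87.8%
```

About 74% of this population's total activity is carried by its top
quintile of cells, and a mean-field (Gaussian) respiration model can
overestimate community respiration by up to ~88% at the high-skew,
high-Km corner of the simulated grid.

## Analysis scripts

The `analysis/` directory holds numbered drivers that run the study
end-to-end on synthetic data and write tidy tables under `results/`:

1. `01_simulate_data.py` — generate growth-series, community and
   productivity-gradient event tables
2. `02_fit_models.py` — gate and fit all six families, tally best fits
3. `03_inequality.py` — top-20% shares vs the lognormal closed form
4. `04_productivity_regression.py` — σ vs log₁₀(BP) indicator regression
5. `05_ecosystem_icc.py` — variance partitioning of σ across ecosystems
6. `06_respiration_bias.py` — the (Km, σ) respiration-bias surface

A `cellskew` CLI wraps the same library for ad-hoc use
(`cellskew run-all --config cfg.yaml --out results/ --seed 42`).

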