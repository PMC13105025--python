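# Methods

## Data model and gating

The unit of analysis is an `ActivitySample`: one sample's vector of per-cell
fluorescence intensities (RFU, dimensionless) from a redox-probe cytometry
run, with regime metadata (batch / chemostat / environmental / isolate /
external) and optional covariates (time in h, dilution rate in h⁻¹,
bacterial productivity in μM C h⁻¹, ecosystem label). Event tables are
long-format delimited text, one row per event; wide per-sample layouts are
deliberately unsupported to keep reading and streaming simple.

Background removal emulates the instrument-software gate drawn against
cell-free buffer controls: events are retained only if strictly brighter
than the empirical q-quantile of the control sample. The percentile used by
the original instrument workflow is not documented, so the default is
q = 0.999 — essentially "brighter than everything in the control" while
robust to a single outlying control event. Gating guarantees strictly
positive values, which the lognormal and Pareto likelihoods require.
Gate provenance (threshold, retained fraction, empty-result warning) is
recorded in sample metadata; note the retained fraction always describes
the most recent application of the gate.

## Candidate activity distributions

Six families, each encoding a generating mechanism for single-cell
activity:

| family | parameters | mechanism sketch |
|---|---|---|
| uniform | a, b | every cell contributes equally within a range |
| bimodal | w, μ₁, σ₁, μ₂, σ₂ | on/off regulation (two truncated-Gaussian modes) |
| truncated Gaussian | μ, σ | additive independent effects around a mean, support [0, ∞) |
| gamma | shape, rate | sums of sequential exponential-waiting-time steps |
| lognormal | μ_log, σ | multiplicative stochastic growth/expression dynamics |
| Pareto | α, x_m | unbounded reinforcing feedback, power-law tail |

Fitting is maximum likelihood in nats. Uniform ([min, max]), lognormal
(mean/sd of logs) and Pareto (x_m = sample minimum profiled out, α in
closed form) use exact MLEs; both Pareto parameters count as estimated
(k = 2) in AIC/BIC. The truncated Gaussian uses log-density
log φ((x−μ)/σ) − log σ − log Φ(μ/σ) with μ unbounded and σ > 0. The
bimodal form is a two-component mixture of zero-truncated Gaussians with
mixing weight w and the label constraint μ₁ ≤ μ₂, enforced by relabelling
(the likelihood is symmetric); starting values come from a median split of
the data. The original analysis never specifies its bimodal form; this
mixture is this package's concrete choice.

Optimised families (truncated Gaussian, gamma, bimodal) run bounded
L-BFGS-B from moment-based starts, gradient tolerance 1e-8, bounds clamped
1e-10 inside open endpoints. Optimizer failure or degenerate data (all
values identical) yields `converged = False` with a message rather than an
exception; non-converged fits are excluded from model selection. Truncated
normal densities use direct `scipy.special` expressions (`ndtr`,
`log_ndtr`, `ndtri`) rather than frozen distribution objects; this is
numerically identical and ~50× faster inside optimizer loops. Mixture
quantiles are found by vectorised bisection between the component
quantiles, which brackets the mixture quantile.

## Model comparison

Per sample and family: AIC = 2k − 2lnL, BIC = k·ln n − 2lnL; two fits are
treated as distinguishable only when |ΔIC| > 2, and the reported tie set
contains every converged fit within that band of the minimum. The K-S
statistic is the plain sup distance between the ECDF and the fitted CDF —
no correction for estimated parameters, since it is used as a descriptive
distance rather than a test. The Q-Q r² regresses nothing: with sorted
observations x₍ᵢ₎ and model quantiles qᵢ at plotting positions (i − ½)/n,
r² = 1 − Σ(x₍ᵢ₎ − qᵢ)²/Σ(x₍ᵢ₎ − x̄)², which is 1 for a perfect fit and can
go negative. The pooled bootstrap r²m subsamples n_sub cells (default
5,000) from the pooled data without replacement, refits, and averages r²
over repetitions (default 10,000; far fewer suffice for a stable mean and
the analysis scripts use reduced repetition counts).

A caveat worth knowing: even for data genuinely drawn from the fitted
family, the expected Q-Q r² falls with skew, because the largest order
statistics dominate the residual sum of squares (measured means at
n_sub = 5,000: ≈ 0.998 at σ = 0.5, 0.99 at σ = 0.8, 0.98 at σ = 1.0, 0.92
at σ = 1.5). High-skew r²m values well below 1 are therefore not evidence
of misfit on their own.

One-way ANOVA compares per-sample metrics across families. As the post hoc
procedure the package provides pairwise Welch t-tests with Holm adjustment;
a studentized-range (Tukey) procedure would add dependency weight without
changing any conclusion of interest here.

## Inequality statistics

The top-f share (default f = 0.2) is 1 − L(1 − f) on the empirical Lorenz
curve; fractional cell counts are resolved by linear interpolation between
Lorenz knots, which is exact for cumulative shares and independent of tie
order. Shares are computed on raw gated values, not on fitted
distributions. For a lognormal population the share has the closed form
Φ(σ − Φ⁻¹(1 − f)), independent of μ_log; this serves both as the
large-sample oracle for the empirical statistic and as the link from
printed medians/means to expected inequality, via μ_log = ln(median),
σ = √(2·ln(mean/median)) — the unique lognormal consistent with a printed
(median, mean) pair. σ is always reported from the lognormal fit even for
samples whose selected family differs (a flag records that case), because
σ is the cross-sample skew currency. A Gini coefficient is provided as a
convenience but is not part of the analysis surface.

## Productivity and ecosystem statistics

Leucine-incorporation counts convert to productivity as: CPM/efficiency →
DPM (counting efficiency default 0.643); voucher-corrected DPM → mol
leucine via 2.22×10¹² DPM Ci⁻¹ and the stock's specific activity (Ci/mmol,
a required input — only the 50 nM final concentration is documented, not
the stock activity); mol leucine → g C via molar mass 131.2 g mol⁻¹,
leucine fraction of protein 0.073, and 0.86 g C per g protein (all
configurable; the isotope-dilution factor is fixed at 1); finally g C →
μM C h⁻¹ over the incubated volume (default 1.5 mL) and duration (default
1 h). The function is homogeneous of degree 1 in net DPM and −1 in volume
and duration, which the tests assert.

The productivity–skew model is σ = β₀ + β₁·I(chemostat) + β₂·log₁₀(BP) +
β₃·I·log₁₀(BP), ordinary least squares. The interaction is dropped (and
the common-slope model refit and reported) when its two-sided p ≥ 0.05; in
the zero-residual degenerate case where p is undefined, the interaction is
dropped only when its estimate is numerically zero. Rank-deficient designs
raise an error naming the columns.

The intraclass correlation uses the one-way random-effects
method-of-moments estimator, ICC = (MSB − MSW)/(MSB + (n₀ − 1)·MSW) with
n₀ = (N − Σnᵢ²/N)/(k − 1) for unbalanced groups, clamped to [0, 1]. A
REML mixed model estimates the same quantity; the moment estimator was
chosen because it is exactly testable by hand and carries no extra
dependency. The grouping variable (ecosystem type) is an explicit input.

## Respiration-bias simulation

Per-cell respiration is R = Rmax·E/(Km + E). Defaults are the study
conditions: n = 10⁶ cells per draw, mean activity μ = 10⁵ (arbitrary
units), Gaussian baseline sd 0.25μ with negative draws floored to 0.1
(10⁻⁶μ — the flooring touches ~Φ(−4) ≈ 3×10⁻⁵ of draws and is numerically
irrelevant, which tests assert), Rmax = 1, Km ∈ {10², 10³, 10⁴, 10⁵}, and
σ ∈ {0.01, 0.1, 0.2, …, 3.5} (36 values; the source ranges are stated
without step sizes, so decade Km spacing and 0.1 σ steps are this
package's grid). The lognormal arm is mean-matched by μ_log = ln μ − σ²/2.
IR is the ratio of the two simulated mean respirations, each from an
independent draw (a shared-baseline variance-reduction mode is not the
default because IR is defined as a ratio of two simulated means).
Substreams are derived from the master seed by hashing the (Km, σ,
distribution) values themselves, so refining or reordering the grid never
perturbs existing cells.

The deterministic oracle computes E[R] by 128-node Gauss–Hermite
quadrature over the latent normal for the lognormal arm (relative error
< 1e-8 up to σ = 3.5; 64 nodes give ~5×10⁻⁶ at the extreme corner) and by
adaptive quadrature over the *floored* Gaussian — exactly the law the
Monte-Carlo draws, including the point mass at the floor — for the
baseline.

With these parameters the bias (1 − IR)·100 increases with σ and with Km:
at μ = 10⁵, larger Km means the response saturates more gradually, so the
low-activity majority of a skewed population drags the mean response down
relative to the symmetric baseline. The grid maximum sits at (σ = 3.5,
Km = 10⁵) at ≈ 88% by quadrature, comfortably above the "more than half"
headline. Note a figure-caption convention elsewhere describes the bias as
greatest at *low* Km; the equations with mean activity 10⁵ imply the
high-Km direction, which both the simulation and the quadrature oracle
confirm, so that caption appears to be a slip.

## Synthetic data: what it does and does not emulate

Generators produce i.i.d. draws from the six families; growth-phase series
are single lognormals anchored to the printed phase medians and means
(lag: 810/2,461 → σ ≈ 1.49; exponential: 93,083/111,569 → σ ≈ 0.60;
stationary: 60,734/63,203 → σ ≈ 0.28); productivity gradients draw σ from
condition-specific lines in log₁₀(BP) (default slope −0.14, intercepts
0.8/1.6 — a twofold offset) with Gaussian noise resampled (up to 100
attempts) to keep σ > 0; mixtures assign species per cell categorically so
cells stay i.i.d.; background controls are exponential with configurable
scale (the control distribution is otherwise undocumented — only its use
as a gate). All generators are bit-reproducible under a seed, with
per-sample substreams hashed by value so adding samples never perturbs
earlier ones.

Not emulated: instrument noise physics, doublets and scatter-channel
structure, autofluorescence spectra, non-lognormal batch-phase shapes
(family is exposed as a knob rather than asserted), and any temporal
autocorrelation between samples. Passing tests therefore validate the
statistical machinery under the assumed generative models, not the
biological claim that real communities are lognormal.

## Verification strategy and problem sizes

Every stochastic claim is checked against an independent oracle: K-S
against a dense-grid brute force (agreement to 1e-12 at n ≤ 100),
Monte-Carlo mean respiration against quadrature (within 3 Monte-Carlo
standard errors on a 3×3 spot grid), empirical top shares against the
closed form (within 0.01 at n = 10⁵), and parameter recovery within
3-standard-error bands in ≥ 95% of 100 replicates at n = 10⁴ per family.
For the non-regular extreme-value estimators (uniform endpoints, Pareto
x_m) a 3σ Gaussian band has no 99.7% coverage — their error laws are
exponential-type — so the equal-coverage 99.73% quantile of the exact
error distribution is used instead. Model recovery requires the AIC-best
family to be the generating one in ≥ 90% of 20 replicates per family at
n = 10⁴ (parameters chosen away from degenerate corners; note the bimodal
family nests the truncated Gaussian, so occasional ΔAIC ≤ 2 ties on
Gaussian data are expected, not errors).

The analysis drivers default to 10⁴ cells per sample and 10⁵ cells per
simulation grid cell, sizes at which every qualitative conclusion is
stable; the acceptance script runs the bias surface at the full 10⁶ cells
per grid cell.

## Known limitations

- The bimodal family's starting values assume reasonably separated modes;
  heavily overlapping components can converge to a local optimum (reported
  honestly via the likelihood, not detected specially).
- The Pareto x_m = min(data) convention makes the fitted support start at
  the smallest observation; alternative conventions (fixed x_m) would
  change α̂ and the IC ranking for heavy-tailed-but-not-Pareto data.
- bootstrap r²m interpretation at high skew (see above).
- The leucine→carbon conversion constants are literature defaults; any
  site-specific calibration must be supplied by the caller.
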