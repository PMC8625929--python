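# Methods

This note documents the models, the synthetic-data design, the numerical
choices and the known limitations of `winsorbnn`.

## Winsorization

For a sample x₁,…,xₙ and limit α ∈ [0, ½), write the order statistics
X₍₁₎ ≤ … ≤ X₍ₙ₎. When α·n is an integer k, Winsorization replaces the
smallest k values with X₍ₖ₊₁₎ and the largest k with X₍ₙ₋ₖ₎. For
non-integral α·n the replacement bounds are linearly interpolated between
adjacent order statistics (continuous 0-based position α·n at the bottom,
(1−α)·n − 1 at the top), which is continuous in α and coincides with the
order-statistic rule at integral α·n. Element order is preserved; α = 0 is
the identity.

On datasets, replacement quantiles are estimated per variable from the
pooled training and validation rows and applied by clipping to those same
rows; test rows are never consulted or modified. Which variables are
clipped follows the contamination site under study (target-site noise →
target only; feature-site → features only; both → both; in the noise-free
condition both are clipped), with an explicit override available. Note
that Winsorization with *re-estimated* quantiles is idempotent only at
integral α·n; with the fitted bounds held fixed (the `WinsorSpec`
returned by `winsorize_dataset`) re-application is always a no-op, which
is what the experiment pipeline relies on.

A known variant adds small random noise to the 2αn replacement values; it
is not implemented.

## Contamination design

Noise is additive i.i.d. Cauchy(location 0, scale 1 — "standard") applied
to the raw, unstandardized variables, at one of four sites (none, target,
features, both) and to a configurable set of splits (train+val by
default; adding `test` gives the contaminated-test condition). Draws come
from per-row streams keyed by (seed, row index, site-stream), so
(a) whether other rows are in the contaminated subset never changes a
row's draws, and (b) target draws and feature draws are independent. The
`both` site reuses the target-stream draw for the target — the draws are
not resampled — and independent feature-stream draws for the features.

## Gaussian processes

**Exact GP.** Constant prior mean set to the training-target mean; RBF
covariance with amplitude a and lengthscale ℓ, the only two trainable
hyperparameters. The observation-noise variance is *fixed* (default 1e-2
on the standardized target scale) rather than learned, keeping the
trainable count at two; it is configurable. Hyperparameters maximize the
log marginal likelihood by L-BFGS-B with analytic gradients in
(log a, log ℓ), initialized at a = 1 and ℓ = the median pairwise training
distance; if the optimizer terminates worse than the initialization the
initialization is kept, so the final objective never falls below the
initial one. Features and target are z-scored with (post-treatment)
training statistics — GPs are scale-sensitive — and predictions are
reported back on the original scale. Cholesky factorizations add jitter
1e-6 to the diagonal, escalating ×10 to at most 1e-2 before raising a
numerical-failure error.

**Sparse variational GP.** q(u) = N(m_u, S_u) at m inducing locations Z
(default 64, initialized by seeded subsampling of training rows). The
per-point bound

L′ = Σᵢ [ log N(yᵢ | kᵢᵀK⁻¹ₘₘ m_u, β⁻¹) − (β/2)·k̃ᵢᵢ − ½·tr(S_u Λᵢ) ]
     − KL[q(u)‖p(u)],

with k̃ᵢᵢ = kᵢᵢ − kᵢᵀK⁻¹ₘₘkᵢ and Λᵢ = β K⁻¹ₘₘ kᵢkᵢᵀ K⁻¹ₘₘ, is maximized
jointly over Z, q(u), (a, ℓ) and β by variational EM: gradient ascent
(Adam, 300 iterations, learning rate 5e-2) on the collapsed form
log N(y | 0, K_nm K⁻¹ₘₘ K_mn + β⁻¹I) − (β/2)tr(K̃) — which is L′ already
maximized analytically over q(u) — with q(u) set to its closed-form
optimum at each checkpoint. The best checkpoint by bound value is
returned, so the final bound never falls below its initial value. With
Z = X the trace term vanishes and the bound equals the exact log marginal
likelihood, which the tests verify numerically; the uncollapsed L′ is
exposed separately (with its KL/fit decomposition) for bound-property
checks.

## Neural models

All three neural families use a fully connected rectifier backbone. The
benchmark's reference architecture has hidden widths 52, 250, 300, 450,
202, 452, 50, 300, 200, 52, 400, 350, 450, 450 (the `full` preset); the
default experiment profile and the test suite use a `small` preset of two
32-unit layers, because the protocol repeats dozens of fits and the
qualitative robustness conclusions do not depend on network depth at the
problem sizes used here.

Training is full-batch Adam (learning rate 1e-3), with early stopping on
the validation loss at patience 20 — early stopping is on by default since
long training mainly learns the contamination. Inputs are z-scored and
targets centred/scaled by post-treatment training statistics; metrics are
computed on the original scale. A non-finite loss raises a
training-failure error, never a silent result; the grid runner records
such cells with a failure flag and excludes them from optimal-limit means.

**Concrete dropout.** Each layer's dropout probability pᵢ is trained
through its logit. The Bernoulli mask is replaced by the concrete
relaxation z̃ = sigmoid((log p − log(1−p) + log u − log(1−u))/t) with
temperature t = 0.1, giving pathwise gradients. The variational
regularizer per layer is l²(1−p)‖W‖²/(2N) + ‖b‖²/(2N) − K·H(p)/N with
prior lengthscale l = 1e-2, K the number of weights in the layer, H the
Bernoulli entropy, and N the training-set size; the precision is absorbed
into a heteroscedastic Gaussian head (the network outputs mean and
log-variance, and the data term is the heteroscedastic Gaussian NLL).
Dropout probabilities initialize at 0.1. Dropout stays active at test
time: the predictive mean and epistemic sd are the sample statistics of
S = 100 stochastic forward passes.

**Flipout.** Designated layers (all, or the early/middle/final five —
clipped to the network depth when shallower) carry a mean-field Gaussian
posterior W ~ N(μ, softplus(ρ)²) with a standard-normal prior; ρ
initializes at −5 (posterior sd ≈ 7e-3). The objective is the closed-form
Gaussian KL plus a Monte-Carlo Gaussian NLL with a learned homoscedastic
noise scale; the KL is scaled by batch/N so one epoch weighs it once. A
shared base perturbation ΔŴ = softplus(ρ)⊙ε is decorrelated across the
minibatch with per-example ±1 sign vectors: the batched computation is
x·μ + ((x⊙s)·ΔŴ)⊙r. The sign modulation preserves elementwise magnitudes,
averages to exactly zero over the four sign patterns, and measurably
lowers minibatch gradient variance relative to a shared perturbation
(both verified in tests).

**Mixture density network.** The head emits 3K values per input: mixture
logits (softmax to π), component means, and pre-softplus scales
(softplus + floor 1e-3). The loss is the mixture NLL via log-sum-exp,
which agrees with the naive density computation wherever the latter is
representable. The last-layer mean biases initialize spread over [−1, 1]
so components can separate. Predictive moments are the closed-form
mixture mean and total-variance sd. Unlabeled "MDN" rows in summaries
mean K = 2; K = 4 is spelled `mdn:4`.

**Uncertainty reporting.** For the sampled models the reported predictive
sd is the spread of the mean prediction across stochastic passes — the
epistemic component; the concrete-dropout aleatoric variance head is
available on the model but deliberately not folded into the summary
statistic. GPs report the closed-form posterior sd (including the noise
term), the MDN its mixture sd.

## Trend + seasonal adjustment (series archetype)

Y_t = μ_t + μ_{t,month} + f(X_t): a linear trend in the integer time index
fit by OLS, per-month seasonal means of the detrended series, and a
probabilistic regressor on the residual, re-trended for evaluation. The
residual model consumes the original feature columns (time index and its
annual harmonics), not lagged residuals. Trend and seasonal components
are estimated from training rows only; months absent from training keep a
zero seasonal mean with a warning. Series splits are contiguous in time
(train earliest) because a random split would leak the trend into the
hold-out.

## Synthetic-data design

Each generator is a pure function of its arguments and stores its planted
parameters in a provenance record, so recovery tests compare against
stored truth rather than re-deriving it.

* **crop** — rows are site-year pairs; 365-day tmax/tmin/precipitation
  curves with a seasonal sinusoid, a latitude-dependent temperature level,
  and nonnegative gamma precipitation with a summer peak; plus longitude,
  latitude, and their cosine/sine transforms (p = 1101). Yield = intercept
  4.0 − 0.25·(lat − 43) + 0.35·(growing-season mean tmax − 20) −
  0.8·(harvest-window mean precipitation − 3) + N(0, 0.5²): the negative
  harvest-precipitation coefficient encodes that wet harvests hurt yield.
  Default desk scale: 30 sites × 10 years = 300 rows.
* **tabular / heavy_tail** — 8 standard-normal features; the mean is
  linear + sinusoid + one interaction with seeded coefficients; noise sd
  0.5. The heavy-tailed variant pushes the standardized response through
  an amplified softplus, which makes the sample skewness positive.
* **series** — 480 months, slope 0.05/month, a 12-month sinusoidal
  seasonal pattern of amplitude 2, noise sd 0.3. The month-effect vector
  is adjusted (a weighted projection off the span of the constant and the
  mean-time-per-month) so the seasonal block is orthogonal to the linear
  trend while remaining a pure function of calendar month; OLS then
  recovers the slope exactly at zero noise, and the stored
  `seasonal_effective` values are exactly recoverable.
* **highdim** — 300 samples × 238 features from 4 latent group centroids
  with block-correlated noise; the target depends on 10 seeded columns.
* **multimodal** — scalar input; the conditional response is a mixture of
  well-separated Gaussians (component sd 0.3, symmetric offsets) around
  an odd base curve, for MDN component-recovery checks.

What the generators do *not* emulate: spatial autocorrelation beyond the
latitude trend, temporal dependence in the weather curves, measurement
censoring, covariate shift, and real-data missingness. Passing tests
therefore demonstrate that the pipeline behaves correctly under the
modeled contamination mechanism, not that any model is robust on a
particular real dataset.

## Experiment orchestration

Cell seeds derive from a stable CRC32 hash of (repetition seed, cell
key), so a grid subset reproduces the corresponding full-grid cells bit
for bit, and data for a given (archetype, repetition) are shared across
models, limits and conditions — pre/post-treatment comparisons and
relative efficiencies are computed on identical draws. The limit grid
defaults to {0, 0.01, 0.05, 0.10, 0.15, 0.20, 0.25}; the "optimal" limit
minimizes the seed-mean Winsorized test MSE, with ties broken toward the
smaller limit (less information loss). The default repetition count is 5
seeds. The contaminated-test condition draws test-row noise from an
independent stream at the same site. Failed fits are flagged, logged, and
excluded from limit selection with their count visible in the records.

The R² on contaminated test sets uses the contaminated targets' own
variance as the reference (the targets are evaluated as given).

## Numerical choices

* Reverse-mode autodiff engine: gradients of all primitives (including
  the PSD solve and log-determinant adjoints) are finite-difference
  checked; log-sum-exp uses a constant max shift, which leaves gradients
  exact.
* Gradient clipping at ±100 elementwise protects early training under
  extreme (contaminated) targets.
* GP jitter 1e-6 escalating ×10 to 1e-2; oracle tests that need exact
  agreement set jitter near zero explicitly.
* Quantiles: sorted-sample linear interpolation at the order-statistic
  positions described above (not the default numpy quantile convention,
  which would disagree with the integral-α·n replacement rule).
* Optimal-limit ties: smaller α wins. Degenerate inputs (constant
  features, constant test targets, singular trend designs) raise typed
  errors or warnings rather than producing silent numbers.

## Problem sizes

The default profiles are desk-scale: ≤ 500 rows per dataset (300 for the
1101-feature crop archetype), the small network preset, 300 training
epochs with early stopping, S = 100 predictive passes, 5 repetition
seeds. These sizes were chosen so the full protocol and its tests run in
minutes on a single CPU while leaving every qualitative contrast (clean
vs contaminated, raw vs Winsorized, per-site behavior) clearly resolved.
The `full` architecture preset and larger n are opt-in through the
experiment config.

## Known limitations

* The observation-noise variance of the exact GP is fixed, not learned;
  badly mis-scaled targets would need the config override.
* The flipout likelihood is homoscedastic; only concrete dropout carries
  a heteroscedastic head.
* The sparse GP optimizes the collapsed bound; minibatch (stochastic)
  variational inference is not implemented, so it shares the exact GP's
  O(n²)–O(n³) scaling in the fit, acceptable at desk scale.
* Winsorization variants (asymmetric limits, noise-dressed replacements,
  residual Winsorization, trimming) are out of scope.
* No significance testing between methods is performed; summaries are
  seed means/medians.
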