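# Methods

## The model

`popcode` implements an idealized population code for stimulus
orientation.  Orientation is a circular variable with period 180°; the
interval (−90°, 90°] is mapped linearly onto the circle (−π, π] and all
internal computation happens on that doubled circle.

**Encoding.**  M neurons have Von Mises tuning curves with concentration
κ and preferred orientations φᵢ evenly spaced on the circle.  A sigmoidal
contrast-response function g(c) = cᵅ/(cᵅ + σ_cᵅ) — a hyperbolic ratio,
i.e. a logistic in log contrast — multiplies all rates.  The mean rate of
neuron i to a stimulus (θ, c) is

    rᵢ = η + g(c) · γ · exp(κ cos(θ − φᵢ)) / (M I₀(κ)),

with population gain γ (spikes/s) and optional per-neuron baseline η.
The normalisation makes the summed stimulus-driven rate equal γ·g(c)
independently of κ and M (discretisation error < 0.5 % for M ≥ 100,
κ ≤ 10; asserted in the test suite), so the expected total spike count in
a decoding window of length T is ξ = T(γ g(c) + M η).  Spike counts are
independent Poisson draws with means rᵢT; the total count is therefore
Poisson(ξ).

**Decoding.**  The observer reads out the maximum a-posteriori
orientation under a uniform prior (equivalently, maximum likelihood).
Dropping count-independent terms, the log posterior is
Σᵢ nᵢ log rᵢ(θ).  For η = 0 this is κ·Re(z·e^{−iθ}) with
z = Σᵢ nᵢ e^{iφᵢ}, so the decoded orientation is the resultant direction
of the spike-weighted preferred orientations, and the posterior is Von
Mises with concentration κ|z|.  With baseline activity the posterior is
evaluated on a grid (1024 points by default).  Zero total count — and the
measure-zero event of an exactly vanishing resultant — leaves a uniform
posterior; the decoder then guesses uniformly at random and the trial is
flagged.  The report is the decoded orientation plus a response bias β.

**The error distribution.**  Writing each spike as a unit step in the
direction of its neuron's preferred orientation, the decoding error given
m spikes is the resultant direction of an m-step Von Mises(0, κ) random
walk.  Conditional on the walk's resultant length r the error is
VM(0, κr); the density of r is the uniform-walk resultant density
exponentially tilted by I₀(κr)/I₀(κ)^m; and m is Poisson(ξ).  The
marginal error density is therefore

    p(Δθ) = e^{−ξ}/(2π) + Σ_{m≥1} Pois(m; ξ) · E_r[ VM(Δθ; 0, κ r) ],

shifted by β.  This mixture is not a Von Mises: it develops a sharp peak
with long tails at intermediate ξ (positive circular-kurtosis excess),
approaches a circular normal at high ξ, and flattens to uniform as
ξ → 0.  That progression is the package's central prediction and is
asserted directly in the acceptance tests.

## Numerical scheme for the error density

* The uniform-walk resultant densities r·ψ_m(r) for m = 1…100 are
  tabulated by Monte Carlo with 10⁶ walkers and 10³ bins per m, built in
  a single pass (each walker is extended one step at a time) with a fixed
  internal seed, so likelihoods are reproducible to machine precision.
* Exponential tilting of a Monte-Carlo histogram is only valid while the
  tilted mass lies in a well-sampled region of the uniform walk.  The
  tilted distribution concentrates near r ≈ m·A(κ), A = I₁/I₀, where the
  uniform walk has probability ~e^{−mA²}; the tilted table is therefore
  used only while m·A(κ)² ≤ 8 (≈ 335 expected walkers beyond that
  radius).
* For larger m the conditional error density is computed as the direction
  density of the resultant vector under a bivariate normal approximation
  with the exact per-step trigonometric moments (mean (mA, 0), variances
  m·var(cos ε), m·var(sin ε)) — the offset-normal ("projected normal")
  distribution, evaluated in log space.  Unlike a single matched Von
  Mises, this captures the spread of the resultant length, which is what
  keeps the high-gain kurtosis excess near its true, small value.
* Both routes were validated against brute-force Von Mises walks: total
  variation ≤ ~0.01 throughout their operating ranges, ~1 % mutual
  disagreement at the switch point (asserted in the tests).
* The Poisson sum is truncated at its 1 − 10⁻⁸ quantile and the density
  renormalised on the grid.  The default grid has 1024 points; during
  optimisation a 512-point grid is used and each tilted conditional is
  compressed to ≤ 80 equal-mass components (TV error < 2·10⁻³ against
  the full computation, asserted).

## Fitting

Three models are fitted to trial tables by maximising the summed log
density of the per-trial errors, using Nelder-Mead on transformed
parameters (log for positive parameters, logit for probabilities), with
multiple jittered starts around a moment-based initializer and a final
restart ("polish") from the incumbent.  Soft quadratic penalties keep the
search inside generous boxes (e.g. γ ≤ 3000 Hz, i.e. ξ ≤ 300 at
T = 100 ms); density values are floored at 10⁻³⁰⁰ before logs.

* **Population coding model** — five parameters (γ, κ, β, α, σ_c).  The
  expected count at each contrast is ξ(c) = γ T g(c); one conditional
  matrix per κ is shared across contrast conditions.  If trials carry an
  absolute-contrast column it feeds the contrast-response function;
  otherwise threshold-relative contrast is used and (α, σ_c) absorb the
  per-subject threshold scale.
* **Threshold model** — each trial is "seen" with contrast-level
  probability p_c (VM error with SD σ_seen and bias β) or unseen
  (uniform).  Degenerate fits (all p_c ≈ 0, or a near-uniform seen
  component, a flat ridge in (σ_seen, p)) are flagged in the results
  notes.
* **Two-stage model** — a circular-normal first stage with per-contrast
  SD, circularly convolved (FFT on the grid) with the population-decoding
  density at shared (ξ, κ).

The moment initializer inverts per-contrast-level precision through the
high-gain limit (precision ≈ κ A(κ) ξ) to seed ξ per level, reads γ off
the top level, places σ_c at the half-maximum crossing in log contrast,
and takes β from the circular mean at the highest contrast.

Models are compared with AICc (−2LL + 2k + 2k(k+1)/(n−k−1); undefined
and reported as NaN when n ≤ k+1) and BIC (−2LL + k ln n).

Standard errors, when requested, come from a finite-difference Hessian of
the negative log likelihood in the transformed space, propagated to the
natural scale by the delta method.

A caution for users: with four contrast levels and ~1600 trials the
likelihood has a flat ridge trading γ against κ (their product near
κ·A(κ)·γ·T sets precision; only higher-order shape separates them).
Individual ML estimates of γ scatter widely (right-skewed) along this
ridge even when the optimizer verifiably reaches the maximum; medians
over replicate datasets are the meaningful recovery summary, and the
reported standard errors are correspondingly large.

## Detection

The 2AFC observer compares total spike counts in the stimulus and null
intervals and picks the larger, flipping a fair coin on ties (the tie
policy implied by a 50 % guessing rate).  Because only totals matter,
each interval is simulated as a single Poisson draw (Poisson
superposition; asserted against full-vector simulation).  With η = 0 the
null interval is always silent and the 75 %-correct threshold has the
closed form g(c*) = ln 2/(γT), hence c* = σ_c (q/(1−q))^{1/α} with
q = ln 2/(γT); the threshold does not exist when γT ≤ ln 2.  With
baseline activity the psychometric function is estimated by Monte Carlo
on a contrast grid and the threshold read off by monotone interpolation
(cumulative-maximum smoothing) at 0.75.

## Analyses

* Precision is 1/σ² with σ the Fisher circular SD √(−2 ln R̄); chance
  level is reported from matched-size uniform samples.
* Deviation-from-normality curves bin the errors (25 bins over (−π, π]
  by default, configurable) and subtract the binned probability of the
  Von Mises matched in circular mean and variance.
* Median splits are taken within contrast level; ties at the median are
  assigned uniformly at random (seeded) so halves are balanced to within
  one trial.  An optional reference summary yields a mean squared
  difference of precisions across (level × half) cells, in precision
  units squared.
* Confidence-error correlations are computed per subject and contrast
  level between the (numeric 0–100) rating and absolute circular error;
  group tests apply Fisher's z transform before a one-sample t test.
* The anisotropy control estimates per-stimulus-bin bias and dispersion
  (15 bins), resamples reports from the corresponding Von Mises
  distributions, and feeds the pooled synthetic errors through the
  deviation-from-normality analysis; empty bins inherit their nearest
  neighbour's parameters with a warning.
* Baseline matching grid-searches (γ, κ) for the η-baseline model whose
  simulated error histograms (decoded on a grid, uniform per-trial
  stimulus orientations) minimise the summed total-variation distance to
  the no-baseline model's analytic densities over the four contrast
  levels (60 histogram bins).  The choice of total variation as the match
  criterion is the package's own; with 10⁴ simulations per grid point the
  attainable distance floor is Monte-Carlo noise (~0.15–0.2 summed over
  four contrasts), so fine structure of the distance surface below that
  floor is not interpretable.

Simulations draw the stimulus orientation uniformly per trial, as in the
experimental design.  This matters beyond realism: with M = 100 discrete
preferred orientations, a fixed stimulus leaves single-spike decodes on a
100-point lattice whose aliasing against histogram bin edges fabricates
apparent density mismatches an order of magnitude above the true
discretisation error.

## Synthetic data

The generator emulates the study's design: 8 subjects, 280–480 trials
each, uniform random orientations, contrasts drawn from
{50, 100, 200, 400} % of a per-subject detection threshold computed from
that subject's own parameters via the closed form above.  Per-subject
generating parameters are log-normal around the group means
(γ = 145 Hz, κ = 2.40, α = 48.2, σ_c = 0.096, β = −0.050 rad) with
per-parameter coefficients of variation equal to the reported
between-subject dispersions (γ: 92/145, κ: 0.58/2.40, α: 16.6/48.2,
σ_c: 0.0081/0.096; β jittered with SD 0.028 rad).  Note a structural
consequence of threshold-relative contrast with a steep contrast-response
function: the expected count at the 100 % level is pinned at ln 2 for
every subject, the 50 % level is effectively invisible (ξ ≈ 0), and the
200/400 % levels are both near-saturated.

Confidence is generated as a logistic-scale latent score of log posterior
precision plus Gaussian noise (temperature 0.6), quantised by fixed cut
points into {0, 25, 50, 75, 100}.  This mechanism is synthetic-only: the
behavioural study records confidence but does not model its generation.
The generator likewise omits motor noise in the response bar, stimulus
anisotropies (orientation-dependent biases), reaction times and the
adaptive staircase.  Passing tests on synthetic data therefore
demonstrate that the pipeline recovers the structure this generator
produces — not that real observers contain no additional error sources.

## Degenerate inputs and edge conventions

* Angles wrap to (−π, π]; the boundary −π maps to +π.
* A zero resultant reports undefined mean direction (NaN) and infinite
  circular SD; precision is 0 for maximal dispersion and ∞ for a
  degenerate point mass.
* κ ↔ σ conversions use σ = √(−2 ln A(κ)); the inverse inverts the
  Bessel ratio numerically.
* Fits with a single contrast level flag (α, σ_c) as unidentifiable;
  threshold-model fits flag the uniform-data ridge.
* The Rayleigh/V-test p value uses the large-sample normal approximation
  u = V√(2/n).

## Known limitations

* Homogeneous tuning widths, no interneuronal correlations, Poisson
  dispersion exactly 1 — deliberate idealisations of the underlying
  model.
* M = 100 stands in for the infinite-population limit (rate
  normalisation verified to < 0.5 %).
* The pooled correlation between total spike count and posterior
  precision is high (r² ≈ 0.9 at the group-mean parameters) because
  posterior precision is nearly linear in the count at moderate-to-high
  gain; analyses that rely on these two criteria disagreeing will find
  them nearly interchangeable, which is precisely why the two median
  splits produce indistinguishable precision curves.
* Problem sizes used by the test suite and the acceptance script (10⁵
  simulated trials per density comparison, 10⁴ per contrast level for
  correlation analyses, 20 replicate fits of 1600 trials, 10⁴
  repetitions per baseline-matching grid point) were chosen as the
  package's default desk-scale experiment; all are configurable.
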