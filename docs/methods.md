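# Methods

## Model family and estimation

All three observer models are one discrete Kalman filter on the state
X = [x, m] (current stimulus and current distribution mean in log
coordinates) with transition F = [[0, 1], [0, 1]], observation H = [1, 0],
process covariance Q = diag(v, q) and measurement-noise variance r.  Because
scaling (v, q, r) jointly leaves the filter invariant, r ≡ 1 and the ratios
v/r and q/r are fitted directly.  The model kinds are constraints: q = 0
(static), v = 0 (simple iterative), both free (two-state).  d₀, the
constant of the logarithmic transform z = ln(1 + d/d₀), is a fixed property
of the dataset (default 1 linear unit), not a free parameter, keeping the
free-parameter count at three (v/r, q/r, Δx).

**Transforms.**  The forward transform is z = ln(1 + d/d₀).  Its exact
inverse d̂ = d₀·(exp(x̂ + Δx) − 1) is the default back-transform, so the
Δx = 0 roundtrip is the identity and testable to machine precision.  The
convention d̂ = d₀·exp(x̂ + Δx) is available via
`back_transform(..., paper_literal_inverse=True)`; the two agree for
d ≫ d₀, which holds for duration/distance data measured in small units.

**Initialization.**  x̂₀ = m̂₀ = z₁ and P₀ = diag(10·(v + q + 1)) — a
diffuse start whose influence decays within a few trials, so the steady
state dominates.  The first response is emitted at trial 1 after the first
update (its innovation is zero by construction).

**Gains.**  The gain recursion is data-independent, so the filter computes
the gain sequences once per parameter value, runs the exact time-varying
recursion until successive gains change by < 1e−12, and continues with the
constant-gain form (the mean update is then an exponential smoother,
evaluated by a vectorized IIR filter).  This is an exact reformulation, not
an approximation: the full dense-matrix recursion and the fast path agree
elementwise to 1e−9 in tests, and to an independent state-space library to
1e−9.  `steady_state_gains` seeds the covariance iteration with the
closed-form nonnegative root of the Riccati fixed point p² = q·(p + v + 1)
and polishes by iterating; the closed form is needed because at q = 0 the
recursion converges only harmonically (the mean gain decays like the weight
of a running average), which also means gain "convergence within a few
trials" holds for q > 0 but not in the exact static limit — the tests
document grids where convergence within 50 (moderate ratios) or 200
(extreme v/q) trials holds at tolerance 1e−10.

**Fitting.**  Parameters are estimated by nonlinear least squares in the
linear stimulus domain: the filter consumes the stimuli in presented order
and the squared distance between observed and simulated responses is
minimized (trust-region reflective, variance ratios bounded at 0).  Eight
starts from a log-spaced grid over the ratios in [0.01, 10] (Δx = 0) guard
against local minima.  95% confidence intervals are linearized:
cov(θ) = s²(JᵀJ)⁻¹ with s² = SSE/(n − p) and J the finite-difference
Jacobian of the residuals at the optimum (central differences, forward
against an active bound); a singular JᵀJ yields unbounded intervals for the
parameters in its null space.  Monte-Carlo checks at moderate noise put the
realized coverage near the nominal level.

**Model selection.**  Windowed leave-one-out for time series: for every
validation centre t (each trial except the first, which has no prediction
history), the k trials centred on t are excluded from the fitting loss —
window truncated at the sequence edges — and only the squared error at t
counts.  The refits start from the full-data optimum (single start; the
objective changes little when 11 of 400 residuals are masked).  The filter
always consumes the full stimulus sequence: stimuli are known to the
observer, so deleting them would alter the state trajectory, whereas only
the held-out *responses* are out of sample.  The model with the smallest
mean validation error is chosen; near-ties (relative difference < 1e−12) go
to fewer free parameters.  k defaults to 11, with k = 3 and k = 1 (plain
LOO) exposed.

## Synthetic data

The generator emulates a two-condition magnitude-reproduction design:

* **Random-walk condition** — cumulative sums of N(0, step_sd²) increments
  starting at the midpoint of the bounds (default 400–1900 ms).  Whole
  sequences are rejection-sampled from fresh sub-seeds until all values lie
  within bounds (cap 10,000), preserving exactly Gaussian increments;
  reflection would distort them.  The default step SD is calibrated by
  bisection so that ~10% of unconstrained length-n walks stay within
  bounds — large enough to sweep the range, small enough to be sampleable.
* **Randomized condition** — the same values in scrambled order (exact
  multiset copy), as in the blocked two-session design.
* **Observers** — per-subject parameters drawn uniformly from the ranges
  estimated across real subjects: v/r ∈ [0.20, 4.12], q/r ∈ [0, 0.66].  Δx
  is drawn from ±0.05 (small global over/under-reproduction); the paper
  family gives no distribution for it.  Response noise is Gaussian in the
  log domain with SD 0.1 log units (≈10% coefficient of variation, a
  typical reproduction variability), applied to the filter output before
  back-transforming so linear responses stay positive.  A response-noise
  model is a design choice here; the estimation framework itself is
  deterministic given the stimuli.
* Default cohort: 14 subjects × 2 conditions × 400 trials, everything
  derived from one master seed (byte-identical tables on rerun).

What the generator does **not** emulate: lapses and outliers, motor noise in
linear units, feedback-driven adaptation, range drift across sessions, and
any reaction-time structure.  Passing tests on these cohorts therefore show
that the estimation and selection machinery is correct and well-calibrated
under the model's own assumptions, not that real observers satisfy them.

### Histogram matching

`match_histograms` tunes a generator's variance parameters so its marginal
distribution matches a reference sequence's: KL divergence between 20
equal-width histogram bins spanning the union of both ranges, additive
smoothing 1e−9 per bin before normalization, reference sequence as the
reference distribution.  Minimization is two-stage: a coarse log-spaced
parameter grid evaluated over a pool of candidate realizations, then
Nelder–Mead refinement of the log variance parameters around the best few
candidates.  Realization selection is part of the procedure: the occupation
histogram of a (bounded) random walk does not self-average — staying within
bounds requires step·√n small while mixing requires it large — so a matched
sequence is necessarily an exemplary realization.  For the two-state
generator, plain KL minimization over (v, q) is degenerate (q → 0
reproduces the i.i.d. reference itself), so the coarse stage pins the v : q
mix to a target lag-1 autocorrelation (default 0.66, the value the matched
sequences are built to exhibit; within one realization a length-n walk
contributes ≈ q·n/6 of empirical variance, giving
ρ ≈ (qn/6)/(qn/6 + v)), and the refinement rejects candidates whose
realized lag-1 autocorrelation falls below half the target.

With a 1000-sample reference and 20 bins, the expected KL between two
empirical histograms of the *same* distribution is ≈ (k − 1)/n ≈ 0.019, so
achieved divergences of ~0.015–0.025 are at the noise floor of this
estimator; materially smaller values would require longer sequences or
fewer bins, not better matching.

## Bias metrics

All metrics are computed in the linear stimulus domain on raw trials
(computing them on log-transformed data gives different numbers; tests pin
the convention).  Central tendency c = 1 − OLS slope of response on
stimulus.  Sequential dependence s = OLS slope of the current error
(response − stimulus) on the previous stimulus, trials 2…n; trial 1 is
dropped wherever a predecessor is required, and lag pairs never span
session boundaries because each subject × condition series is analysed
separately.  Partial correlations use the first-order identity
(r_xy − r_xz·r_yz)/√((1 − r_xz²)(1 − r_yz²)), cross-checked in tests
against residual-on-residual correlation.  No outliers are removed
anywhere.  Group tests are two-sided one-sample t-tests with
Cohen's d = (mean − null)/SD and no multiple-testing correction.

## Numerical choices and edge cases

* Gain freeze tolerance 1e−12 inside the filter; steady-state tolerance
  1e−10, iteration cap 10,000.
* Covariances are re-symmetrized each update against roundoff; tests check
  positive semidefiniteness along the whole trace.
* Zero-variance regressors, constant stimuli, empty histogram bins and
  singular Jacobians raise informative errors or are flagged (bins with no
  subjects are kept with n = 0, single-subject bins have undefined SEM)
  rather than silently propagating NaNs.
* Degenerate group tests (zero variance) use a relative tolerance of 1e−12
  on the SD before declaring the t statistic undefined.
* Binned cohort summaries default to 10 equal-width bins over the stimulus
  range; subject-level bin means are averaged first, SEM is across
  subjects.

## Problem sizes

The test suite and the examples run cohorts of up to 14 subjects × 400
trials; cross-validation refits use warm starts from the full-data optimum,
which keeps a full 3-model, k = 11 selection at about 5 s per subject.  The
Monte-Carlo coverage check uses 30 replicates of 200 trials; recovery-grid
checks use 80–500 trials.  These sizes were chosen so the complete analysis
of a cohort — metrics, fits, selection, prediction — reproduces every
qualitative effect the framework predicts while remaining comfortable to
run repeatedly during development.

## Known limitations

* The spec-level static model (fixed prior) is reached by the filter only
  asymptotically: with q = 0 the believed mean is a running average whose
  influence decays harmonically, so short sequences retain a slight order
  dependence even for "static" observers.
* Linearized confidence intervals are symmetric and can cross the v, q ≥ 0
  boundary; coverage statements near the boundary are approximate.
* The windowed-LOO refits reuse the full-data optimum as the single start;
  a pathological fit landscape could in principle make a refit land in a
  different basin than a full multi-start would.
* Histogram matching returns an exemplary realization, not a distributional
  guarantee (see above); its KL floor is set by the estimator, not the
  generators.
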