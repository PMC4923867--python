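# Methods

## Observer model

Interval reproduction is modelled as Gaussian prior–likelihood integration.
Within a session with stimulus set {S₁…S₁₁} and mean t̄ₛ:

- the prior over durations is `N(μ_P, σ_P²)` with μ_P = t̄ₛ (the
  "session-mean" sentinel in `ObserverParams`; a fixed μ_P can be set
  instead). The prior is assumed stationary within a session — the model
  deliberately does not capture the build-up of regression across a session
  that the split-half estimator can reveal in data;
- each trial draws a measurement `t ~ N(Sᵢ, σ_L²)` with `σ_L = WF · t̄ₛ`.
  Sensory noise is scaled by the *session mean*, not by the individual
  stimulus, so σ_L is a session-level constant. This matches the slope
  formula below exactly; a per-stimulus (scalar-timing) variant would make
  the reproduction line very slightly convex;
- the response is the posterior mean
  `μ_R = (μ_P σ_L² + t σ_P²)/(σ_P² + σ_L²)`, plus motor noise, plus an
  optional constant bias.

Because the measurement noise is independent of the stimulus, the
population OLS slope of responses on stimuli equals the shrinkage weight
`σ_P²/(σ_P² + σ_L²)` regardless of motor noise, which is what licenses the
closed-form inversion `σ_P = σ_L·√((1−r)/r)` from a measured regression
index r ∈ (0, 1). A Monte-Carlo variant
(`prior_width_from_regression_mc`) calibrates the same mapping by
simulation; the two agree to within Monte-Carlo error, so the closed form
is the default.

### Motor noise

The motor-noise SD is `0.05 ×` the trial's noise-free posterior mean
(zero-mean Gaussian, added after integration). Scaling with the posterior
mean rather than the stimulus or the final response is a modelling choice:
the three loci differ only in second-order ways (none changes the expected
slope), and the locus is configurable (`motor_noise_ref`). Responses are
floored at 1 ms with a warning; with realistic parameters clamping never
triggers.

### Parameters and defaults

| parameter | meaning | default |
|---|---|---|
| `prior_width_ms` (σ_P) | SD of the duration prior | — (per observer) |
| `weber_fraction` (WF) | temporal resolution; σ_L = WF·t̄ₛ | — (per observer) |
| `motor_noise_coef` | motor-noise level | 0.05 |
| `constant_bias_ms` | additive response offset | 0 |
| `prior_mean_ms` | prior centre | session mean |

`constant_bias_ms` is a generator-only extension for emulating the constant
underestimation real observers show; it is absorbed by the intercept and
leaves every slope-based measure unchanged (tested).

## Paradigm and synthetic data

`build_paradigm()` reconstructs the two-session design: 11 linearly spaced
durations per session, short 1006–1536 ms and long 1270–1800 ms (53 ms
spacing; session means 1271 and 1535 ms, grand mean 1403 ms), 7 trials per
duration → 77 trials per session, presented in random order.

Cohorts draw per-participant WF and σ_P from normals truncated at zero and
a constant bias from an untruncated normal. The truncation guard rejects
specifications whose untruncated mass below zero exceeds 50%. Seeding uses
`numpy` SeedSequence spawning, so a (spec, seed) pair fully determines
every table and participants are independent of cohort size order.

Discrimination data replace the original adaptive (QUEST-style) placement
with a fixed symmetric grid of 9 comparison levels around the 500 ms
reference spanning ±min(3·WF, 0.95)·reference — the cap keeps comparisons
positive at large WF; the estimand (the psychometric SD) is unchanged. A
`halfwidth_ms` override pins the grid when a WF-independent placement is
needed. Responses are Bernoulli draws from the cumulative-Gaussian
psychometric function with SD = WF·reference (optional lapse rate,
default 0).

What the generator does *not* emulate: block structure and breaks,
reaction-time dynamics, within-session prior learning, sequential (n−1
carry-over) effects, and non-Gaussian response distributions. Passing
recovery tests therefore show the estimators are consistent for this
generative family, not that real data satisfy its assumptions.

## Estimators

- **Reproduction line / regression index**: OLS of reproduced on presented
  duration; r = 1 − slope. Requires ≥ 2 distinct stimuli.
- **Error partition**: with per-stimulus mean reproductions mᵢ and sample
  variances vᵢ (ddof = 1) and normaliser T (default t̄ₛ, configurable):
  `BIAS = √(mean (mᵢ−Sᵢ)²)/T`, `CV = √(mean vᵢ)/T`,
  `total = √(BIAS²+CV²)`. The quadratic identity holds exactly by
  construction, the components are orthogonal (accuracy vs reliability),
  and a smaller normaliser inflates both.
- **Weber fraction**: probit regression (statsmodels) of choice on the
  comparison duration, predictor scaled to reference units for numerical
  stability; WF = fitted SD / reference. Perfectly separated responses are
  a zero-width psychometric function: returns 0 with a warning. A non-zero
  lapse switches to a direct MLE (Nelder–Mead on PSE and log SD).
- **Context dependency**: mean difference (long − short) of mean
  reproductions over stimuli matched within 5 ms (the two printed grids are
  offset by 1 ms in their overlap). Positive values are the signature of
  session-specific priors.
- **Split half**: regression index in the first and second half of trials
  by presentation order; odd counts put the extra trial in the first half.
- **Cohen's d**: pooled-SD effect size from group summary statistics.

Estimated Weber fractions outside [0, 1] flag a participant as `excluded`
in the analysis output, mirroring the usual screening rule.

## Simulation studies

`predict_measures_grid` crosses prior widths (conventionally 400, 300, 200,
100 ms) with Weber fractions 0–1 and reports Monte-Carlo means of the
regression index, BIAS and CV, averaged over the two sessions (default 100
repetitions per cell).

`relative_error_landscape` estimates the total reproduction error per
(WF, σ_P) cell and normalises **within each WF row** — min–max to [0, 1] by
default (ratio-to-row-minimum available), so the error-minimising prior at
each resolution level reads as the coldest cell. Cells are seeded
independently of iteration order; the Monte-Carlo SE of each cell is stored
(`raw_se`) and used by the stability tests (doubling repetitions moves no
cell by more than 3 combined SEs). The default 1,000 repetitions per cell
keep a 10 × 4 grid under a second; heavier runs (e.g. 10,000) are a
parameter away.

`optimal_prior_width` minimises the same objective over a fine width grid
with common random numbers (the same Gaussian draws are reused for every
candidate width), which makes the objective smooth in σ_P and the argmin
stable at moderate repetitions. A structural note: under this squared-error
objective the optimum is the Bayes-matched prior — σ_P* equals the RMS
spread of the stimulus set (≈168 ms for the standard sessions, pulled
slightly lower by response-scaled motor noise) for *every* WF > 0, and the
objective flattens entirely as WF → 0 (flagged, upper bound returned).
The optimum does **not** drift with WF; what changes with WF is the cost of
deviating from it, which is exactly what the row-normalised landscape
displays.

`superimpose_groups` converts a group's (r, WF) into a prior width via the
inversion formula using the design's grand-mean stimulus (1403 ms), reads
its relative error off the surface by bilinear interpolation, and refuses
to extrapolate outside the grid (such points are flagged).

## Numerical choices and degenerate inputs

- r outside (0, 1) has no finite prior-width inverse → domain error.
- σ_P ≤ 0, WF < 0, non-finite inputs → domain errors at the boundary of
  every closed-form function.
- Landscapes require ≥ 2 prior widths (nothing to normalise across
  otherwise) and ≥ 2 repetitions (no variance estimate otherwise).
- Within-stimulus variance uses ddof = 1; with 7 trials per duration the
  distinction is material.
- All simulations accept either an integer seed or a `numpy` Generator;
  identical seeds give bit-identical tables.

## Known limitations

- The stationary-prior assumption means the model cannot produce the
  first-half/second-half regression increase seen empirically; the
  split-half estimator exists to measure that mismatch, not to fit it.
- σ_L = WF·t̄ₛ transfers a Weber fraction measured at a 500 ms reference to
  a ~1.4 s reproduction task unchanged; any failure of that transfer
  propagates directly into prior-width estimates.
- Group prior widths are estimated from group-mean r and WF, not by
  hierarchical fitting; with heterogeneous participants the inversion of
  means is not the mean of inversions.
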