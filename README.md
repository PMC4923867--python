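# timeprior

Bayesian ideal-observer modelling of **central tendency in time-interval
reproduction** — the robust tendency of observers to reproduce short
intervals too long and long intervals too short, pulling responses toward
the mean of the stimulus set.

The package is aimed at researchers in time perception and computational
psychophysics who want to simulate the standard two-session
interval-reproduction paradigm, derive the field's standard measures from
trial data, and assess how close an observer's prior weighting is to the
error-minimising optimum.

## The model

An observer reproducing a duration *S* combines a Gaussian prior over
durations with a noisy sensory measurement:

- prior: `N(μ_P, σ_P²)`, with μ_P centred on the session mean stimulus t̄ₛ;
- likelihood: the measurement of *S* is `N(S, σ_L²)` with `σ_L = WF · t̄ₛ`,
  where WF is the observer's Weber fraction (temporal resolution);
- the response is the posterior mean
  `μ_R = (μ_P σ_L² + t σ_P²) / (σ_P² + σ_L²)`
  plus zero-mean motor noise at a 5% level.

The predicted slope of reproduced on presented duration is

```
slope = σ_P² / (σ_P² + σ_L²),   regression index r = 1 − slope
```

so veridical reproduction (slope 1) arises when sensory noise vanishes and
full regression to the mean (slope 0) when resolution is poor. Inverting
the slope formula gives the prior width implied by a measured regression
index and Weber fraction:

```
σ_P = σ_L · √((1 − r) / r)
```

On top of the observer model the package provides:

- the standard paradigm generator (11 "short" durations 1006–1536 ms, 11
  "long" durations 1270–1800 ms, 7 trials each → 77 trials per session),
  simulated cohorts with participant heterogeneity, and 2AFC time
  discrimination data against a 500 ms reference;
- estimators: OLS reproduction line and regression index, the orthogonal
  BIAS/CV partition of total reproduction error (`total² = BIAS² + CV²`),
  maximum-likelihood cumulative-Gaussian Weber fractions, context
  dependency on stimuli common to both sessions, split-half regression
  build-up, and Cohen's *d* from group summaries;
- the Monte-Carlo **relative-error landscape** over a (WF × prior width)
  grid, with per-WF normalisation, an optimal-prior search, and placement
  of measured groups on the surface via the inversion formula.

## Worked example

```python
import numpy as np
from timeprior import (ObserverParams, build_paradigm, simulate_reproduction,
                       session_measures, prior_width_from_regression)

paradigm = build_paradigm()          # short: 1006-1536 ms, long: 1270-1800 ms
observer = ObserverParams(prior_width_ms=400.0, weber_fraction=0.36)

rng = np.random.default_rng(0)
indices = []
for session in paradigm.sessions:
    trials = simulate_reproduction(observer, session, rng)
    m = session_measures(trials)
    print(f"{session.label:>5}: slope={m.slope:.3f}  r={m.regression_index:.3f}  "
          f"BIAS={m.bias:.3f}  CV={m.cv:.3f}  total={m.total_error:.3f}")
    indices.append(m.regression_index)

r = float(np.mean(indices))
sigma_p = prior_width_from_regression(r, 0.36, paradigm.mean_stimulus_ms)
print(f"session-averaged r = {r:.3f}  ->  estimated prior width = {sigma_p:.0f} ms")
```

prints

```
short: slope=0.550  r=0.450  BIAS=0.085  CV=0.171  total=0.191
 long: slope=0.397  r=0.603  BIAS=0.077  CV=0.144  total=0.164
session-averaged r = 0.526  ->  estimated prior width = 479 ms
```

One simulated participant shows substantial central tendency in both
sessions (single-session regression indices scatter around the analytic
expectation of ≈0.61 for this parameter pair); the final line inverts the
measured regression back to a prior-width estimate. Averaging over many
simulated observers recovers σ_P = 400 ms; see the parameter-recovery
tests.

The same pipeline runs from the shell:

```sh
timeprior simulate  -c config.yaml -o out/        # cohort CSVs
timeprior analyze   -c config.yaml -i out/ -o out/analysis/
timeprior landscape -c config.yaml -o out/landscape/ --figure
timeprior estimate-prior -r 0.61 -w 0.36          # -> 403.9
```

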