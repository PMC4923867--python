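"""Per-session and per-participant psychophysical measurements.

Given reproduction-trial tables this module computes the regression index
(the magnitude of central tendency), the orthogonal BIAS/CV partition of the
total reproduction error, context dependency on stimuli common to the short
and long sessions, and split-half regression build-up; given 2AFC
discrimination trials it fits a cumulative-Gaussian psychometric function
and returns the Weber fraction. Effect sizes between group summaries use
Cohen's d with the pooled SD.

Error partition
---------------
With stimuli s_1..s_k, per-stimulus mean reproductions m_i and sample
variances v_i, and a normalising interval T (the session mean stimulus by
default):

    BIAS = sqrt(mean_i (m_i - s_i)**2) / T      # accuracy error
    CV   = sqrt(mean_i v_i) / T                 # reliability error
    total = sqrt(BIAS**2 + CV**2)

so total**2 = BIAS**2 + CV**2 holds exactly by construction, and a smaller
normaliser inflates both components.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SessionMeasures",
    "GroupSummary",
    "EstimationError",
    "fit_reproduction_line",
    "regression_index",
    "error_components",
    "session_measures",
    "weber_fraction_from_2afc",
    "context_dependency",
    "split_half_regression",
    "cohens_d",
    "measures_table",
]


class EstimationError(RuntimeError):
    """An estimator could not produce a defined result."""


@dataclass(frozen=True)
class SessionMeasures:
    """All measures derived from one session of reproduction trials."""

    slope: float
    intercept_ms: float
    regression_index: float
    bias: float
    cv: float
    total_error: float


@dataclass(frozen=True)
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float


def _stim_resp(trials: pd.DataFrame):
    return (
        np.asarray(trials["stimulus_ms"], dtype=float),
        np.asarray(trials["reproduced_ms"], dtype=float),
    )


def fit_reproduction_line(trials: pd.DataFrame):
    """OLS fit of reproduced on presented duration: (slope, intercept_ms)."""
    s, r = _stim_resp(trials)
    if np.unique(s).size < 2:
        raise EstimationError("need >= 2 distinct stimulus values to fit a line")
    fit = stats.linregress(s, r)
    return float(fit.slope), float(fit.intercept)


def regression_index(trials: pd.DataFrame) -> float:
    """Central-tendency magnitude: 1 - OLS slope.

    0 is veridical reproduction, 1 is complete regression to the mean.
    Invariant to a constant offset added to every response (the intercept
    absorbs systematic bias).
    """
    slope, _ = fit_reproduction_line(trials)
    return 1.0 - slope


def error_components(trials: pd.DataFrame, normaliser_ms: float):
    """(BIAS, CV, total_error) of one session, normalised by ``normaliser_ms``."""
    if not (math.isfinite(normaliser_ms) and normaliser_ms > 0):
        raise ValueError("normaliser_ms must be > 0")
    g = trials.groupby("stimulus_ms")["reproduced_ms"]
    means = g.mean()
    counts = g.count()
    if (counts < 2).any():
        raise EstimationError("need >= 2 trials per stimulus for the CV component")
    variances = g.var(ddof=1)
    bias = math.sqrt(np.mean((means.to_numpy() - means.index.to_numpy()) ** 2)) / normaliser_ms
    cv = math.sqrt(np.mean(variances.to_numpy())) / normaliser_ms
    return bias, cv, math.hypot(bias, cv)


def session_measures(trials: pd.DataFrame, normaliser_ms: float | None = None) -> SessionMeasures:
    """All session measures at once; normaliser defaults to the session mean
    of the distinct stimulus values."""
    if normaliser_ms is None:
        normaliser_ms = float(np.unique(trials["stimulus_ms"]).mean())
    slope, intercept = fit_reproduction_line(trials)
    bias, cv, total = error_components(trials, normaliser_ms)
    return SessionMeasures(
        slope=slope,
        intercept_ms=intercept,
        regression_index=1.0 - slope,
        bias=bias,
        cv=cv,
        total_error=total,
    )


def weber_fraction_from_2afc(trials: pd.DataFrame, lapse: float = 0.0) -> float:
    """Weber fraction from 2AFC discrimination trials.

    Maximum-likelihood cumulative-Gaussian fit of P(chose comparison longer)
    against the comparison duration; returns fitted SD / reference. With the
    default zero lapse this is a probit regression. Perfectly separated
    responses (a step function) imply a zero-width psychometric function:
    returns 0 with a warning.
    """
    comp = np.asarray(trials["comparison_ms"], dtype=float)
    chose = np.asarray(trials["chose_comparison_longer"], dtype=bool)
    reference = float(np.asarray(trials["reference_ms"], dtype=float)[0])
    if np.unique(comp).size < 2 or chose.all() or (~chose).all():
        raise EstimationError(
            "need >= 2 distinct comparison levels with both response types"
        )
    if np.max(comp[~chose], initial=-np.inf) < np.min(comp[chose], initial=np.inf):
        warnings.warn(
            "perfectly separated 2AFC responses: psychometric SD is 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0

    if lapse == 0.0:
        import statsmodels.api as sm

        # predictor scaled to reference units so the probit slope is O(1)
        x = sm.add_constant((comp - reference) / reference)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Probit(chose.astype(float), x).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            raise EstimationError(f"probit fit did not converge: {fit.mle_retvals}")
        b0, b1 = fit.params
        if b1 <= 0:
            raise EstimationError(f"non-increasing psychometric fit (slope {b1:.4g})")
        sd = reference / b1
    else:
        from scipy.optimize import minimize

        def nll(theta):
            mu, log_sd = theta
            p = lapse / 2 + (1 - lapse) * stats.norm.cdf(comp, mu, np.exp(log_sd))
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return -np.sum(np.where(chose, np.log(p), np.log1p(-p)))

        res = minimize(nll, x0=[reference, np.log(0.2 * reference)], method="Nelder-Mead")
        if not res.success:
            raise EstimationError(f"psychometric MLE failed: {res.message}")
        sd = float(np.exp(res.x[1]))
    return sd / reference


def context_dependency(
    short_trials: pd.DataFrame,
    long_trials: pd.DataFrame,
    match_tolerance_ms: float = 5.0,
) -> float:
    """Mean reproduction difference (long - short) on common stimuli, ms.

    Stimuli in the two sessions are matched within ``match_tolerance_ms``
    (the printed grids are offset by 1 ms in the overlap region). A positive
    value means the same physical duration is reproduced longer when it
    occurs in the long-range session — the signature of session-specific
    priors.
    """
    short_means = short_trials.groupby("stimulus_ms")["reproduced_ms"].mean()
    long_means = long_trials.groupby("stimulus_ms")["reproduced_ms"].mean()
    diffs = []
    for s_stim, s_mean in short_means.items():
        gaps = np.abs(long_means.index.to_numpy() - s_stim)
        j = int(np.argmin(gaps))
        if gaps[j] <= match_tolerance_ms:
            diffs.append(long_means.iloc[j] - s_mean)
    if not diffs:
        raise EstimationError(
            f"no common stimuli within {match_tolerance_ms} ms between sessions"
        )
    return float(np.mean(diffs))


def split_half_regression(trials: pd.DataFrame):
    """Regression index in the first and second half of a session.

    Trials are split by presentation order (``trial_index``); an odd count
    puts the extra trial in the first half. A stationary observer shows
    equal indices in expectation; an increase across halves indicates prior
    build-up within the session.
    """
    ordered = trials.sort_values("trial_index")
    n = len(ordered)
    if n < 4:
        raise EstimationError("need >= 4 trials for a split-half analysis")
    cut = (n + 1) // 2
    first, second = ordered.iloc[:cut], ordered.iloc[cut:]
    try:
        return regression_index(first), regression_index(second)
    except EstimationError as exc:
        raise EstimationError(f"degenerate half in split-half analysis: {exc}") from exc


def cohens_d(m1: float, sd1: float, n1: int, m2: float, sd2: float, n2: int) -> float:
    """Cohen's d between two group summaries, using the pooled SD."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in each group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("sds must be >= 0")
    pooled = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if pooled == 0:
        raise ValueError("pooled SD is zero; d undefined")
    return (m1 - m2) / pooled


def measures_table(trials: pd.DataFrame, normaliser_ms: float | None = None) -> pd.DataFrame:
    """Per-participant, per-session measures for a multi-participant table.

    Expects ``participant_id`` and ``session`` columns in addition to the
    trial columns; returns one row per (participant, session).
    """
    rows = []
    for (pid, session), grp in trials.groupby(["participant_id", "session"], sort=False):
        m = session_measures(grp, normaliser_ms)
        rows.append(
            {
                "participant_id": pid,
                "session": session,
                "slope": m.slope,
                "intercept_ms": m.intercept_ms,
                "regression_index": m.regression_index,
                "bias": m.bias,
                "cv": m.cv,
                "total_error": m.total_error,
            }
        )
    return pd.DataFrame(rows)
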