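"""Synthetic paradigm designs, cohorts, and 2AFC discrimination data.

Everything downstream of the observer model is testable without any
empirical download: this module rebuilds the interval-reproduction paradigm
(a "short" session of 11 durations spanning 1006-1536 ms and a "long"
session spanning 1270-1800 ms, 7 trials per duration), simulates cohorts of
heterogeneous observers, and generates two-alternative forced-choice time
discrimination data against a 500 ms reference.

Adaptive (QUEST-style) comparison placement is replaced by a fixed symmetric
grid of comparison levels around the reference; the estimand (the SD of the
cumulative-Gaussian psychometric function) is identical, and an adaptive
placement hook can be layered on top of :func:`psychometric_p`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .observer import ObserverParams, SessionDesign, simulate_reproduction

__all__ = [
    "ParadigmDesign",
    "CohortSpec",
    "build_paradigm",
    "generate_cohort",
    "generate_discrimination_data",
    "generate_cohort_discrimination",
    "psychometric_p",
    "PARTICIPANT_COLUMNS",
    "DISCRIMINATION_COLUMNS",
]

SHORT_RANGE_MS = (1006.0, 1536.0)
LONG_RANGE_MS = (1270.0, 1800.0)
N_DURATIONS = 11
REFERENCE_MS = 500.0

PARTICIPANT_COLUMNS = [
    "participant_id",
    "group",
    "true_wf",
    "true_prior_width_ms",
    "true_bias_ms",
]
DISCRIMINATION_COLUMNS = [
    "trial_index",
    "reference_ms",
    "comparison_ms",
    "chose_comparison_longer",
]


@dataclass(frozen=True)
class ParadigmDesign:
    """The two-session reproduction paradigm."""

    short_session: SessionDesign
    long_session: SessionDesign

    @property
    def sessions(self) -> tuple:
        return (self.short_session, self.long_session)

    @property
    def mean_stimulus_ms(self) -> float:
        """Mean stimulus averaged over the two sessions (t_bar for Eq.-10-style
        group estimates; 1403 ms at the default paradigm)."""
        return float(np.mean([s.mean_stimulus_ms for s in self.sessions]))

    def to_dict(self) -> dict:
        return {
            "short_session": self.short_session.to_dict(),
            "long_session": self.long_session.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParadigmDesign":
        return cls(
            short_session=SessionDesign.from_dict(d["short_session"]),
            long_session=SessionDesign.from_dict(d["long_session"]),
        )


@dataclass(frozen=True)
class CohortSpec:
    """Specification of one simulated participant group.

    Per-participant Weber fractions and prior widths are drawn from normals
    truncated at zero (the paradigm only reports group-level summaries, so
    the heterogeneity model is a modelling choice); the constant bias is an
    untruncated normal and defaults to zero.
    """

    group_label: str
    n_participants: int
    wf_distribution: tuple  # (mean, sd)
    prior_width_distribution: tuple  # (mean, sd), ms
    motor_noise_coef: float = 0.05
    bias_distribution: tuple = (0.0, 0.0)  # (mean, sd), ms
    seed: int = 0

    def __post_init__(self):
        if int(self.n_participants) < 1:
            raise ValueError("n_participants must be >= 1")
        for name in ("wf_distribution", "prior_width_distribution", "bias_distribution"):
            mean, sd = getattr(self, name)
            if not (math.isfinite(mean) and math.isfinite(sd)):
                raise ValueError(f"{name} must be finite")
            if sd < 0:
                raise ValueError(f"{name} sd must be >= 0")
        object.__setattr__(self, "n_participants", int(self.n_participants))

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("wf_distribution", "prior_width_distribution", "bias_distribution"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        for k in ("wf_distribution", "prior_width_distribution", "bias_distribution"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


def build_paradigm(trials_per_duration: int = 7) -> ParadigmDesign:
    """Build the default two-session paradigm.

    Eleven linearly spaced durations per session with the printed endpoints
    (short 1006-1536 ms, long 1270-1800 ms; 53 ms spacing), seven trials per
    duration by default, hence 77 trials per session.
    """
    if int(trials_per_duration) < 1:
        raise ValueError("trials_per_duration must be >= 1")
    short = SessionDesign(
        "short", tuple(np.linspace(*SHORT_RANGE_MS, N_DURATIONS)), int(trials_per_duration)
    )
    long = SessionDesign(
        "long", tuple(np.linspace(*LONG_RANGE_MS, N_DURATIONS)), int(trials_per_duration)
    )
    return ParadigmDesign(short_session=short, long_session=long)


def _draw_truncated(rng, mean, sd, n, lower=0.0):
    """Draw from Normal(mean, sd) truncated below at ``lower``.

    Rejects specs whose untruncated mass below zero exceeds 50% — such a
    'distribution' is dominated by the truncation, not the stated mean.
    """
    if sd == 0:
        if mean < lower:
            raise ValueError(f"degenerate distribution: constant {mean} below {lower}")
        return np.full(n, float(mean))
    if stats.norm.cdf(0.0, loc=mean, scale=sd) > 0.5:
        raise ValueError(
            f"distribution mean {mean}, sd {sd} places >50% mass below zero"
        )
    a = (lower - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def generate_cohort(spec: CohortSpec, design: ParadigmDesign):
    """Simulate a participant group through both reproduction sessions.

    Returns
    -------
    participants : pandas.DataFrame
        One row per participant with the true generating parameters
        (columns ``participant_id, group, true_wf, true_prior_width_ms,
        true_bias_ms``), for parameter-recovery checks.
    trials : pandas.DataFrame
        All reproduction trials, with ``participant_id`` and ``group``
        prepended to the standard trial columns.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss)
    n = spec.n_participants
    wfs = _draw_truncated(rng, *spec.wf_distribution, n)
    priors = _draw_truncated(rng, *spec.prior_width_distribution, n)
    # prior width must be strictly positive
    priors = np.maximum(priors, 1e-6)
    bias_mean, bias_sd = spec.bias_distribution
    biases = bias_mean + rng.standard_normal(n) * bias_sd

    participants = pd.DataFrame(
        {
            "participant_id": [f"{spec.group_label}-{i:03d}" for i in range(n)],
            "group": spec.group_label,
            "true_wf": wfs,
            "true_prior_width_ms": priors,
            "true_bias_ms": biases,
        }
    )

    child_seeds = ss.spawn(n)
    frames = []
    for i, (pid, child) in enumerate(zip(participants["participant_id"], child_seeds)):
        params = ObserverParams(
            prior_width_ms=priors[i],
            weber_fraction=wfs[i],
            motor_noise_coef=spec.motor_noise_coef,
            constant_bias_ms=biases[i],
        )
        prng = np.random.default_rng(child)
        for session in design.sessions:
            t = simulate_reproduction(params, session, prng)
            t.insert(0, "group", spec.group_label)
            t.insert(0, "participant_id", pid)
            frames.append(t)
    trials = pd.concat(frames, ignore_index=True)
    return participants, trials


def psychometric_p(comparison_ms, reference_ms, weber_fraction, lapse: float = 0.0):
    """P(choose 'comparison longer') under a cumulative-Gaussian observer.

    The psychometric SD is WF * reference; an optional lapse rate mixes in
    chance responding symmetrically.
    """
    sd = weber_fraction * reference_ms
    p = stats.norm.cdf(np.asarray(comparison_ms, dtype=float), loc=reference_ms, scale=sd)
    return lapse / 2.0 + (1.0 - lapse) * p


def generate_discrimination_data(
    weber_fraction: float,
    reference_ms: float = REFERENCE_MS,
    n_trials: int = 54,
    n_levels: int = 9,
    seed=0,
    halfwidth_ms: float | None = None,
) -> pd.DataFrame:
    """Generate 2AFC time-discrimination trials on a fixed comparison grid.

    Comparison intervals sit on ``n_levels`` symmetric levels around the
    reference spanning +/- min(3*WF, 0.95) * reference (the cap keeps every
    comparison interval positive for large Weber fractions); pass
    ``halfwidth_ms`` to pin the grid span independently of WF. Each response
    is a Bernoulli draw from the cumulative-Gaussian psychometric function
    with SD = WF * reference.
    """
    if not (math.isfinite(weber_fraction) and weber_fraction > 0):
        raise ValueError("weber_fraction must be > 0")
    if int(n_trials) < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    half = (
        float(halfwidth_ms)
        if halfwidth_ms is not None
        else min(3.0 * weber_fraction, 0.95) * reference_ms
    )
    if not 0 < half < reference_ms:
        raise ValueError("halfwidth_ms must be in (0, reference_ms)")
    levels = reference_ms + np.linspace(-half, half, n_levels)
    comparisons = np.resize(levels, int(n_trials))
    comparisons = rng.permutation(comparisons)
    p = psychometric_p(comparisons, reference_ms, weber_fraction)
    chose_longer = rng.random(int(n_trials)) < p
    return pd.DataFrame(
        {
            "trial_index": np.arange(int(n_trials), dtype=int),
            "reference_ms": reference_ms,
            "comparison_ms": comparisons,
            "chose_comparison_longer": chose_longer,
        }
    )


def generate_cohort_discrimination(
    participants: pd.DataFrame, n_trials: int = 54, seed: int = 0
) -> pd.DataFrame:
    """Generate a discrimination dataset per participant of a cohort table.

    Uses each participant's ``true_wf``; returns the standard discrimination
    columns with ``participant_id`` prepended.
    """
    ss = np.random.SeedSequence(seed)
    frames = []
    for (_, row), child in zip(participants.iterrows(), ss.spawn(len(participants))):
        t = generate_discrimination_data(
            row["true_wf"], n_trials=n_trials, seed=np.random.default_rng(child)
        )
        t.insert(0, "participant_id", row["participant_id"])
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
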