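"""Simulation studies over the (Weber fraction x prior width) grid.

Two studies: model-predicted measures (regression index, BIAS, CV) across a
parameter grid, and the relative-error landscape — the Monte-Carlo total
reproduction error over the grid, normalised within each Weber-fraction row
so the prior width that minimises error at each resolution level is visible.
Superimposing a group's measured (regression index, Weber fraction) point on
the landscape, via the prior-width inversion, shows how close the group sits
to the optimal prior for its temporal resolution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .observer import likelihood_sd, prior_width_from_regression
from .synth import ParadigmDesign

__all__ = [
    "ErrorLandscape",
    "GroupPoint",
    "OptimalPrior",
    "predict_measures_grid",
    "relative_error_landscape",
    "optimal_prior_width",
    "superimpose_groups",
    "plot_landscape",
]


def _batch_session_measures(rng, session, sigma_p, wf, motor_coef, reps):
    """Per-replicate (slope, bias, cv) for ``reps`` simulated sessions.

    Vectorised counterpart of simulate_reproduction + session_measures:
    stimuli are in design order (order does not affect any of the three
    measures), variance uses ddof=1, and the normaliser is the session mean
    stimulus. Responses are floored at 1 ms as in the trial-level simulator.
    """
    durations = np.asarray(session.durations_ms)
    tpd = session.trials_per_duration
    n = durations.size * tpd
    tbar = session.mean_stimulus_ms
    sl = likelihood_sd(wf, tbar)
    stim = np.tile(np.repeat(durations, tpd), (reps, 1))
    w = sigma_p**2 / (sigma_p**2 + sl**2)
    measurement = stim + rng.standard_normal((reps, n)) * sl
    post = (1.0 - w) * tbar + w * measurement
    resp = post + rng.standard_normal((reps, n)) * motor_coef * np.abs(post)
    resp = np.maximum(resp, 1.0)

    sx = stim - stim.mean(axis=1, keepdims=True)
    slopes = np.sum(sx * resp, axis=1) / np.sum(sx**2, axis=1)

    by_stim = resp.reshape(reps, durations.size, tpd)
    means = by_stim.mean(axis=2)
    variances = by_stim.var(axis=2, ddof=1)
    bias = np.sqrt(np.mean((means - durations) ** 2, axis=1)) / tbar
    cv = np.sqrt(np.mean(variances, axis=1)) / tbar
    return slopes, bias, cv


def _cell_measures(seed_seq, design, sigma_p, wf, motor_coef, reps):
    """Session-averaged per-replicate measures for one grid cell."""
    rng = np.random.default_rng(seed_seq)
    per_session = [
        _batch_session_measures(rng, s, sigma_p, wf, motor_coef, reps)
        for s in design.sessions
    ]
    slopes = np.mean([p[0] for p in per_session], axis=0)
    bias = np.mean([p[1] for p in per_session], axis=0)
    cv = np.mean([p[2] for p in per_session], axis=0)
    return slopes, bias, cv


def predict_measures_grid(
    prior_widths_ms,
    wf_values,
    design: ParadigmDesign,
    reps: int = 100,
    seed: int = 0,
    motor_noise_coef: float = 0.05,
) -> pd.DataFrame:
    """Model-predicted measures for each (prior width, Weber fraction) cell.

    For every cell, ``reps`` replicate observers complete both sessions;
    regression index, BIAS and CV are averaged across sessions and
    replicates. The conventional grid is prior widths {400, 300, 200, 100}
    ms crossed with Weber fractions 0-1 in steps of 0.1 at 100 repetitions.
    """
    prior_widths_ms = list(prior_widths_ms)
    wf_values = list(wf_values)
    if reps < 1 or not prior_widths_ms or not wf_values:
        raise ValueError("reps must be >= 1 and grids non-empty")
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(prior_widths_ms) * len(wf_values)))
    rows = []
    for sp in prior_widths_ms:
        for wf in wf_values:
            slopes, bias, cv = _cell_measures(next(children), design, sp, wf, motor_noise_coef, reps)
            rows.append(
                {
                    "prior_width_ms": sp,
                    "wf": wf,
                    "regression_index": 1.0 - slopes.mean(),
                    "bias": bias.mean(),
                    "cv": cv.mean(),
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ErrorLandscape:
    """Monte-Carlo total-error surface over a (WF x prior width) grid.

    ``relative_error`` is normalised within each WF row — per-row min-max to
    [0, 1] by default, or ratio-to-row-minimum ("ratio" mode, minimum 1).
    ``raw_se`` is the Monte-Carlo standard error of each raw cell mean.
    """

    wf_grid: tuple
    prior_grid_ms: tuple
    raw_total_error: np.ndarray  # (n_wf, n_prior)
    relative_error: np.ndarray
    raw_se: np.ndarray
    reps: int
    seed: int
    normalisation: str
    design: ParadigmDesign = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Long-form table `wf, prior_width_ms, raw_total_error, relative_error`."""
        wf, sp = np.meshgrid(self.wf_grid, self.prior_grid_ms, indexing="ij")
        return pd.DataFrame(
            {
                "wf": wf.ravel(),
                "prior_width_ms": sp.ravel(),
                "raw_total_error": self.raw_total_error.ravel(),
                "relative_error": self.relative_error.ravel(),
            }
        )

    def to_csv(self, path, sidecar_path=None):
        self.to_frame().to_csv(path, index=False)
        if sidecar_path is not None:
            meta = {
                "reps": self.reps,
                "seed": self.seed,
                "normalisation": self.normalisation,
                "design": self.design.to_dict(),
            }
            with open(sidecar_path, "w") as fh:
                json.dump(meta, fh, indent=2)

    def row_argmin_prior(self, wf_index: int) -> float:
        """Prior width with minimal raw error in one WF row."""
        return float(self.prior_grid_ms[int(np.argmin(self.raw_total_error[wf_index]))])


@dataclass(frozen=True)
class GroupPoint:
    """A participant group located on the landscape."""

    label: str
    wf: float
    prior_width_ms: float
    source: str  # "estimated" | "assigned"
    relative_error: float  # NaN when outside the grid
    in_grid: bool


@dataclass(frozen=True)
class OptimalPrior:
    width_ms: float
    flat_objective: bool = False


def _normalise_rows(raw: np.ndarray, mode: str) -> np.ndarray:
    if mode == "minmax":
        lo = raw.min(axis=1, keepdims=True)
        hi = raw.max(axis=1, keepdims=True)
        span = np.where(hi > lo, hi - lo, 1.0)
        return (raw - lo) / span
    if mode == "ratio":
        return raw / raw.min(axis=1, keepdims=True)
    raise ValueError(f"unknown normalisation mode {mode!r}")


def relative_error_landscape(
    wf_grid,
    prior_grid_ms,
    design: ParadigmDesign,
    reps: int = 1000,
    seed: int = 0,
    motor_noise_coef: float = 0.05,
    normalisation: str = "minmax",
) -> ErrorLandscape:
    """Monte-Carlo relative-error landscape over (WF x prior width).

    Raw cell value: mean over replicates of the session-averaged total
    reproduction error sqrt(BIAS**2 + CV**2). Relative error normalises
    within each WF row. Deterministic under a fixed seed; cells are seeded
    independently so the surface does not depend on iteration order.
    """
    wf_grid = tuple(float(w) for w in wf_grid)
    prior_grid_ms = tuple(float(p) for p in prior_grid_ms)
    if len(prior_grid_ms) < 2:
        raise ValueError("need >= 2 prior widths to normalise across priors")
    if reps < 2:
        raise ValueError("need reps >= 2 to estimate Monte-Carlo error")
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(wf_grid) * len(prior_grid_ms)))
    raw = np.empty((len(wf_grid), len(prior_grid_ms)))
    se = np.empty_like(raw)
    for i, wf in enumerate(wf_grid):
        for j, sp in enumerate(prior_grid_ms):
            _, bias, cv = _cell_measures(next(children), design, sp, wf, motor_noise_coef, reps)
            total = np.hypot(bias, cv)
            raw[i, j] = total.mean()
            se[i, j] = total.std(ddof=1) / math.sqrt(reps)
    rel = _normalise_rows(raw, normalisation)
    return ErrorLandscape(
        wf_grid=wf_grid,
        prior_grid_ms=prior_grid_ms,
        raw_total_error=raw,
        relative_error=rel,
        raw_se=se,
        reps=reps,
        seed=seed,
        normalisation=normalisation,
        design=design,
    )


def optimal_prior_width(
    wf: float,
    design: ParadigmDesign,
    search_range_ms=(50.0, 1000.0),
    reps: int = 1000,
    seed: int = 0,
    motor_noise_coef: float = 0.05,
    n_grid: int = 60,
) -> OptimalPrior:
    """Prior width minimising Monte-Carlo total error at a given WF.

    Fine-grid search with common random numbers: the same measurement and
    motor-noise draws are reused for every candidate width, so the objective
    is a smooth function of the width and the argmin is stable at moderate
    ``reps``. A flat objective (WF = 0: the response does not depend on the
    prior) returns the upper search bound, flagged.
    """
    if wf < 0:
        raise ValueError("wf must be >= 0")
    lo, hi = float(search_range_ms[0]), float(search_range_ms[1])
    if wf == 0:
        return OptimalPrior(width_ms=hi, flat_objective=True)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    draws = []
    for session in design.sessions:
        n = session.n_trials
        draws.append(
            (session, rng.standard_normal((reps, n)), rng.standard_normal((reps, n)))
        )
    grid = np.linspace(lo, hi, n_grid)
    objective = np.zeros(grid.size)
    for session, z_meas, z_motor in draws:
        durations = np.asarray(session.durations_ms)
        tpd = session.trials_per_duration
        tbar = session.mean_stimulus_ms
        sl = likelihood_sd(wf, tbar)
        stim = np.tile(np.repeat(durations, tpd), (reps, 1))
        measurement = stim + z_meas * sl
        for k, sp in enumerate(grid):
            w = sp**2 / (sp**2 + sl**2)
            post = (1.0 - w) * tbar + w * measurement
            resp = np.maximum(post + z_motor * motor_noise_coef * np.abs(post), 1.0)
            by_stim = resp.reshape(reps, durations.size, tpd)
            bias = np.sqrt(np.mean((by_stim.mean(axis=2) - durations) ** 2, axis=1)) / tbar
            cv = np.sqrt(np.mean(by_stim.var(axis=2, ddof=1), axis=1)) / tbar
            objective[k] += np.hypot(bias, cv).mean() / len(draws)
    if np.ptp(objective) < 1e-12:
        return OptimalPrior(width_ms=hi, flat_objective=True)
    return OptimalPrior(width_ms=float(grid[int(np.argmin(objective))]))


def superimpose_groups(landscape: ErrorLandscape, groups) -> list:
    """Place measured groups on the landscape.

    Each group is a ``(label, regression_index, wf)`` triple; its prior
    width is estimated by the inversion formula using the design's mean
    stimulus averaged over the two sessions, and its relative error is read
    from the surface by bilinear interpolation. Points outside the grid are
    flagged and not extrapolated.
    """
    groups = list(groups)
    if not groups:
        raise ValueError("groups must be non-empty")
    from scipy.interpolate import RegularGridInterpolator

    interp = RegularGridInterpolator(
        (np.asarray(landscape.wf_grid), np.asarray(landscape.prior_grid_ms)),
        landscape.relative_error,
        method="linear",
        bounds_error=False,
        fill_value=np.nan,
    )
    tbar = landscape.design.mean_stimulus_ms
    points = []
    for label, r, wf in groups:
        sp = prior_width_from_regression(r, wf, tbar)
        in_grid = (
            landscape.wf_grid[0] <= wf <= landscape.wf_grid[-1]
            and landscape.prior_grid_ms[0] <= sp <= landscape.prior_grid_ms[-1]
        )
        rel = float(interp([[wf, sp]])[0]) if in_grid else float("nan")
        points.append(
            GroupPoint(
                label=label,
                wf=float(wf),
                prior_width_ms=sp,
                source="estimated",
                relative_error=rel,
                in_grid=in_grid,
            )
        )
    return points


def plot_landscape(landscape: ErrorLandscape, points=None, path=None):
    """Heat-map of the relative-error surface with optional group points."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    mesh = ax.pcolormesh(
        landscape.prior_grid_ms,
        landscape.wf_grid,
        landscape.relative_error,
        shading="nearest",
        cmap="viridis",
    )
    fig.colorbar(mesh, ax=ax, label="relative total error")
    if points:
        for p in points:
            if p.in_grid:
                ax.plot(p.prior_width_ms, p.wf, "s", color="white", markersize=7)
                ax.annotate(p.label, (p.prior_width_ms, p.wf), color="white", fontsize=8,
                            xytext=(4, 4), textcoords="offset points")
    ax.set_xlabel("prior width $\\sigma_P$ (ms)")
    ax.set_ylabel("Weber fraction")
    ax.set_title("Relative reproduction-error landscape")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
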