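"""Run configuration: YAML/JSON parsing and validation for the pipeline."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synth import CohortSpec, ParadigmDesign, build_paradigm

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid run configuration; the message names the offending field."""


@dataclass
class RunConfig:
    seed: int
    cohorts: list  # list[CohortSpec]
    paradigm: ParadigmDesign
    discrimination_trials: int = 54
    normaliser_ms: float | None = None  # None -> per-session mean stimulus
    match_tolerance_ms: float = 5.0
    split_half: bool = True
    landscape_wf_grid: list = field(default_factory=lambda: [round(0.1 * k, 1) for k in range(1, 11)])
    landscape_prior_grid_ms: list = field(default_factory=lambda: [100.0, 200.0, 300.0, 400.0])
    landscape_reps: int = 1000
    compare_groups: list = field(default_factory=list)  # list of [label_a, label_b]

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "paradigm": self.paradigm.to_dict(),
            "cohorts": [c.to_dict() for c in self.cohorts],
            "discrimination_trials": self.discrimination_trials,
            "analysis": {
                "normaliser_ms": self.normaliser_ms,
                "match_tolerance_ms": self.match_tolerance_ms,
                "split_half": self.split_half,
                "compare_groups": [list(p) for p in self.compare_groups],
            },
            "landscape": {
                "wf_grid": list(self.landscape_wf_grid),
                "prior_grid_ms": list(self.landscape_prior_grid_ms),
                "reps": self.landscape_reps,
            },
        }


def _require(cond: bool, field_name: str, msg: str):
    if not cond:
        raise ConfigError(f"{field_name}: {msg}")


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration.

    Minimal file::

        seed: 7
        cohorts:
          - group_label: autistic-like
            n_participants: 23
            wf_distribution: [0.36, 0.21]
            prior_width_distribution: [400, 50]

    All other blocks default to the standard paradigm and analysis settings.
    """
    text = Path(path).read_text()
    raw = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    _require(isinstance(raw, dict), "config", "top level must be a mapping")
    _require("seed" in raw, "seed", "is required")
    _require(isinstance(raw["seed"], int), "seed", "must be an integer")

    paradigm_block = raw.get("paradigm", {})
    if "short_session" in paradigm_block:
        paradigm = ParadigmDesign.from_dict(paradigm_block)
    else:
        tpd = paradigm_block.get("trials_per_duration", 7)
        _require(isinstance(tpd, int) and tpd >= 1, "paradigm.trials_per_duration", "must be a positive integer")
        paradigm = build_paradigm(tpd)

    cohorts = []
    raw_cohorts = raw.get("cohorts", [])
    _require(isinstance(raw_cohorts, list) and raw_cohorts, "cohorts", "must be a non-empty list")
    for i, c in enumerate(raw_cohorts):
        where = f"cohorts[{i}]"
        _require(isinstance(c, dict), where, "must be a mapping")
        for key in ("group_label", "n_participants", "wf_distribution", "prior_width_distribution"):
            _require(key in c, f"{where}.{key}", "is required")
        for key in ("wf_distribution", "prior_width_distribution", "bias_distribution"):
            if key in c:
                val = c[key]
                _require(
                    isinstance(val, (list, tuple)) and len(val) == 2,
                    f"{where}.{key}",
                    "must be a [mean, sd] pair",
                )
                _require(float(val[1]) >= 0, f"{where}.{key}", "sd must be >= 0")
        c = dict(c)
        c.setdefault("seed", raw["seed"] + i)
        try:
            cohorts.append(CohortSpec.from_dict(c))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"{where}: {exc}") from exc

    analysis = raw.get("analysis", {})
    landscape = raw.get("landscape", {})
    cfg = RunConfig(
        seed=raw["seed"],
        cohorts=cohorts,
        paradigm=paradigm,
        discrimination_trials=raw.get("discrimination_trials", 54),
        normaliser_ms=analysis.get("normaliser_ms"),
        match_tolerance_ms=analysis.get("match_tolerance_ms", 5.0),
        split_half=analysis.get("split_half", True),
        landscape_wf_grid=landscape.get("wf_grid", RunConfig.__dataclass_fields__["landscape_wf_grid"].default_factory()),
        landscape_prior_grid_ms=landscape.get("prior_grid_ms", [100.0, 200.0, 300.0, 400.0]),
        landscape_reps=landscape.get("reps", 1000),
        compare_groups=analysis.get("compare_groups", []),
    )
    _require(cfg.landscape_reps >= 2, "landscape.reps", "must be >= 2")
    _require(len(cfg.landscape_prior_grid_ms) >= 2, "landscape.prior_grid_ms", "needs >= 2 widths")
    if cfg.normaliser_ms is not None:
        _require(cfg.normaliser_ms > 0, "analysis.normaliser_ms", "must be > 0")
    labels = {c.group_label for c in cfg.cohorts}
    for pair in cfg.compare_groups:
        _require(
            isinstance(pair, (list, tuple)) and len(pair) == 2 and set(pair) <= labels,
            "analysis.compare_groups",
            f"each entry must name two configured groups (got {pair!r})",
        )
    return cfg
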