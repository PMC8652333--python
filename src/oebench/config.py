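"""Experiment configuration: YAML/JSON schema -> typed config objects.

An experiment config has two sections: ``scenario`` (what data to simulate)
and ``analysis`` (how to analyse it), plus a ``scenario_id``.  Minimal
example::

    scenario_id: quickstart
    scenario:
      n_persons: 2000
      seed: 7
      surveillance_months: 12
      uptake: {kind: rapid, coverage: 0.4}
      outcomes:
        negative_controls: {n: 12, base_rate: 0.4}
    analysis:
      accrual_months: [6, 12]

Outcome definitions may be given as an explicit ``defs`` list or via the
``negative_controls`` shorthand (n outcomes with log-spaced base rates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .incidence import ALL_DESIGNS, DesignVariant, TimeAtRiskWindow
from .synthetic import (
    DAYS_PER_MONTH,
    BiasKnobs,
    ConfigError,
    OutcomeDef,
    ScenarioConfig,
    UptakeCurve,
    make_negative_controls,
)

_DESIGNS_BY_NAME = {d.name: d for d in ALL_DESIGNS}


@dataclass(frozen=True)
class AnalysisConfig:
    tar: TimeAtRiskWindow = field(default_factory=TimeAtRiskWindow)
    irrs: tuple[float, ...] = (1.5, 2.0, 4.0)
    min_outcomes: int = 25
    accrual_months: tuple[int, ...] | None = None  # None -> every month 1..M
    designs: tuple[DesignVariant, ...] = ALL_DESIGNS
    alpha: float = 0.05
    rate_change_threshold: float = 1.5
    rate_change_rule: str = "maxmin"
    loo_family: bool = True

    def months(self, n_months: int) -> tuple[int, ...]:
        if self.accrual_months is None:
            return tuple(range(1, n_months + 1))
        bad = [m for m in self.accrual_months if not 1 <= m <= n_months]
        if bad:
            raise ConfigError(f"accrual months outside 1..{n_months}: {bad}")
        return tuple(self.accrual_months)


@dataclass(frozen=True)
class ExperimentConfig:
    scenario_id: str
    scenario: ScenarioConfig
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)


def _build_outcomes(spec: dict) -> tuple[OutcomeDef, ...]:
    defs: list[OutcomeDef] = []
    for d in spec.get("defs", []):
        d = dict(d)
        if "age_multipliers" in d:
            d["age_multipliers"] = tuple(d["age_multipliers"])
        defs.append(OutcomeDef(**d))
    shorthand = spec.get("negative_controls")
    if shorthand:
        sh = dict(shorthand)
        n = sh.pop("n")
        if "age_multipliers" in sh:
            sh["age_multipliers"] = tuple(sh["age_multipliers"])
        defs.extend(make_negative_controls(n, **sh))
    return tuple(defs)


def scenario_from_dict(d: dict) -> ScenarioConfig:
    d = dict(d)
    months = d.pop("surveillance_months", 12)
    hist_days = d.pop("historical_days", 365)
    surv_start = d.pop("surveillance_start", hist_days)
    kwargs: dict = {
        "historical_window": tuple(d.pop("historical_window", (0, hist_days))),
        "surveillance_window": tuple(
            d.pop("surveillance_window", (surv_start, surv_start + months * DAYS_PER_MONTH))
        ),
    }
    if "uptake" in d:
        kwargs["uptake"] = UptakeCurve(**d.pop("uptake"))
    if "bias" in d:
        kwargs["bias"] = BiasKnobs(**d.pop("bias"))
    if "outcomes" in d:
        kwargs["outcome_defs"] = _build_outcomes(d.pop("outcomes"))
    if "age_distribution" in d:
        kwargs["age_distribution"] = tuple(d.pop("age_distribution"))
    cfg = ScenarioConfig(**d, **kwargs)
    cfg.validate()
    return cfg


def analysis_from_dict(d: dict) -> AnalysisConfig:
    d = dict(d)
    kwargs: dict = {}
    if "tar" in d:
        start, end = d.pop("tar")
        kwargs["tar"] = TimeAtRiskWindow(start, end)
    if "designs" in d:
        names = d.pop("designs")
        unknown = [n for n in names if n not in _DESIGNS_BY_NAME]
        if unknown:
            raise ConfigError(f"unknown designs {unknown}; choose from {sorted(_DESIGNS_BY_NAME)}")
        kwargs["designs"] = tuple(_DESIGNS_BY_NAME[n] for n in names)
    if "irrs" in d:
        kwargs["irrs"] = tuple(float(r) for r in d.pop("irrs"))
    if "accrual_months" in d:
        am = d.pop("accrual_months")
        kwargs["accrual_months"] = tuple(am) if am is not None else None
    return AnalysisConfig(**d, **kwargs)


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse a YAML or JSON experiment config file."""
    path = Path(path)
    try:
        raw = path.read_text()
    except OSError as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    data = json.loads(raw) if path.suffix == ".json" else yaml.safe_load(raw)
    if not isinstance(data, dict) or "scenario" not in data:
        raise ConfigError(f"{path}: expected a mapping with a 'scenario' section")
    return ExperimentConfig(
        scenario_id=str(data.get("scenario_id", path.stem)),
        scenario=scenario_from_dict(data["scenario"]),
        analysis=analysis_from_dict(data.get("analysis", {})),
    )
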