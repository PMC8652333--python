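"""End-to-end orchestration: scenario -> tables -> rates -> controls ->
estimates -> calibration -> metrics -> report.

Stage outputs are plain files under the run directory so any stage can be
re-run or inspected independently:

* ``tables/``             the five simulated event tables + scenario.json
* ``outcomes_augmented.csv`` outcome table after positive-control injection
* ``controls.csv``        control manifest
* ``estimates.csv``       one row per (control, design, month), calibrated
                          fields included
* ``metrics.csv``         one row per (design, calibration flag, month)
* ``exclusions.csv``      estimability exclusion log
* ``first_detection.csv`` earliest signalling month per positive control
* ``manifest.json``       config hash, seed, file digests

Partial failures (non-estimable cells) never abort a run; they surface as
flagged rows.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import leave_one_out_calibrate
from .config import AnalysisConfig, ExperimentConfig, load_config
from .controls import (
    ControlDefinition,
    controls_frame,
    controls_from_frame,
    synthesize_positive_controls,
)
from .estimation import EffectEstimate, estimate_effect
from .evaluation import (
    estimability_filter,
    metrics_row,
    population_rate_series,
    timeliness_table,
)
from .incidence import (
    DesignVariant,
    RateEstimate,
    draw_anchor_visits,
    expected_count,
    historical_rates,
    observed_rates,
    person_time_by_stratum,
    totals,
)
from .synthetic import EventTables, ScenarioConfig, simulate_scenario, write_scenario

logger = logging.getLogger("oebench")

_ESTIMATE_COLUMNS = [
    "control_id", "design", "month", "observed", "expected", "n_historical",
    "log_irr", "se_log_irr", "ci_low", "ci_high", "p", "llr", "estimable",
    "cal_log_irr", "cal_se", "cal_ci_low", "cal_ci_high", "cal_p",
]


def estimates_to_frame(estimates: list[EffectEstimate]) -> pd.DataFrame:
    rows = [{c: getattr(e, c) for c in _ESTIMATE_COLUMNS} for e in estimates]
    return pd.DataFrame(rows, columns=_ESTIMATE_COLUMNS)


def estimates_from_frame(df: pd.DataFrame) -> list[EffectEstimate]:
    out = []
    for rec in df.to_dict("records"):
        clean = {k: (None if pd.isna(v) else v) for k, v in rec.items()}
        clean["observed"] = int(clean["observed"] or 0)
        clean["month"] = int(clean["month"])
        clean["n_historical"] = int(clean["n_historical"] or 0)
        clean["estimable"] = bool(clean["estimable"])
        out.append(EffectEstimate(**clean))
    return out


def _marginalize(rates: list[RateEstimate]) -> list[RateEstimate]:
    if not rates:
        return []
    ev, pt = totals(rates)
    if pt == 0:
        return []
    return [RateEstimate(rates[0].outcome_id, None, ev, pt)]


def compute_estimates(
    tables: EventTables,
    controls: list[ControlDefinition],
    scenario: ScenarioConfig,
    analysis: AnalysisConfig,
) -> list[EffectEstimate]:
    """Uncalibrated effect estimates for every (control, design, accrual month).

    Stratified observed and historical rates are computed once per outcome
    and marginalized for the unadjusted designs; visit anchors are drawn once
    per run (seeded) and shared across outcomes, mirroring one index visit
    per person.
    """
    months = analysis.months(scenario.n_months)
    outcome_ids = [c.control_id for c in controls]
    surv_start = scenario.surveillance_window[0]
    anchored_needed = any(d.anchored for d in analysis.designs)
    anchors = (
        draw_anchor_visits(tables, scenario.historical_window, seed=scenario.seed)
        if anchored_needed
        else None
    )

    # pre-split the outcome table so per-outcome calls don't rescan all rows
    grouped = {oid: grp for oid, grp in tables.outcomes.groupby("outcome_id", sort=False)}
    empty_outcomes = tables.outcomes.iloc[0:0]

    estimates: list[EffectEstimate] = []
    for oid in outcome_ids:
        sub = EventTables(
            persons=tables.persons,
            observation_periods=tables.observation_periods,
            visits=tables.visits,
            exposures=tables.exposures,
            outcomes=grouped.get(oid, empty_outcomes),
        )
        hist: dict[bool, dict[bool, list[RateEstimate]]] = {}  # [anchored][adjusted]
        for anchored in {d.anchored for d in analysis.designs}:
            strat = historical_rates(
                sub, oid, analysis.tar, DesignVariant(adjusted=True, anchored=anchored),
                scenario.historical_window, anchors=anchors if anchored else None,
                seed=scenario.seed,
            )
            hist[anchored] = {True: strat, False: _marginalize(strat)}

        for month in months:
            obs_strat = observed_rates(
                sub, scenario.vaccine_id, oid, analysis.tar,
                DesignVariant(adjusted=True), month, surv_start,
            )
            obs = {True: obs_strat, False: _marginalize(obs_strat)}
            for design in analysis.designs:
                o_rates = obs[design.adjusted]
                h_rates = hist[design.anchored][design.adjusted]
                O, _ = totals(o_rates)
                E = expected_count(h_rates, person_time_by_stratum(o_rates))
                n_hist, _ = totals(h_rates)
                est = estimate_effect(O, E, n_hist).with_ids(oid, design.name, month)
                estimates.append(est)
    return estimates


def calibrate_cells(
    estimates: list[EffectEstimate],
    controls: list[ControlDefinition],
    loo_family: bool = True,
) -> list[EffectEstimate]:
    """Leave-one-out calibration applied independently per (design, month) cell."""
    out: list[EffectEstimate] = []
    df = pd.DataFrame({"design": [e.design for e in estimates],
                       "month": [e.month for e in estimates],
                       "idx": range(len(estimates))})
    for (_, _), grp in df.groupby(["design", "month"]):
        cell = [estimates[i] for i in grp["idx"]]
        out.extend(leave_one_out_calibrate(cell, controls, loo_family=loo_family))
    return out


def metrics_table(
    estimates: list[EffectEstimate],
    controls: list[ControlDefinition],
    tables: EventTables,
    scenario: ScenarioConfig,
    analysis: AnalysisConfig,
    scenario_id: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble MetricsRows per (design, calibration flag, month) + exclusion log."""
    negatives = [c.control_id for c in controls if not c.synthesized]
    monthly = population_rate_series(
        tables, negatives, scenario.surveillance_window[0], scenario.n_months
    )
    rows = []
    excl_rows = []
    df = estimates_to_frame(estimates)
    for (design, month), grp in df.groupby(["design", "month"]):
        cell = [estimates[i] for i in grp.index]
        kept, exclusions = estimability_filter(
            cell, controls, monthly,
            threshold=analysis.rate_change_threshold, rule=analysis.rate_change_rule,
        )
        for x in exclusions:
            excl_rows.append({"design": design, "month": month,
                              "control_id": x.control_id, "reason": x.reason})
        for calibrated in (False, True):
            row = metrics_row(kept, controls, calibrated,
                              n_excluded=len(exclusions), alpha=analysis.alpha)
            row.update({"scenario_id": scenario_id, "vaccine_id": scenario.vaccine_id,
                        "design": design, "month": int(month)})
            rows.append(row)
    lead = ["scenario_id", "vaccine_id", "design", "month", "calibrated"]
    metrics = pd.DataFrame(rows)
    metrics = metrics[lead + [c for c in metrics.columns if c not in lead]]
    return metrics.sort_values(lead).reset_index(drop=True), pd.DataFrame(excl_rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_experiment(
    config: ExperimentConfig | str | Path,
    out_dir: str | Path,
    seed: int | None = None,
) -> Path:
    """Execute every stage for one experiment config; returns the run directory."""
    if not isinstance(config, ExperimentConfig):
        config = load_config(config)
    scenario = config.scenario
    if seed is not None:
        scenario = replace(scenario, seed=seed)
    analysis = config.analysis
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("simulating scenario %s (n=%d)", config.scenario_id, scenario.n_persons)
    tables = simulate_scenario(scenario)
    write_scenario(tables, scenario, out / "tables")

    negatives = [od.outcome_id for od in scenario.outcome_defs]
    logger.info("synthesizing positive controls from %d negatives", len(negatives))
    tables_aug, controls = synthesize_positive_controls(
        tables, scenario.vaccine_id, negatives, analysis.tar,
        irrs=analysis.irrs, min_outcomes=analysis.min_outcomes, seed=scenario.seed,
    )
    tables_aug.outcomes.to_csv(out / "outcomes_augmented.csv", index=False)
    controls_frame(controls).to_csv(out / "controls.csv", index=False)

    logger.info("estimating effects (%d designs x %d months x %d controls)",
                len(analysis.designs), len(analysis.months(scenario.n_months)),
                len(controls))
    estimates = compute_estimates(tables_aug, controls, scenario, analysis)
    estimates = calibrate_cells(estimates, controls, loo_family=analysis.loo_family)
    estimates_to_frame(estimates).to_csv(out / "estimates.csv", index=False)

    logger.info("computing metrics")
    metrics, exclusions = metrics_table(
        estimates, controls, tables_aug, scenario, analysis, config.scenario_id
    )
    metrics.to_csv(out / "metrics.csv", index=False)
    exclusions.to_csv(out / "exclusions.csv", index=False)

    _, det = timeliness_table(metrics, estimates, controls, alpha=analysis.alpha)
    det.to_csv(out / "first_detection.csv", index=False)

    config_blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=list)
    manifest = {
        "scenario_id": config.scenario_id,
        "seed": scenario.seed,
        "config_sha256": hashlib.sha256(config_blob.encode()).hexdigest(),
        "oebench_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime()),
        "files": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*.csv")) + sorted(out.rglob("*.json"))
            if p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    logger.info("run complete: %s", out)
    return out


def report(
    metrics: pd.DataFrame,
    out_dir: str | Path,
    plots: bool = False,
    tables: EventTables | None = None,
    scenario: ScenarioConfig | None = None,
) -> Path:
    """Write a per-scenario markdown summary (and optional plots) from metrics."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / "summary.md"
    if metrics.empty:
        logger.warning("empty metrics table; writing empty report")
        path.write_text("# Run summary\n\nNo metrics available.\n")
        return path

    lines = ["# Run summary", ""]
    for sid, sgrp in metrics.groupby("scenario_id"):
        last_month = sgrp["month"].max()
        lines.append(f"## Scenario `{sid}` (month {last_month})")
        lines.append("")
        final = sgrp[sgrp["month"] == last_month]
        cols = ["design", "calibrated", "type1", "type2", "auc", "coverage",
                "mean_precision", "mse"]
        cols = [c for c in cols if c in final.columns]
        lines.append("```")
        lines.append(final[cols].round(3).to_string(index=False))
        lines.append("```")
        lines.append("")
    path.write_text("\n".join(lines))

    if plots:
        _plot_metrics(metrics, out, tables, scenario)
    return path


def _plot_metrics(metrics, out: Path, tables=None, scenario=None) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    last = metrics[metrics["month"] == metrics["month"].max()]
    fig, axes = plt.subplots(1, 2, figsize=(10, 4), sharey=True)
    for ax, metric in zip(axes, ("type1", "type2")):
        for calibrated, grp in last.groupby("calibrated"):
            ax.bar(
                [f"{d}\n{'cal' if calibrated else 'uncal'}" for d in grp["design"]],
                grp[metric],
                alpha=0.7,
                label="calibrated" if calibrated else "uncalibrated",
            )
        ax.set_title(metric)
        ax.tick_params(axis="x", rotation=60)
    axes[0].legend()
    fig.tight_layout()
    fig.savefig(out / "error_by_design.png", dpi=100)
    plt.close(fig)

    series = metrics[~metrics["calibrated"]]
    fig, ax = plt.subplots(figsize=(7, 4))
    for design, grp in series.groupby("design"):
        ax.plot(grp["month"], grp["type1"], marker="o", label=design)
    ax.set_xlabel("accrual month")
    ax.set_ylabel("type 1 error")
    ax.legend()
    if tables is not None and scenario is not None and not tables.exposures.empty:
        ax2 = ax.twinx()
        months = np.arange(1, scenario.n_months + 1)
        bounds = scenario.surveillance_window[0] + months * 30
        cum = [
            (tables.exposures["exposure_day"].to_numpy() < b).mean()
            for b in bounds
        ]
        uptake = np.array(cum) * len(tables.exposures) / max(len(tables.persons), 1)
        ax2.fill_between(months, uptake, color="orange", alpha=0.3)
        ax2.set_ylabel("cumulative uptake")
    fig.tight_layout()
    fig.savefig(out / "timeliness.png", dpi=100)
    plt.close(fig)
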