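"""Shared simulated scenarios (session-scoped: the expensive fixtures are
reused across unit, property and acceptance tests)."""

from __future__ import annotations

from dataclasses import replace

import pytest

from oebench.config import AnalysisConfig
from oebench.controls import ControlDefinition, synthesize_positive_controls
from oebench.fixtures import scenario_profile
from oebench.incidence import DesignVariant
from oebench.pipeline import calibrate_cells, compute_estimates
from oebench.synthetic import OutcomeDef, UptakeCurve, make_negative_controls, simulate_scenario

UNADJUSTED = DesignVariant(False, False)
AGE_SEX = DesignVariant(True, False)
ANCHORED = DesignVariant(False, True)


def negatives_as_controls(cfg) -> list[ControlDefinition]:
    return [
        ControlDefinition(od.outcome_id, od.outcome_id, 1.0, synthesized=False)
        for od in cfg.outcome_defs
    ]


@pytest.fixture(scope="session")
def rapid_50k():
    """50,000-person rapid-uptake unbiased scenario with one ample parent outcome."""
    cfg = scenario_profile(
        "rapid_unbiased",
        n_persons=50_000,
        seed=202,
        visit_rate=0.5,
        outcome_defs=(OutcomeDef("parent", base_rate=0.08),),
    )
    return cfg, simulate_scenario(cfg)


@pytest.fixture(scope="session")
def nominal_cell():
    """Unbiased scenario, 220 negative controls, unadjusted estimates at month 12."""
    cfg = scenario_profile(
        "rapid_unbiased",
        n_persons=30_000,
        seed=303,
        visit_rate=1.0,
        uptake=UptakeCurve("rapid", 0.5),
        outcome_defs=make_negative_controls(220, base_rate=0.02),
    )
    tables = simulate_scenario(cfg)
    analysis = AnalysisConfig(accrual_months=(12,), designs=(UNADJUSTED,))
    controls = negatives_as_controls(cfg)
    estimates = compute_estimates(tables, controls, cfg, analysis)
    return {"config": cfg, "tables": tables, "controls": controls, "estimates": estimates}


@pytest.fixture(scope="session")
def biased_cell():
    """Constant multiplicative bias (healthy-vaccinee shift), 200 negatives plus
    positives at IRRs 1.5/2/4, LOO-calibrated unadjusted estimates at month 12."""
    cfg = scenario_profile(
        "healthy_vaccinee",
        n_persons=20_000,
        seed=404,
        visit_rate=1.0,
        uptake=UptakeCurve("rapid", 0.5),
        outcome_defs=make_negative_controls(200, base_rate=0.06, rate_spread=1.5),
    )
    tables = simulate_scenario(cfg)
    analysis = AnalysisConfig(accrual_months=(12,), designs=(UNADJUSTED,))
    negatives = [od.outcome_id for od in cfg.outcome_defs]
    tables_aug, controls = synthesize_positive_controls(
        tables, cfg.vaccine_id, negatives, analysis.tar,
        irrs=analysis.irrs, min_outcomes=analysis.min_outcomes, seed=cfg.seed,
    )
    estimates = compute_estimates(tables_aug, controls, cfg, analysis)
    calibrated = calibrate_cells(estimates, controls)
    return {
        "config": cfg,
        "tables": tables_aug,
        "controls": controls,
        "estimates": calibrated,
    }


@pytest.fixture(scope="session")
def confounded_cells():
    """Age-confounded scenario: unadjusted vs age-sex adjusted estimates."""
    cfg = scenario_profile(
        "age_confounded",
        n_persons=10_000,
        seed=505,
        visit_rate=1.0,
        outcome_defs=make_negative_controls(
            150, base_rate=0.04, rate_spread=1.5,
            age_multipliers=tuple(1.25**b for b in range(10)),
        ),
    )
    tables = simulate_scenario(cfg)
    analysis = AnalysisConfig(accrual_months=(12,), designs=(UNADJUSTED, AGE_SEX))
    controls = negatives_as_controls(cfg)
    estimates = compute_estimates(tables, controls, cfg, analysis)
    return {"config": cfg, "tables": tables, "controls": controls, "estimates": estimates}


@pytest.fixture(scope="session")
def visit_capture_cells():
    """Visit-proximity recording bias: unadjusted vs visit-anchored estimates."""
    cfg = scenario_profile(
        "visit_capture",
        n_persons=10_000,
        seed=606,
        outcome_defs=make_negative_controls(150, base_rate=0.05, rate_spread=1.5),
    )
    tables = simulate_scenario(cfg)
    analysis = AnalysisConfig(accrual_months=(12,), designs=(UNADJUSTED, ANCHORED))
    controls = negatives_as_controls(cfg)
    estimates = compute_estimates(tables, controls, cfg, analysis)
    return {"config": cfg, "tables": tables, "controls": controls, "estimates": estimates}


def _timeliness_run(profile: str, seed: int):
    cfg = scenario_profile(
        profile,
        n_persons=20_000,
        seed=seed,
        visit_rate=1.0,
        outcome_defs=make_negative_controls(10, base_rate=0.02, rate_spread=1.5),
    )
    tables = simulate_scenario(cfg)
    # scaled-down threshold: at desk scale, parents cannot both accrue the
    # default 25 exposed-TAR events and keep month-1 detection non-trivial
    analysis = AnalysisConfig(designs=(UNADJUSTED,), irrs=(4.0,), min_outcomes=5)
    negatives = [od.outcome_id for od in cfg.outcome_defs]
    tables_aug, controls = synthesize_positive_controls(
        tables, cfg.vaccine_id, negatives, analysis.tar,
        irrs=analysis.irrs, min_outcomes=analysis.min_outcomes, seed=cfg.seed,
    )
    estimates = compute_estimates(tables_aug, controls, cfg, analysis)
    return {"config": cfg, "controls": controls, "estimates": estimates}


@pytest.fixture(scope="session")
def timeliness_runs():
    """Rapid (9-month flu-like) vs slow (12-month HPV-like) campaigns with
    IRR=4 positives, monthly accrual."""
    return {
        "rapid": _timeliness_run("ccae_like", 707),
        "slow": _timeliness_run("mdcd_like", 808),
    }
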