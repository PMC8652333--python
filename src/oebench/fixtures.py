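"""Tiny hand-computable fixtures and canned scenario profiles.

Each fixture is a literal :class:`EventTables` plus an expectation ledger —
a dict of values recomputable by hand (the derivations are spelled out in
the builder bodies).  Scenario profiles are ready-made
:class:`ScenarioConfig` presets used by the test suite, the docs and the
acceptance script; they are constructors, not data files, so every keyword
can be overridden.
"""

from __future__ import annotations

from typing import Callable

import pandas as pd

from .incidence import RateEstimate
from .synthetic import (
    DAYS_PER_MONTH,
    DAYS_PER_YEAR,
    BiasKnobs,
    EventTables,
    OutcomeDef,
    ScenarioConfig,
    UptakeCurve,
    make_negative_controls,
)

_REGISTRY: dict[str, Callable[[], tuple[EventTables, dict]]] = {}


def _fixture(fn: Callable[[], tuple[EventTables, dict]]):
    _REGISTRY[fn.__name__.lstrip("_")] = fn
    return fn


def load_fixture(name: str) -> tuple[EventTables, dict]:
    """Return (tables, expectation ledger) for a registered fixture name."""
    try:
        builder = _REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown fixture {name!r}; known: {sorted(_REGISTRY)}") from None
    return builder()


def fixture_names() -> list[str]:
    return sorted(_REGISTRY)


def _tables(persons, obs, visits=(), exposures=(), outcomes=()) -> EventTables:
    t = EventTables.empty()
    t.persons = pd.DataFrame(persons, columns=["person_id", "sex", "birth_day"])
    t.observation_periods = pd.DataFrame(obs, columns=["person_id", "start_day", "end_day"])
    if visits:
        t.visits = pd.DataFrame(visits, columns=["person_id", "visit_day"])
    if exposures:
        t.exposures = pd.DataFrame(exposures, columns=["person_id", "vaccine_id", "exposure_day"])
    if outcomes:
        t.outcomes = pd.DataFrame(outcomes, columns=["person_id", "outcome_id", "outcome_day"])
    return t


@_fixture
def _two_person_half_rate() -> tuple[EventTables, dict]:
    # 2 persons observed all of the historical year [0, 365); 1 event total.
    # Marginal rate = 1 event / (2 * 365/365.25 py) = 365.25/730 per py.
    tables = _tables(
        persons=[(0, "M", -10000), (1, "F", -20000)],
        obs=[(0, 0, 365), (1, 0, 365)],
        outcomes=[(0, "nc", 100)],
    )
    expected = {
        "historical_interval": (0, 365),
        "events": 1,
        "person_time_years": 2 * 365 / DAYS_PER_YEAR,
        "rate": 1 / (2 * 365 / DAYS_PER_YEAR),  # ~0.5/py
    }
    return tables, expected


@_fixture
def _five_person_rates() -> tuple[EventTables, dict]:
    # Ages at day 0: p0 M 25, p1 F 25, p2 F 67, p3 M 40, p4 F 8.
    # Historical interval [0, 365); all persons observed [0, 730).
    # Events: p0 has nc at days 50 and 200 (one incident person), p1 at 400
    # (outside interval), p2 at 10, p4 none -> 2 incident persons.
    yr = DAYS_PER_YEAR
    tables = _tables(
        persons=[
            (0, "M", -int(25 * yr)),
            (1, "F", -int(25 * yr)),
            (2, "F", -int(67 * yr)),
            (3, "M", -int(40 * yr)),
            (4, "F", -int(8 * yr)),
        ],
        obs=[(p, 0, 730) for p in range(5)],
        outcomes=[
            (0, "nc", 50),
            (0, "nc", 200),
            (1, "nc", 400),
            (2, "nc", 10),
        ],
    )
    pt1 = 365 / yr  # each person contributes the whole interval
    expected = {
        "historical_interval": (0, 365),
        "marginal": {"events": 2, "person_time_years": 5 * pt1},
        # hand tally per (10-year band, sex) stratum at interval start:
        "strata": {
            (2, "M"): {"events": 1, "person_time_years": pt1},  # p0
            (2, "F"): {"events": 0, "person_time_years": pt1},  # p1
            (6, "F"): {"events": 1, "person_time_years": pt1},  # p2
            (4, "M"): {"events": 0, "person_time_years": pt1},  # p3
            (0, "F"): {"events": 0, "person_time_years": pt1},  # p4
        },
    }
    return tables, expected


def _threshold_tables(n_events: int) -> EventTables:
    # 30 vaccinated persons (exposure day 400), full 28-day TARs; the first
    # n_events of them have one parent-outcome event inside the TAR (day 405).
    persons = [(p, "M", -12000) for p in range(30)]
    obs = [(p, 0, 760) for p in range(30)]
    exposures = [(p, "vaccine", 400) for p in range(30)]
    outcomes = [(p, "nc", 405) for p in range(n_events)]
    # one event outside every TAR so the outcome id always exists
    outcomes.append((0, "nc", 10))
    return _tables(persons, obs, exposures=exposures, outcomes=outcomes)


@_fixture
def _threshold_24_events() -> tuple[EventTables, dict]:
    # 24 first-events among exposed TARs < 25 -> no positives synthesized.
    return _threshold_tables(24), {
        "vaccine_id": "vaccine",
        "negative_ids": ["nc"],
        "n_positive_controls": 0,
    }


@_fixture
def _threshold_25_events() -> tuple[EventTables, dict]:
    # exactly at the threshold -> one positive per target IRR.
    return _threshold_tables(25), {
        "vaccine_id": "vaccine",
        "negative_ids": ["nc"],
        "n_positive_controls": 3,
    }


@_fixture
def _six_stratum_expected() -> tuple[EventTables, dict]:
    # Pure-arithmetic fixture for expected_count: six strata with known
    # background rates and observed person-time.
    # E = 0.1*2 + 0.2*1 + 0.3*4 + 0.05*10 + 0.5*0.5 + 1.0*1 = 3.35
    rates = [
        RateEstimate("nc", (0, "F"), 10, 100.0),   # 0.10/py
        RateEstimate("nc", (0, "M"), 20, 100.0),   # 0.20/py
        RateEstimate("nc", (1, "F"), 30, 100.0),   # 0.30/py
        RateEstimate("nc", (1, "M"), 5, 100.0),    # 0.05/py
        RateEstimate("nc", (2, "F"), 50, 100.0),   # 0.50/py
        RateEstimate("nc", (2, "M"), 100, 100.0),  # 1.00/py
    ]
    observed_pt = {
        (0, "F"): 2.0, (0, "M"): 1.0, (1, "F"): 4.0,
        (1, "M"): 10.0, (2, "F"): 0.5, (2, "M"): 1.0,
    }
    expected_e = 0.1 * 2 + 0.2 * 1 + 0.3 * 4 + 0.05 * 10 + 0.5 * 0.5 + 1.0 * 1
    return EventTables.empty(), {
        "background": rates,
        "observed_person_time": observed_pt,
        "expected_count": expected_e,
    }


# ---------------------------------------------------------------------------
# scenario profiles
# ---------------------------------------------------------------------------

def scenario_profile(name: str, **overrides) -> ScenarioConfig:
    """Named ScenarioConfig preset; keyword arguments override any field.

    Profiles: ``quickstart``, ``ccae_like`` (female share 51.1%, rapid
    9-month campaign), ``mdcd_like`` (female share 56.23%, slow 12-month
    campaign), ``rapid_unbiased``, ``slow_unbiased``, ``age_confounded``,
    ``healthy_vaccinee``, ``visit_capture``.
    """
    surv9 = (365, 365 + 9 * DAYS_PER_MONTH)
    surv12 = (365, 365 + 12 * DAYS_PER_MONTH)
    base = dict(
        n_persons=10_000,
        seed=0,
        female_fraction=0.511,
        visit_rate=3.0,
        surveillance_window=surv12,
        uptake=UptakeCurve("rapid", 0.4),
        outcome_defs=make_negative_controls(20, base_rate=0.2),
    )
    profiles: dict[str, dict] = {
        "quickstart": dict(
            n_persons=2_000,
            outcome_defs=make_negative_controls(12, base_rate=1.0),
        ),
        "ccae_like": dict(
            female_fraction=0.511,
            surveillance_window=surv9,
            uptake=UptakeCurve("rapid", 0.4),
        ),
        "mdcd_like": dict(
            female_fraction=0.5623,
            surveillance_window=surv12,
            uptake=UptakeCurve("slow", 0.4),
        ),
        "rapid_unbiased": dict(uptake=UptakeCurve("rapid", 0.4)),
        "slow_unbiased": dict(uptake=UptakeCurve("slow", 0.4)),
        "age_confounded": dict(
            bias=BiasKnobs(age_confounding_strength=0.6),
            outcome_defs=make_negative_controls(
                20, base_rate=0.2,
                age_multipliers=tuple(1.5**b for b in range(10)),
            ),
        ),
        "healthy_vaccinee": dict(bias=BiasKnobs(healthy_vaccinee_shift=1.5)),
        "visit_capture": dict(
            bias=BiasKnobs(visit_capture_boost=3.0, visit_capture_days=30)
        ),
    }
    if name not in profiles:
        raise KeyError(f"unknown profile {name!r}; known: {sorted(profiles)}")
    params = {**base, **profiles[name], **overrides}
    cfg = ScenarioConfig(**params)
    cfg.validate()
    return cfg
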