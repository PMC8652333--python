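"""Background (historical) and observed (post-vaccination) incidence rates.

Four design variants are supported, crossing two switches:

* ``adjusted`` — stratify rates by (10-year age band, sex) instead of a
  single marginal stratum;
* ``anchored`` — estimate background person-time in a time-at-risk window
  following one random outpatient visit per person, instead of the full
  historical interval (mimics the healthcare-contact context of vaccination).

All rates are first-event-per-person incidence: within a person's
time-at-risk only the earliest occurrence counts.  Observed rates support
monthly data accrual: with accrual month ``m`` only exposures and events
recorded before the end of surveillance month ``m`` are visible and
time-at-risk is clipped at that boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .synthetic import (
    DAYS_PER_MONTH,
    DAYS_PER_YEAR,
    STREAM_ANCHOR,
    EventTables,
    age_band,
    stream_rng,
)

Stratum = tuple[int, str] | None  # (age band, sex) or None for marginal


@dataclass(frozen=True)
class TimeAtRiskWindow:
    """Post-index window in days, inclusive offsets; default days 1-28."""

    start_offset: int = 1
    end_offset: int = 28

    def __post_init__(self) -> None:
        if not 1 <= self.start_offset <= self.end_offset:
            raise ValueError("need 1 <= start_offset <= end_offset")

    def bounds(self, index_day: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Half-open day interval [index+start, index+end+1)."""
        index_day = np.asarray(index_day)
        return index_day + self.start_offset, index_day + self.end_offset + 1


@dataclass(frozen=True)
class DesignVariant:
    adjusted: bool = False
    anchored: bool = False

    @property
    def name(self) -> str:
        return {
            (False, False): "unadjusted",
            (True, False): "age_sex",
            (False, True): "anchored",
            (True, True): "anchored_age_sex",
        }[(self.adjusted, self.anchored)]


ALL_DESIGNS: tuple[DesignVariant, ...] = (
    DesignVariant(False, False),
    DesignVariant(True, False),
    DesignVariant(False, True),
    DesignVariant(True, True),
)


@dataclass(frozen=True)
class RateEstimate:
    """Events and person-time for one outcome in one stratum of one design."""

    outcome_id: str
    stratum: Stratum
    events: int
    person_time: float  # person-years

    @property
    def estimable(self) -> bool:
        return self.person_time > 0

    @property
    def rate(self) -> float:
        """Events per person-year; NaN when not estimable."""
        return self.events / self.person_time if self.estimable else float("nan")


def totals(rates: Sequence[RateEstimate]) -> tuple[int, float]:
    """(total events, total person-years) across strata."""
    return sum(r.events for r in rates), sum(r.person_time for r in rates)


def person_time_by_stratum(rates: Sequence[RateEstimate]) -> dict[Stratum, float]:
    return {r.stratum: r.person_time for r in rates}


# ---------------------------------------------------------------------------
# person-level scaffolding
# ---------------------------------------------------------------------------

def _person_arrays(tables: EventTables):
    persons = tables.persons
    pid = persons["person_id"].to_numpy()
    obs = tables.observation_periods.drop_duplicates("person_id").set_index("person_id")
    return (
        pid,
        persons["birth_day"].to_numpy(),
        persons["sex"].to_numpy(),
        obs.loc[pid, "start_day"].to_numpy(),
        obs.loc[pid, "end_day"].to_numpy(),
    )


def draw_anchor_visits(
    tables: EventTables, interval: tuple[int, int], seed: int = 0
) -> pd.Series:
    """One outpatient visit per person, uniform among their visits in ``interval``.

    Returns a Series indexed by person_id with the anchor day; persons with
    no visit in the interval are absent.  Deterministic for a fixed seed.
    """
    v = tables.visits
    v = v[(v["visit_day"] >= interval[0]) & (v["visit_day"] < interval[1])]
    if v.empty:
        return pd.Series(dtype=np.int64, name="anchor_day")
    v = v.sort_values(["person_id", "visit_day"], kind="mergesort")
    pid = v["person_id"].to_numpy()
    days = v["visit_day"].to_numpy()
    uniq, start = np.unique(pid, return_index=True)
    counts = np.diff(np.append(start, len(pid)))
    rng = stream_rng(seed, STREAM_ANCHOR)
    pick = start + np.floor(rng.random(len(uniq)) * counts).astype(np.int64)
    return pd.Series(days[pick], index=pd.Index(uniq, name="person_id"), name="anchor_day")


def _first_event_mask(
    tables: EventTables,
    outcome_id: str,
    pid: np.ndarray,
    tar_start: np.ndarray,
    tar_end: np.ndarray,
) -> np.ndarray:
    """Boolean per person: has >= 1 occurrence of ``outcome_id`` in their TAR."""
    oc = tables.outcomes
    oc = oc[oc["outcome_id"] == outcome_id]
    has = np.zeros(len(pid), dtype=bool)
    if oc.empty:
        return has
    pos = pd.Index(pid).get_indexer(oc["person_id"])
    valid = pos >= 0
    pos = pos[valid]
    day = oc["outcome_day"].to_numpy()[valid]
    inside = (day >= tar_start[pos]) & (day < tar_end[pos])
    has[pos[inside]] = True
    return has


def _emit(
    outcome_id: str,
    events_mask: np.ndarray,
    pt_days: np.ndarray,
    strata_keys: tuple[np.ndarray, np.ndarray] | None,
) -> list[RateEstimate]:
    """Aggregate to RateEstimates, marginal or per (band, sex) stratum."""
    active = pt_days > 0
    if strata_keys is None:
        pt = pt_days[active].sum() / DAYS_PER_YEAR
        if pt == 0:
            return []
        return [RateEstimate(outcome_id, None, int(events_mask[active].sum()), float(pt))]
    bands, sexes = strata_keys
    out: list[RateEstimate] = []
    df = pd.DataFrame({
        "band": bands[active],
        "sex": sexes[active],
        "ev": events_mask[active].astype(int),
        "pt": pt_days[active] / DAYS_PER_YEAR,
    })
    for (band, sex), grp in df.groupby(["band", "sex"], sort=True):
        out.append(RateEstimate(outcome_id, (int(band), str(sex)),
                                int(grp["ev"].sum()), float(grp["pt"].sum())))
    return out


# ---------------------------------------------------------------------------
# rate operations
# ---------------------------------------------------------------------------

def historical_rates(
    tables: EventTables,
    outcome_id: str,
    window: TimeAtRiskWindow,
    variant: DesignVariant,
    historical_interval: tuple[int, int],
    *,
    anchors: pd.Series | None = None,
    seed: int = 0,
) -> list[RateEstimate]:
    """Background incidence of ``outcome_id`` in the historical interval.

    Unanchored: cohort-style — person-time is each person's overlap with the
    interval and events are first occurrences within it.  Anchored: index is
    one random outpatient visit per person in the interval (reusable via
    ``anchors``; persons without a visit contribute nothing) and person-time
    is the TAR window after that visit clipped to observation.

    Returns one :class:`RateEstimate` per stratum with positive person-time
    (``adjusted`` variants stratify by age band and sex); an empty list means
    the rate is not estimable.
    """
    pid, birth, sex, obs_start, obs_end = _person_arrays(tables)
    h0, h1 = historical_interval

    if variant.anchored:
        if anchors is None:
            anchors = draw_anchor_visits(tables, historical_interval, seed=seed)
        anchor = anchors.reindex(pid).to_numpy(dtype=float)
        has_anchor = ~np.isnan(anchor)
        index_day = np.where(has_anchor, anchor, 0).astype(np.int64)
        tar_start, tar_end = window.bounds(index_day)
        tar_start = np.maximum(tar_start, obs_start)
        tar_end = np.minimum(tar_end, obs_end)
        tar_end = np.where(has_anchor, tar_end, tar_start)  # zero PT without anchor
    else:
        index_day = np.maximum(h0, obs_start)
        tar_start = np.maximum(h0, obs_start)
        tar_end = np.minimum(h1, obs_end)

    pt_days = np.maximum(tar_end - tar_start, 0)
    events = _first_event_mask(tables, outcome_id, pid, tar_start,
                               np.maximum(tar_end, tar_start))
    strata = (age_band(birth, index_day), sex) if variant.adjusted else None
    return _emit(outcome_id, events, pt_days, strata)


def observed_rates(
    tables: EventTables,
    vaccine_id: str,
    outcome_id: str,
    window: TimeAtRiskWindow,
    variant: DesignVariant,
    accrual_month: int,
    surveillance_start: int,
) -> list[RateEstimate]:
    """Post-vaccination incidence with data accrued through ``accrual_month``.

    Index is the (single) vaccination day; only exposures and outcome events
    before the accrual boundary are visible and the TAR is clipped there and
    at observation end.  Empty list when nobody is exposed yet.
    """
    if accrual_month < 1:
        raise ValueError("accrual_month must be >= 1")
    boundary = surveillance_start + accrual_month * DAYS_PER_MONTH

    pid, birth, sex, obs_start, obs_end = _person_arrays(tables)
    ex = tables.exposures
    ex = ex[(ex["vaccine_id"] == vaccine_id) & (ex["exposure_day"] < boundary)]
    if ex.empty:
        return []
    ex = ex.sort_values("exposure_day", kind="mergesort").drop_duplicates("person_id")

    pos = pd.Index(pid).get_indexer(ex["person_id"])
    exp_day = np.full(len(pid), -1, dtype=np.int64)
    exp_day[pos] = ex["exposure_day"].to_numpy()
    exposed = exp_day >= 0

    tar_start, tar_end = window.bounds(exp_day)
    tar_end = np.minimum(np.minimum(tar_end, obs_end), boundary)
    tar_start = np.maximum(tar_start, obs_start)
    pt_days = np.where(exposed, np.maximum(tar_end - tar_start, 0), 0)

    events = _first_event_mask(tables, outcome_id, pid, tar_start,
                               np.maximum(tar_end, tar_start)) & exposed
    strata = (age_band(birth, exp_day), sex) if variant.adjusted else None
    return _emit(outcome_id, events, pt_days, strata)


def expected_count(
    background: Sequence[RateEstimate],
    observed_person_time: Mapping[Stratum, float],
) -> float | None:
    """Expected events: sum over strata of background rate x observed person-time.

    Returns ``None`` (non-estimable) when a stratum with positive observed
    person-time has no estimable background rate, or when nothing is exposed.
    """
    bg = {r.stratum: r for r in background}
    total = 0.0
    any_pt = False
    for stratum, pt in observed_person_time.items():
        if pt <= 0:
            continue
        any_pt = True
        r = bg.get(stratum)
        if r is None or not r.estimable:
            return None
        total += r.rate * pt
    return total if any_pt else None
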