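"""Synthetic OMOP-lite event table generation.

Generates the five event tables consumed by the rest of the package —
persons, observation periods, outpatient visits, vaccination exposures and
outcome occurrences — with the statistical structure the observed-vs-expected
analysis assumes, plus switchable bias mechanisms:

* age-dependent vaccination propensity (confounding by indication),
* a multiplicative outcome-rate factor among vaccinees (healthy-vaccinee
  style shift),
* boosted outcome recording in the days following a healthcare visit
  (visit-proximity capture).

Calendar convention: days are integers with the scenario's ``study_origin``
at day 0; all intervals are half-open ``[start, end)``; "months" are fixed
30-day blocks.  Vaccination contact is recorded as a visit on the exposure
day, which is what lets visit-proximity capture bias post-vaccination rates.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25
DAYS_PER_MONTH = 30
N_AGE_BANDS = 10  # [0,10), ..., [80,90), [90, inf)

# fixed per-stage offsets for deriving independent RNG streams from one seed
_STREAM_POPULATION = 0
_STREAM_VISITS = 1
_STREAM_UPTAKE = 2
_STREAM_OUTCOMES = 3
STREAM_ANCHOR = 4
STREAM_INJECTION = 5


class ConfigError(ValueError):
    """Raised when a scenario configuration violates its invariants."""


def stream_rng(seed: int, stream: int) -> np.random.Generator:
    """Independent generator for one pipeline stage, derived from the master seed."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(stream))))


def age_band(birth_day: np.ndarray, at_day: np.ndarray | int) -> np.ndarray:
    """10-year age band index at a given day; band 9 is open-ended [90, inf)."""
    age_years = (np.asarray(at_day) - np.asarray(birth_day)) / DAYS_PER_YEAR
    return np.clip((age_years // 10).astype(int), 0, N_AGE_BANDS - 1)


@dataclass(frozen=True)
class OutcomeDef:
    """Rate model for one outcome: a base rate with multiplicative structure.

    ``base_rate`` is in events per person-year for a male in age band 0 with
    no seasonal/secular modulation.  ``sex_multiplier`` applies to females.
    ``seasonal_amplitude`` is the relative amplitude of a 12-month sinusoid;
    ``secular_slope`` is the log-linear rate change per year.
    """

    outcome_id: str
    base_rate: float
    age_multipliers: tuple[float, ...] = (1.0,) * N_AGE_BANDS
    sex_multiplier: float = 1.0
    seasonal_amplitude: float = 0.0
    secular_slope: float = 0.0

    def validate(self) -> None:
        if self.base_rate < 0:
            raise ConfigError(f"{self.outcome_id}: base_rate must be >= 0")
        if len(self.age_multipliers) != N_AGE_BANDS:
            raise ConfigError(f"{self.outcome_id}: need {N_AGE_BANDS} age multipliers")
        if any(m <= 0 for m in self.age_multipliers) or self.sex_multiplier <= 0:
            raise ConfigError(f"{self.outcome_id}: multipliers must be > 0")
        if not -1.0 <= self.seasonal_amplitude <= 1.0:
            raise ConfigError(f"{self.outcome_id}: seasonal_amplitude must be in [-1, 1]")


@dataclass(frozen=True)
class BiasKnobs:
    """Bias mechanism switches; the defaults are all neutral (no bias)."""

    age_confounding_strength: float = 0.0
    healthy_vaccinee_shift: float = 1.0
    visit_capture_boost: float = 1.0
    visit_capture_days: int = 30

    def validate(self) -> None:
        if self.healthy_vaccinee_shift <= 0 or self.visit_capture_boost <= 0:
            raise ConfigError("multiplicative bias factors must be > 0")
        if self.visit_capture_days < 0:
            raise ConfigError("visit_capture_days must be >= 0")


@dataclass(frozen=True)
class UptakeCurve:
    """Vaccination campaign shape.

    ``rapid`` concentrates >=80% of doses in surveillance months 1-2
    (H1N1/seasonal-flu style); ``slow`` spreads doses uniformly over months
    1-12 (HPV/zoster style).  ``coverage`` is the fraction of persons
    receiving a (single) dose.
    """

    kind: str = "rapid"
    coverage: float = 0.4

    def validate(self) -> None:
        if self.kind not in ("rapid", "slow"):
            raise ConfigError(f"unknown uptake curve {self.kind!r}")
        if not 0.0 <= self.coverage <= 1.0:
            raise ConfigError("coverage must be in [0, 1]")


def _default_age_distribution() -> tuple[float, ...]:
    # mild adult-skewed population; one weight per 10-year band
    return (0.11, 0.12, 0.14, 0.14, 0.13, 0.13, 0.11, 0.07, 0.04, 0.01)


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of one synthetic scenario."""

    n_persons: int
    seed: int = 0
    study_origin: int = 0
    historical_window: tuple[int, int] = (0, 365)
    surveillance_window: tuple[int, int] = (365, 365 + 12 * DAYS_PER_MONTH)
    female_fraction: float = 0.511
    age_distribution: tuple[float, ...] = field(default_factory=_default_age_distribution)
    visit_rate: float = 3.0
    vaccine_id: str = "vaccine"
    uptake: UptakeCurve = field(default_factory=UptakeCurve)
    outcome_defs: tuple[OutcomeDef, ...] = ()
    bias: BiasKnobs = field(default_factory=BiasKnobs)

    def validate(self) -> None:
        if self.n_persons < 0:
            raise ConfigError("n_persons must be >= 0")
        h0, h1 = self.historical_window
        s0, s1 = self.surveillance_window
        if not (h0 < h1 and s0 < s1):
            raise ConfigError("windows must be non-empty half-open intervals")
        if h1 > s0:
            raise ConfigError("historical window must precede the surveillance window")
        if not 0.0 <= self.female_fraction <= 1.0:
            raise ConfigError("female_fraction must be in [0, 1]")
        if len(self.age_distribution) != N_AGE_BANDS:
            raise ConfigError(f"age_distribution needs {N_AGE_BANDS} weights")
        if any(w < 0 for w in self.age_distribution) or sum(self.age_distribution) <= 0:
            raise ConfigError("age_distribution weights must be >= 0 and sum > 0")
        if self.visit_rate < 0:
            raise ConfigError("visit_rate must be >= 0")
        self.uptake.validate()
        self.bias.validate()
        for od in self.outcome_defs:
            od.validate()

    @property
    def n_months(self) -> int:
        s0, s1 = self.surveillance_window
        return int(np.ceil((s1 - s0) / DAYS_PER_MONTH))

    def month_bounds(self, month: int) -> tuple[int, int]:
        """Half-open day interval of surveillance month ``month`` (1-based)."""
        s0 = self.surveillance_window[0]
        return s0 + (month - 1) * DAYS_PER_MONTH, s0 + month * DAYS_PER_MONTH


_TABLE_COLUMNS: Mapping[str, tuple[str, ...]] = {
    "persons": ("person_id", "sex", "birth_day"),
    "observation_periods": ("person_id", "start_day", "end_day"),
    "visits": ("person_id", "visit_day"),
    "exposures": ("person_id", "vaccine_id", "exposure_day"),
    "outcomes": ("person_id", "outcome_id", "outcome_day"),
}


@dataclass
class EventTables:
    """The OMOP-lite dataset: five event tables keyed by ``person_id``."""

    persons: pd.DataFrame
    observation_periods: pd.DataFrame
    visits: pd.DataFrame
    exposures: pd.DataFrame
    outcomes: pd.DataFrame

    @classmethod
    def empty(cls) -> "EventTables":
        frames = {}
        for name, cols in _TABLE_COLUMNS.items():
            frames[name] = pd.DataFrame({c: pd.Series(dtype=_dtype_for(c)) for c in cols})
        return cls(**frames)

    def copy(self) -> "EventTables":
        return EventTables(**{k: getattr(self, k).copy() for k in _TABLE_COLUMNS})

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name in _TABLE_COLUMNS:
            getattr(self, name).to_csv(out_dir / f"{name}.csv", index=False)

    @classmethod
    def read(cls, in_dir: str | Path) -> "EventTables":
        in_dir = Path(in_dir)
        frames = {}
        for name, cols in _TABLE_COLUMNS.items():
            df = pd.read_csv(in_dir / f"{name}.csv")
            for c in cols:
                df[c] = df[c].astype(_dtype_for(c))
            frames[name] = df[list(cols)]
        return cls(**frames)

    def equals(self, other: "EventTables") -> bool:
        return all(getattr(self, k).equals(getattr(other, k)) for k in _TABLE_COLUMNS)


def _dtype_for(col: str) -> str:
    return "object" if col in ("sex", "vaccine_id", "outcome_id") else "int64"


def write_scenario(tables: EventTables, config: ScenarioConfig, out_dir: str | Path) -> None:
    """Write the five tables plus a JSON sidecar echoing the full config."""
    out_dir = Path(out_dir)
    tables.write(out_dir)
    sidecar = dataclasses.asdict(config)
    (out_dir / "scenario.json").write_text(json.dumps(sidecar, indent=2, default=list))


# ---------------------------------------------------------------------------
# generation stages
# ---------------------------------------------------------------------------

def generate_population(config: ScenarioConfig) -> EventTables:
    """Persons and observation periods only.

    Every person gets one continuous observation period spanning both the
    historical and the surveillance windows (no churn).  Ages at day 0 are
    drawn uniformly within the sampled 10-year band.
    """
    config.validate()
    tables = EventTables.empty()
    n = config.n_persons
    if n == 0:
        return tables

    rng = stream_rng(config.seed, _STREAM_POPULATION)
    sex = np.where(rng.random(n) < config.female_fraction, "F", "M")
    weights = np.asarray(config.age_distribution, dtype=float)
    bands = rng.choice(N_AGE_BANDS, size=n, p=weights / weights.sum())
    age_years = (bands * 10 + 10 * rng.random(n))
    birth_day = (config.study_origin - np.floor(age_years * DAYS_PER_YEAR)).astype(np.int64)

    tables.persons = pd.DataFrame(
        {"person_id": np.arange(n, dtype=np.int64), "sex": sex, "birth_day": birth_day}
    )
    tables.observation_periods = pd.DataFrame(
        {
            "person_id": np.arange(n, dtype=np.int64),
            "start_day": np.full(n, config.historical_window[0], dtype=np.int64),
            "end_day": np.full(n, config.surveillance_window[1], dtype=np.int64),
        }
    )
    return tables


def generate_visits(tables: EventTables, config: ScenarioConfig) -> EventTables:
    """Outpatient visits from a homogeneous per-person Poisson process."""
    tables = tables.copy()
    n = len(tables.persons)
    if n == 0 or config.visit_rate == 0:
        return tables

    rng = stream_rng(config.seed, _STREAM_VISITS)
    obs = tables.observation_periods
    start = obs["start_day"].to_numpy()
    length = obs["end_day"].to_numpy() - start
    counts = rng.poisson(config.visit_rate * length / DAYS_PER_YEAR)
    pid = np.repeat(obs["person_id"].to_numpy(), counts)
    days = np.repeat(start, counts) + np.floor(
        rng.random(counts.sum()) * np.repeat(length, counts)
    ).astype(np.int64)
    tables.visits = _sorted_events(pd.DataFrame({"person_id": pid, "visit_day": days}), "visit_day")
    return tables


def generate_uptake(tables: EventTables, config: ScenarioConfig) -> EventTables:
    """First-dose vaccination exposures following the configured uptake curve.

    Persons are sampled without replacement with probability proportional to
    ``exp(age_confounding_strength * age_band)``.  The vaccination contact is
    also recorded as a visit (it happens at a healthcare encounter), which is
    what exposes post-vaccination time to visit-proximity capture bias.
    """
    tables = tables.copy()
    n = len(tables.persons)
    n_doses = int(round(config.uptake.coverage * n))
    if n == 0 or n_doses == 0:
        return tables

    rng = stream_rng(config.seed, _STREAM_UPTAKE)
    bands = age_band(tables.persons["birth_day"].to_numpy(), config.study_origin)
    # Gumbel top-k = weighted sampling without replacement
    keys = config.bias.age_confounding_strength * bands + rng.gumbel(size=n)
    chosen = np.argsort(keys)[-n_doses:]
    chosen.sort()

    n_months = config.n_months
    month_p = _uptake_month_weights(config.uptake.kind, n_months)
    months = rng.choice(n_months, size=n_doses, p=month_p) + 1
    s0 = config.surveillance_window[0]
    days = (s0 + (months - 1) * DAYS_PER_MONTH
            + np.floor(rng.random(n_doses) * DAYS_PER_MONTH).astype(np.int64))
    # clip inside surveillance window (last month may be short)
    days = np.minimum(days, config.surveillance_window[1] - 1)

    pid = tables.persons["person_id"].to_numpy()[chosen]
    tables.exposures = pd.DataFrame(
        {"person_id": pid, "vaccine_id": config.vaccine_id, "exposure_day": days}
    )
    vacc_visits = pd.DataFrame({"person_id": pid, "visit_day": days})
    tables.visits = _sorted_events(
        pd.concat([tables.visits, vacc_visits], ignore_index=True), "visit_day"
    )
    return tables


def _uptake_month_weights(kind: str, n_months: int) -> np.ndarray:
    if kind == "rapid":
        if n_months == 1:
            return np.array([1.0])
        if n_months == 2:
            return np.array([0.6, 0.4])
        p = np.full(n_months, 0.15 / (n_months - 2))
        p[0], p[1] = 0.55, 0.30
        return p
    # slow: uniform across the first 12 (or fewer) months
    k = min(n_months, 12)
    p = np.zeros(n_months)
    p[:k] = 1.0 / k
    return p


def generate_outcomes(tables: EventTables, config: ScenarioConfig) -> EventTables:
    """Outcome occurrences from per-person-day hazards (recurrent events allowed).

    Hazard per day = base_rate/365.25 x age multiplier x sex multiplier
    x seasonal term (1 + A sin(2 pi day/360)) x secular term exp(slope*day/365.25),
    times ``healthy_vaccinee_shift`` for ever-vaccinated persons and
    ``visit_capture_boost`` within ``visit_capture_days`` after any visit.
    Sampling uses Poisson thinning against a per-person hazard upper bound.
    """
    tables = tables.copy()
    n = len(tables.persons)
    if n == 0 or not config.outcome_defs:
        return tables

    rng = stream_rng(config.seed, _STREAM_OUTCOMES)
    persons = tables.persons
    obs = tables.observation_periods.set_index("person_id")
    pid_all = persons["person_id"].to_numpy()
    birth = persons["birth_day"].to_numpy()
    female = (persons["sex"] == "F").to_numpy()
    obs_start = obs.loc[pid_all, "start_day"].to_numpy()
    obs_end = obs.loc[pid_all, "end_day"].to_numpy()
    length = obs_end - obs_start
    vaccinated = np.isin(pid_all, tables.exposures["person_id"].to_numpy())

    band_lo = age_band(birth, obs_start)
    band_hi = age_band(birth, obs_end - 1)

    # visit lookup: encoded keys for "latest visit at or before day"
    day_min = int(obs_start.min())
    span = int(obs_end.max()) - day_min + 2
    vdays = tables.visits["visit_day"].to_numpy()
    vkeys = np.sort(tables.visits["person_id"].to_numpy() * span + (vdays - day_min))

    knobs = config.bias
    hv = np.where(vaccinated, knobs.healthy_vaccinee_shift, 1.0)

    frames = [tables.outcomes]
    for od in config.outcome_defs:
        if od.base_rate == 0:
            continue
        mult = np.asarray(od.age_multipliers)
        band_max = np.zeros(n)
        for b in range(N_AGE_BANDS):
            in_range = (band_lo <= b) & (b <= band_hi)
            band_max = np.where(in_range, np.maximum(band_max, mult[b]), band_max)
        sex_m = np.where(female, od.sex_multiplier, 1.0)
        secular_max = max(
            np.exp(od.secular_slope * obs_start.min() / DAYS_PER_YEAR),
            np.exp(od.secular_slope * obs_end.max() / DAYS_PER_YEAR),
        )
        lam_max = (od.base_rate / DAYS_PER_YEAR * band_max * sex_m * hv
                   * (1 + abs(od.seasonal_amplitude)) * secular_max
                   * max(knobs.visit_capture_boost, 1.0))

        counts = rng.poisson(lam_max * length)
        m = int(counts.sum())
        if m == 0:
            continue
        idx = np.repeat(np.arange(n), counts)
        day = (np.repeat(obs_start, counts)
               + np.floor(rng.random(m) * np.repeat(length, counts))).astype(np.int64)

        lam = (od.base_rate / DAYS_PER_YEAR
               * mult[age_band(birth[idx], day)]
               * np.where(female[idx], od.sex_multiplier, 1.0)
               * hv[idx]
               * (1 + od.seasonal_amplitude * np.sin(2 * np.pi * day / (12 * DAYS_PER_MONTH)))
               * np.exp(od.secular_slope * day / DAYS_PER_YEAR))
        if knobs.visit_capture_boost != 1.0 and len(vkeys):
            boosted = _after_visit(pid_all[idx], day, vkeys, span, day_min,
                                   knobs.visit_capture_days)
            lam = lam * np.where(boosted, knobs.visit_capture_boost, 1.0)

        accept = rng.random(m) * lam_max[idx] < lam
        if accept.any():
            frames.append(pd.DataFrame({
                "person_id": pid_all[idx][accept],
                "outcome_id": od.outcome_id,
                "outcome_day": day[accept],
            }))

    tables.outcomes = _sorted_events(
        pd.concat(frames, ignore_index=True), "outcome_day", extra_key="outcome_id"
    )
    return tables


def _after_visit(pid: np.ndarray, day: np.ndarray, vkeys: np.ndarray, span: int,
                 day_min: int, d: int) -> np.ndarray:
    """True where ``day`` falls in (v, v+d] for some visit v of the same person."""
    ckey = pid * span + (day - day_min)
    pos = np.searchsorted(vkeys, ckey, side="left") - 1  # latest visit strictly before day
    pos = np.clip(pos, 0, None)
    vpid = vkeys[pos] // span
    vday = vkeys[pos] % span + day_min
    return (len(vkeys) > 0) & (vpid == pid) & (day - vday >= 1) & (day - vday <= d)


def _sorted_events(df: pd.DataFrame, day_col: str, extra_key: str | None = None) -> pd.DataFrame:
    keys = ["person_id", day_col] + ([extra_key] if extra_key else [])
    return df.sort_values(keys, kind="mergesort", ignore_index=True)


def simulate_scenario(config: ScenarioConfig) -> EventTables:
    """Run all four generation stages; deterministic for a fixed (config, seed)."""
    tables = generate_population(config)
    tables = generate_visits(tables, config)
    tables = generate_uptake(tables, config)
    tables = generate_outcomes(tables, config)
    return tables


def make_negative_controls(
    n: int,
    base_rate: float = 0.05,
    rate_spread: float = 2.0,
    prefix: str = "neg",
    **kwargs,
) -> tuple[OutcomeDef, ...]:
    """Convenience constructor for ``n`` negative-control outcome definitions.

    Base rates are log-spaced in ``[base_rate / rate_spread, base_rate * rate_spread]``
    so the control set is not artificially homogeneous.  Extra keyword
    arguments are forwarded to every :class:`OutcomeDef`.
    """
    if n <= 0:
        return ()
    rates = np.exp(np.linspace(np.log(base_rate / rate_spread),
                               np.log(base_rate * rate_spread), n))
    return tuple(
        OutcomeDef(outcome_id=f"{prefix}{i:03d}", base_rate=float(r), **kwargs)
        for i, r in enumerate(rates)
    )
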