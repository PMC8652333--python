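"""Control-set construction: negative controls plus injected positive controls.

Positive controls are synthesized from negative-control outcomes by injecting
additional simulated occurrences during the post-vaccination time-at-risk
window (days 1-28 by default), at a constant hazard ratio, so that the
marginal incidence rate ratio among exposed time-at-risk equals a known
target (1.5, 2 and 4 by default).  No positives are synthesized from a
negative control with fewer than ``min_outcomes`` (default 25) first-events
in exposed time-at-risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .incidence import TimeAtRiskWindow
from .synthetic import STREAM_INJECTION, EventTables, stream_rng

DEFAULT_IRRS: tuple[float, ...] = (1.5, 2.0, 4.0)


@dataclass(frozen=True)
class ControlDefinition:
    control_id: str
    parent_outcome_id: str  # self for negative controls
    true_irr: float
    synthesized: bool
    injected_count: int = 0

    def __post_init__(self) -> None:
        if self.synthesized != (self.true_irr != 1.0):
            raise ValueError("true_irr == 1.0 iff not synthesized")

    @property
    def true_log_irr(self) -> float:
        return float(np.log(self.true_irr))


def positive_control_id(parent_id: str, irr: float) -> str:
    return f"{parent_id}+irr{irr:g}"


def exposed_tar_frame(
    tables: EventTables, vaccine_id: str, window: TimeAtRiskWindow
) -> pd.DataFrame:
    """Per vaccinated person: clipped half-open TAR [tar_start, tar_end).

    Columns: person_id, tar_start, tar_end.  First dose only; TAR clipped to
    the person's observation period.
    """
    ex = tables.exposures
    ex = ex[ex["vaccine_id"] == vaccine_id]
    ex = ex.sort_values("exposure_day", kind="mergesort").drop_duplicates("person_id")
    obs = tables.observation_periods.drop_duplicates("person_id").set_index("person_id")
    pid = ex["person_id"].to_numpy()
    tar_start, tar_end = window.bounds(ex["exposure_day"].to_numpy())
    tar_start = np.maximum(tar_start, obs.loc[pid, "start_day"].to_numpy())
    tar_end = np.minimum(tar_end, obs.loc[pid, "end_day"].to_numpy())
    out = pd.DataFrame({"person_id": pid, "tar_start": tar_start, "tar_end": tar_end})
    return out[out["tar_end"] > out["tar_start"]].reset_index(drop=True)


def _first_events_in_tar(
    tables: EventTables, outcome_id: str, tar: pd.DataFrame, rows: pd.DataFrame | None = None
) -> int:
    oc = rows if rows is not None else tables.outcomes[tables.outcomes["outcome_id"] == outcome_id]
    if oc.empty or tar.empty:
        return 0
    pos = pd.Index(tar["person_id"]).get_indexer(oc["person_id"])
    valid = pos >= 0
    day = oc["outcome_day"].to_numpy()[valid]
    pos = pos[valid]
    inside = (day >= tar["tar_start"].to_numpy()[pos]) & (day < tar["tar_end"].to_numpy()[pos])
    return int(pd.unique(pos[inside]).size)


def synthesize_positive_controls(
    tables: EventTables,
    vaccine_id: str,
    negative_ids: list[str],
    window: TimeAtRiskWindow = TimeAtRiskWindow(),
    irrs: tuple[float, ...] = DEFAULT_IRRS,
    min_outcomes: int = 25,
    seed: int = 0,
) -> tuple[EventTables, list[ControlDefinition]]:
    """Inject positive-control outcomes at each target IRR.

    For each eligible parent (>= ``min_outcomes`` first-events among exposed
    TARs) and each target IRR ``r``, a new outcome id is created holding a
    copy of every parent occurrence plus extra events drawn per exposed
    person from a homogeneous process at rate ``(r - 1) * lambda_hat``, where
    ``lambda_hat`` is the parent's marginal first-event rate over exposed TAR
    person-time.  Original rows are never modified or removed.

    Returns the augmented tables and the full control manifest (negatives
    first, then positives).
    """
    if min_outcomes <= 0:
        raise ValueError("min_outcomes must be > 0")
    if any(r <= 1 for r in irrs):
        raise ValueError("target IRRs must all be > 1")
    present = set(tables.outcomes["outcome_id"].unique())
    missing = [o for o in negative_ids if o not in present]
    if missing:
        raise ValueError(f"negative controls absent from outcome table: {missing}")

    tables = tables.copy()
    tar = exposed_tar_frame(tables, vaccine_id, window)
    tar_len = (tar["tar_end"] - tar["tar_start"]).to_numpy()
    total_days = float(tar_len.sum())

    rng = stream_rng(seed, STREAM_INJECTION)
    controls: list[ControlDefinition] = [
        ControlDefinition(o, o, 1.0, synthesized=False) for o in negative_ids
    ]
    grouped = {oid: grp for oid, grp in tables.outcomes.groupby("outcome_id", sort=False)}
    empty_rows = tables.outcomes.iloc[0:0]
    new_frames = []
    for parent in negative_ids:
        parent_rows = grouped.get(parent, empty_rows)
        n_events = _first_events_in_tar(tables, parent, tar, rows=parent_rows)
        if n_events < min_outcomes or total_days == 0:
            continue
        lam_hat = n_events / total_days  # per exposed TAR day
        for r in irrs:
            cid = positive_control_id(parent, r)
            counts = rng.poisson((r - 1.0) * lam_hat * tar_len)
            m = int(counts.sum())
            pid = np.repeat(tar["person_id"].to_numpy(), counts)
            days = (np.repeat(tar["tar_start"].to_numpy(), counts)
                    + np.floor(rng.random(m) * np.repeat(tar_len, counts))).astype(np.int64)
            copied = parent_rows.assign(outcome_id=cid)
            injected = pd.DataFrame(
                {"person_id": pid, "outcome_id": cid, "outcome_day": days}
            )
            new_frames.append(copied)
            new_frames.append(injected)
            controls.append(
                ControlDefinition(cid, parent, float(r), synthesized=True, injected_count=m)
            )

    if new_frames:
        tables.outcomes = pd.concat(
            [tables.outcomes, *new_frames], ignore_index=True
        ).sort_values(
            ["person_id", "outcome_day", "outcome_id"], kind="mergesort", ignore_index=True
        )
    return tables, controls


def realized_irr(
    tables_with_injection: EventTables,
    control: ControlDefinition,
    vaccine_id: str,
    window: TimeAtRiskWindow = TimeAtRiskWindow(),
) -> float | None:
    """Post-injection over pre-injection first-event rate in exposed TAR.

    Both numerator (the synthesized control) and denominator (its parent,
    untouched by injection) use first-event-per-person counting over the same
    exposed person-time, so the ratio estimates the control's marginal IRR.
    ``None`` when the parent has no events (non-estimable).
    """
    tar = exposed_tar_frame(tables_with_injection, vaccine_id, window)
    n_parent = _first_events_in_tar(tables_with_injection, control.parent_outcome_id, tar)
    if n_parent == 0:
        return None
    n_control = _first_events_in_tar(tables_with_injection, control.control_id, tar)
    return n_control / n_parent


def controls_frame(controls: list[ControlDefinition]) -> pd.DataFrame:
    """Control manifest as a table (for the file handoff)."""
    return pd.DataFrame(
        [
            {
                "control_id": c.control_id,
                "parent_outcome_id": c.parent_outcome_id,
                "true_irr": c.true_irr,
                "synthesized": c.synthesized,
                "injected_count": c.injected_count,
            }
            for c in controls
        ]
    )


def controls_from_frame(df: pd.DataFrame) -> list[ControlDefinition]:
    return [
        ControlDefinition(
            str(r.control_id),
            str(r.parent_outcome_id),
            float(r.true_irr),
            bool(r.synthesized),
            int(r.injected_count),
        )
        for r in df.itertuples()
    ]
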