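"""Performance metrics over control estimates.

All metrics follow the safety-surveillance convention: a signal is a
one-sided p-value below ``alpha`` (default 0.05).  Type 1 error is the
signalling fraction among negative controls; type 2 error is the missed
fraction (p >= alpha) among positive controls, overall and per true IRR.
Discrimination is the rank-based (Mann-Whitney) AUC of the log-IRR score,
coverage the fraction of controls whose true IRR lies inside the 95% CI,
precision the geometric mean of 1/se^2, and MSE the mean squared error of
the log IRR around the log of the true effect.

Estimability filtering drops cells with no exposed person-time or expected
count and negative controls whose monthly population rate varies by more
than 50% (max/min > 1.5) over the surveillance period, together with the
positives derived from them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .controls import ControlDefinition
from .estimation import EffectEstimate
from .synthetic import DAYS_PER_MONTH, DAYS_PER_YEAR, EventTables

ALPHA = 0.05


def type1_error(p_values: Iterable[float], alpha: float = ALPHA) -> float:
    """Fraction of negative-control p-values below ``alpha``."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no estimable negative controls")
    return float(np.mean(p < alpha))


def type2_error(
    p_values: Iterable[float],
    true_irrs: Iterable[float] | None = None,
    by_irr: bool = False,
    alpha: float = ALPHA,
) -> float | dict[float, float]:
    """Fraction of positive controls missed (p >= alpha), optionally per true IRR."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("no estimable positive controls")
    missed = p >= alpha
    if not by_irr:
        return float(np.mean(missed))
    irr = np.asarray(list(true_irrs), dtype=float)
    if irr.shape != p.shape:
        raise ValueError("true_irrs must align with p_values")
    return {float(r): float(np.mean(missed[irr == r])) for r in np.unique(irr)}


def auc_controls(neg_scores: Iterable[float], pos_scores: Iterable[float]) -> float:
    """Rank-based AUC for positives vs negatives; ties count one half."""
    neg = np.asarray(list(neg_scores), dtype=float)
    pos = np.asarray(list(pos_scores), dtype=float)
    if neg.size == 0 or pos.size == 0:
        raise ValueError("need at least one score in each class")
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    rank_sum = ranks[: pos.size].sum()
    return float((rank_sum - pos.size * (pos.size + 1) / 2) / (pos.size * neg.size))


def coverage(
    ci_lows: Iterable[float], ci_highs: Iterable[float], true_irrs: Iterable[float]
) -> float:
    """Fraction of controls whose true IRR lies within the 95% CI."""
    lo = np.asarray(list(ci_lows), dtype=float)
    hi = np.asarray(list(ci_highs), dtype=float)
    tr = np.asarray(list(true_irrs), dtype=float)
    if lo.size == 0:
        raise ValueError("no estimable estimates")
    return float(np.mean((lo <= tr) & (tr <= hi)))


def precision_and_mse(
    log_irrs: Iterable[float], ses: Iterable[float], true_irrs: Iterable[float]
) -> tuple[float, float]:
    """(geometric mean of 1/se^2, mean squared log-scale error)."""
    log_irr = np.asarray(list(log_irrs), dtype=float)
    se = np.asarray(list(ses), dtype=float)
    tr = np.asarray(list(true_irrs), dtype=float)
    if log_irr.size == 0:
        raise ValueError("no estimable estimates")
    mean_precision = float(np.exp(np.mean(np.log(1.0 / se**2))))
    mse = float(np.mean((log_irr - np.log(tr)) ** 2))
    return mean_precision, mse


# ---------------------------------------------------------------------------
# estimability
# ---------------------------------------------------------------------------

def population_rate_series(
    tables: EventTables,
    outcome_ids: Sequence[str],
    period_start: int,
    n_months: int,
) -> pd.DataFrame:
    """Monthly population incidence per outcome over ``n_months`` 30-day blocks.

    Rate is all occurrences in the month divided by total observed
    person-years in the month (whole population, not just vaccinees).
    Columns: outcome_id, month, rate.
    """
    obs = tables.observation_periods
    rows = []
    for m in range(1, n_months + 1):
        b0 = period_start + (m - 1) * DAYS_PER_MONTH
        b1 = period_start + m * DAYS_PER_MONTH
        overlap = (
            np.minimum(obs["end_day"].to_numpy(), b1)
            - np.maximum(obs["start_day"].to_numpy(), b0)
        ).clip(min=0)
        pt_years = overlap.sum() / DAYS_PER_YEAR
        oc = tables.outcomes
        in_month = oc[(oc["outcome_day"] >= b0) & (oc["outcome_day"] < b1)]
        counts = in_month.groupby("outcome_id").size()
        for o in outcome_ids:
            n = int(counts.get(o, 0))
            rows.append({"outcome_id": o, "month": m,
                         "rate": n / pt_years if pt_years > 0 else np.nan})
    return pd.DataFrame(rows)


def rate_change_exclusions(
    monthly_rates: pd.DataFrame,
    threshold: float = 1.5,
    rule: str = "maxmin",
) -> set[str]:
    """Outcomes whose monthly population rate changes by more than 50%.

    ``maxmin`` (default): excluded when max/min over months with nonzero rate
    exceeds ``threshold``.  ``first_last``: excluded when the later of
    first/last nonzero rates exceeds the other by more than ``threshold``-fold.
    """
    if rule not in ("maxmin", "first_last"):
        raise ValueError(f"unknown rule {rule!r}")
    excluded: set[str] = set()
    for outcome_id, grp in monthly_rates.groupby("outcome_id"):
        r = grp.sort_values("month")["rate"].to_numpy()
        r = r[np.isfinite(r) & (r > 0)]
        if r.size < 2:
            continue
        ratio = r.max() / r.min() if rule == "maxmin" else max(r[-1] / r[0], r[0] / r[-1])
        if ratio > threshold:
            excluded.add(str(outcome_id))
    return excluded


@dataclass(frozen=True)
class Exclusion:
    control_id: str
    reason: str


def estimability_filter(
    estimates: Sequence[EffectEstimate],
    controls: Sequence[ControlDefinition],
    monthly_rates: pd.DataFrame | None = None,
    threshold: float = 1.5,
    rule: str = "maxmin",
) -> tuple[list[EffectEstimate], list[Exclusion]]:
    """Drop non-estimable cells and rate-unstable negative controls.

    Returns the retained estimates plus an exclusion log.  The >50%-change
    rule is evaluated on negative controls' monthly population rates; an
    excluded negative takes its derived positives with it (their injected
    events sit on top of the same unstable process).
    """
    unstable: set[str] = set()
    if monthly_rates is not None:
        negatives = {c.control_id for c in controls if not c.synthesized}
        unstable = rate_change_exclusions(
            monthly_rates[monthly_rates["outcome_id"].isin(negatives)], threshold, rule
        )
    by_id = {c.control_id: c for c in controls}

    kept: list[EffectEstimate] = []
    exclusions: list[Exclusion] = []
    for e in estimates:
        ctrl = by_id.get(e.control_id)
        parent = ctrl.parent_outcome_id if ctrl is not None else e.control_id
        if parent in unstable:
            exclusions.append(Exclusion(e.control_id, "rate_change_gt_50pct"))
        elif not e.estimable:
            reason = "no_exposure" if e.expected is None else "no_observed_events"
            exclusions.append(Exclusion(e.control_id, reason))
        else:
            kept.append(e)
    return kept, exclusions


# ---------------------------------------------------------------------------
# metric assembly and timeliness
# ---------------------------------------------------------------------------

def _pvals(estimates: Sequence[EffectEstimate], calibrated: bool) -> list[float]:
    return [e.cal_p if calibrated else e.p for e in estimates]


def metrics_row(
    estimates: Sequence[EffectEstimate],
    controls: Sequence[ControlDefinition],
    calibrated: bool,
    n_excluded: int = 0,
    alpha: float = ALPHA,
) -> dict:
    """All performance metrics for one (design, calibration flag, month) cell.

    Metrics whose control class is empty (or, for calibrated metrics, whose
    estimates lack calibrated fields) are reported as NaN.
    """
    by_id = {c.control_id: c for c in controls}
    usable = [
        e for e in estimates
        if e.estimable and e.control_id in by_id and (not calibrated or e.calibrated)
    ]
    neg = [e for e in usable if not by_id[e.control_id].synthesized]
    pos = [e for e in usable if by_id[e.control_id].synthesized]
    truths = [by_id[e.control_id].true_irr for e in usable]

    row: dict = {
        "calibrated": calibrated,
        "n_negatives_estimable": len(neg),
        "n_positives_estimable": len(pos),
        "fraction_not_estimable": (
            n_excluded / (len(usable) + n_excluded) if (usable or n_excluded) else np.nan
        ),
    }
    row["type1"] = type1_error(_pvals(neg, calibrated), alpha) if neg else np.nan
    if pos:
        row["type2"] = type2_error(_pvals(pos, calibrated), alpha=alpha)
        per_irr = type2_error(
            _pvals(pos, calibrated),
            [by_id[e.control_id].true_irr for e in pos],
            by_irr=True,
            alpha=alpha,
        )
        for irr, v in per_irr.items():
            row[f"type2_irr_{irr:g}"] = v
    else:
        row["type2"] = np.nan
    if neg and pos:
        score = "cal_log_irr" if calibrated else "log_irr"
        row["auc"] = auc_controls(
            [getattr(e, score) for e in neg], [getattr(e, score) for e in pos]
        )
    else:
        row["auc"] = np.nan
    if usable:
        lo = [e.cal_ci_low if calibrated else e.ci_low for e in usable]
        hi = [e.cal_ci_high if calibrated else e.ci_high for e in usable]
        row["coverage"] = coverage(lo, hi, truths)
        li = [e.cal_log_irr if calibrated else e.log_irr for e in usable]
        se = [e.cal_se if calibrated else e.se_log_irr for e in usable]
        row["mean_precision"], row["mse"] = precision_and_mse(li, se, truths)
    else:
        row["coverage"] = row["mean_precision"] = row["mse"] = np.nan
    return row


def first_detection(
    estimates: Sequence[EffectEstimate],
    calibrated: bool = False,
    alpha: float = ALPHA,
) -> dict[str, int | None]:
    """Earliest accrual month with a signal (p < alpha), per control.

    ``estimates`` may span months; controls never signalling map to None.
    """
    result: dict[str, int | None] = {}
    for e in sorted(estimates, key=lambda e: e.month):
        result.setdefault(e.control_id, None)
        p = e.cal_p if calibrated else e.p
        if p is not None and p < alpha and result[e.control_id] is None:
            result[e.control_id] = e.month
    return result


def timeliness_table(
    metrics_by_month: pd.DataFrame,
    estimates: Sequence[EffectEstimate],
    controls: Sequence[ControlDefinition],
    calibrated: bool = False,
    alpha: float = ALPHA,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-month metric series plus first-detection month per positive control."""
    by_id = {c.control_id: c for c in controls}
    pos_est = [e for e in estimates if by_id.get(e.control_id) and by_id[e.control_id].synthesized]
    det = first_detection(pos_est, calibrated=calibrated, alpha=alpha)
    det_df = pd.DataFrame(
        [
            {
                "control_id": cid,
                "true_irr": by_id[cid].true_irr,
                "first_detection_month": month,
            }
            for cid, month in det.items()
        ]
    )
    return metrics_by_month.sort_values("month").reset_index(drop=True), det_df
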