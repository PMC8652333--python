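"""Empirical calibration of effect estimates against control outcomes.

The systematic error on the log-IRR scale is modelled as a Gaussian with
mean ``mu`` and standard deviation ``sigma``, constant across true effect
sizes.  Each control contributes a bias observation
``log_irr - true_log_irr`` whose likelihood is the Gaussian bias convolved
with that estimate's own Gaussian sampling error:

    bias_i ~ N(mu, sigma^2 + se_i^2)

(mu, sigma) are fitted by maximum likelihood; calibrated estimates subtract
``mu``, widen the standard error to ``sqrt(se^2 + sigma^2)``, and recompute
the CI and the one-sided p-value from normal theory.  Leave-one-out
calibration refits the model without the control being calibrated (and, by
default, without positives sharing its parent negative control).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .controls import ControlDefinition
from .estimation import Z95, EffectEstimate

_LOG_SIGMA_BOUNDS = (-10.0, 5.0)


@dataclass(frozen=True)
class SystematicErrorModel:
    mu: float
    sigma: float
    fitted_on: tuple[str, ...] = ()
    converged: bool = False


def fit_systematic_error(
    estimates: Sequence[tuple[float, float, float]],
    ids: Sequence[str] | None = None,
) -> SystematicErrorModel:
    """ML fit of (mu, sigma) from ``(log_irr, se, true_log_irr)`` triples.

    Optimizes over (mu, log sigma) with a bounded quasi-Newton method and
    multiple starts; fewer than two usable triples yields a non-converged
    model that callers must not calibrate with.
    """
    ids = tuple(ids) if ids is not None else ()
    clean = [(b, s) for (b, s, t) in ((e[0] - e[2], e[1], 0.0) for e in estimates)
             if math.isfinite(b) and math.isfinite(s) and s > 0]
    if len(clean) < 2:
        return SystematicErrorModel(math.nan, math.nan, ids, converged=False)

    bias = np.array([b for b, _ in clean])
    se2 = np.array([s * s for _, s in clean])

    def nll(theta: np.ndarray) -> float:
        mu, log_sigma = theta
        var = np.exp(2.0 * log_sigma) + se2
        return float(0.5 * np.sum(np.log(2.0 * np.pi * var) + (bias - mu) ** 2 / var))

    med = float(np.median(bias))
    mad = float(np.median(np.abs(bias - med)))
    starts = [
        (0.0, -2.0),
        (0.0, 0.0),
        (med, math.log(mad) if mad > 0 else -2.0),
    ]
    results = [
        optimize.minimize(
            nll,
            np.array(x0),
            method="L-BFGS-B",
            bounds=[(None, None), _LOG_SIGMA_BOUNDS],
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        for x0 in starts
    ]
    # an unsuccessful start can stop at the optimum with an abnormal line-search
    # status (sigma pinned at its lower bound); prefer the best successful run
    ok = [r for r in results if r.success]
    best = min(ok or results, key=lambda r: r.fun)
    mu, log_sigma = best.x
    return SystematicErrorModel(float(mu), float(np.exp(log_sigma)), ids, bool(ok))


def calibrate_estimate(
    est: EffectEstimate, model: SystematicErrorModel
) -> EffectEstimate:
    """Shift by ``mu``, widen by ``sigma``, recompute CI and one-sided p.

    Non-converged models and non-estimable estimates pass through with
    calibrated fields absent.
    """
    if not model.converged or not est.estimable:
        return est
    cal_log_irr = est.log_irr - model.mu
    cal_se = math.sqrt(est.se_log_irr**2 + model.sigma**2)
    cal_p = float(stats.norm.sf(cal_log_irr / cal_se))
    return replace(
        est,
        cal_log_irr=cal_log_irr,
        cal_se=cal_se,
        cal_ci_low=math.exp(cal_log_irr - Z95 * cal_se),
        cal_ci_high=math.exp(cal_log_irr + Z95 * cal_se),
        cal_p=cal_p,
    )


def leave_one_out_calibrate(
    estimates: Sequence[EffectEstimate],
    controls: Sequence[ControlDefinition],
    loo_family: bool = True,
) -> list[EffectEstimate]:
    """Calibrate every estimable estimate with a model fit on the others.

    ``estimates`` must all belong to one (design, month) cell and align with
    ``controls`` via ``control_id``.  With ``loo_family`` (default) the
    held-out set also excludes positives derived from the same parent
    negative control, so a control never influences its own calibration
    through near-duplicate events.
    """
    if len(controls) < 3:
        raise ValueError("leave-one-out calibration needs >= 3 controls")
    by_id = {c.control_id: c for c in controls}
    triples: dict[str, tuple[float, float, float]] = {}
    for e in estimates:
        if e.estimable and e.control_id in by_id:
            triples[e.control_id] = (e.log_irr, e.se_log_irr, by_id[e.control_id].true_log_irr)

    out: list[EffectEstimate] = []
    for e in estimates:
        if not e.estimable or e.control_id not in by_id:
            out.append(e)
            continue
        held = by_id[e.control_id]
        excluded = {held.control_id}
        if loo_family:
            excluded |= {
                c.control_id for c in controls
                if c.parent_outcome_id == held.parent_outcome_id
            }
        kept = [(cid, tr) for cid, tr in triples.items() if cid not in excluded]
        model = fit_systematic_error([tr for _, tr in kept], ids=[cid for cid, _ in kept])
        out.append(calibrate_estimate(e, model))
    return out
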