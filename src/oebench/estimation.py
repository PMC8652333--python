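"""Effect estimation for one (control, design, accrual month) cell.

The effect measure is the observed-over-expected incidence rate ratio
IRR = O / E, with

* ``se(log IRR) = sqrt(1/O + 1/n_hist)`` (Poisson counts on both sides),
* a Wald 95% CI on the log scale,
* an exact one-sided Poisson tail p-value P(X >= O), X ~ Poisson(E),
  treating E as fixed, and
* the one-sided Poisson MaxSPRT log likelihood ratio
  ``O ln(O/E) - (O - E)`` for O > E, else 0.

Cells with O = 0, E = 0 or no historical events are flagged non-estimable
rather than raising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy import stats

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class EffectEstimate:
    control_id: str = ""
    design: str = ""
    month: int = 0
    observed: int = 0
    expected: float | None = None
    n_historical: int = 0
    log_irr: float | None = None
    se_log_irr: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p: float | None = None
    llr: float | None = None
    estimable: bool = False
    # empirical-calibration outputs (absent until calibrated)
    cal_log_irr: float | None = None
    cal_se: float | None = None
    cal_ci_low: float | None = None
    cal_ci_high: float | None = None
    cal_p: float | None = None

    @property
    def irr(self) -> float | None:
        return math.exp(self.log_irr) if self.log_irr is not None else None

    @property
    def calibrated(self) -> bool:
        return self.cal_p is not None

    def with_ids(self, control_id: str, design: str, month: int) -> "EffectEstimate":
        return replace(self, control_id=control_id, design=design, month=month)


def poisson_tail_p(observed: int, expected: float) -> float:
    """Exact one-sided elevated-risk tail: P(X >= O) for X ~ Poisson(E)."""
    if expected <= 0:
        raise ValueError("expected must be > 0")
    if observed <= 0:
        return 1.0
    return float(stats.poisson.sf(observed - 1, expected))


def poisson_llr(observed: int, expected: float) -> float:
    """One-sided Poisson MaxSPRT log likelihood ratio; 0 unless O > E."""
    if expected <= 0:
        raise ValueError("expected must be > 0")
    if observed <= expected:
        return 0.0
    return observed * math.log(observed / expected) - (observed - expected)


def estimate_effect(
    observed: int,
    expected: float | None,
    n_historical: int,
) -> EffectEstimate:
    """Core effect statistics for one cell; non-estimable cells carry counts only."""
    base = EffectEstimate(
        observed=int(observed),
        expected=expected,
        n_historical=int(n_historical),
        estimable=False,
    )
    if expected is None or expected <= 0 or observed <= 0 or n_historical < 1:
        return base

    log_irr = math.log(observed / expected)
    se = math.sqrt(1.0 / observed + 1.0 / n_historical)
    return replace(
        base,
        log_irr=log_irr,
        se_log_irr=se,
        ci_low=math.exp(log_irr - Z95 * se),
        ci_high=math.exp(log_irr + Z95 * se),
        p=poisson_tail_p(observed, expected),
        llr=poisson_llr(observed, expected),
        estimable=True,
    )
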