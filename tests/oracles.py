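"""Independent brute-force oracles used to freeze expected values.

Deliberately naive implementations (direct summation, pairwise loops, grid
search, quadrature) kept separate from the package code paths they check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate
from scipy import stats as _stats


def poisson_tail_brute(observed: int, expected: float, tol: float = 1e-16) -> float:
    """P(X >= O) for X ~ Poisson(E) by direct pmf summation."""
    if observed <= 0:
        return 1.0
    # sum downward from O until terms vanish is wrong (tail is infinite);
    # sum upward from O until the term is negligible relative to the total
    term = math.exp(-expected + observed * math.log(expected) - math.lgamma(observed + 1))
    total = term
    k = observed
    while term > tol * max(total, 1e-300):
        k += 1
        term *= expected / k
        total += term
    return min(total, 1.0)


def auc_pairwise(neg_scores, pos_scores) -> float:
    """AUC by exhaustive pairwise concordance counting; ties score 1/2."""
    wins = 0.0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))


def grid_mle(triples, mu_range=(-1.0, 1.0), sigma_range=(1e-4, 1.0), step=5e-4):
    """(mu, sigma) maximizing the convolved-Gaussian likelihood on a dense grid."""
    bias = np.array([b - t for b, _, t in triples])
    se2 = np.array([s * s for _, s, _ in triples])
    mus = np.arange(mu_range[0], mu_range[1] + step, step)
    sigmas = np.arange(sigma_range[0], sigma_range[1] + step, step)
    best = (-np.inf, None, None)
    # chunk over sigma to bound memory
    for sig in sigmas:
        var = sig * sig + se2  # (k,)
        ll = -0.5 * np.sum(
            np.log(2 * np.pi * var)[None, :] + (bias[None, :] - mus[:, None]) ** 2 / var[None, :],
            axis=1,
        )
        i = int(np.argmax(ll))
        if ll[i] > best[0]:
            best = (float(ll[i]), float(mus[i]), float(sig))
    return best[1], best[2]


def calibrated_p_quadrature(log_irr: float, se: float, mu: float, sigma: float) -> float:
    """One-sided calibrated p by integrating the bias distribution numerically.

    p = integral over bias b of N(b; mu, sigma^2) * P(N(b, se^2) >= log_irr).
    """
    def integrand(b):
        return _stats.norm.pdf(b, mu, sigma) * _stats.norm.sf((log_irr - b) / se)

    lo, hi = mu - 12 * max(sigma, 1e-9), mu + 12 * max(sigma, 1e-9)
    val, _ = integrate.quad(integrand, lo, hi, epsabs=1e-12, limit=200)
    return val


def llr_direct(observed: int, expected: float) -> float:
    """One-sided Poisson LLR from its closed form, evaluated independently."""
    if observed <= expected:
        return 0.0
    return observed * math.log(observed / expected) - observed + expected
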