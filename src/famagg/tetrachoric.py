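"""Tetrachoric correlation of a 2x2 table.

The estimator assumes the two binary traits are dichotomisations of a latent
bivariate normal.  Thresholds are fixed at the probits of the observed
margins (two-step maximum likelihood): with empirical margins, the ML
estimate of the latent correlation rho solves

    P(X > tau1, Y > tau2; rho) = n11 / n,

which is found by bracketed root-finding.  The bivariate normal CDF is
evaluated in closed form through Owen's T function, so the estimate is fully
deterministic.  The standard error comes from the observed information
(numerical second derivative of the two-step profile log-likelihood in rho).
"""

from __future__ import annotations

import math
import warnings
from typing import Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.special import owens_t
from scipy.stats import norm

__all__ = ["bvn_cdf", "tetrachoric_mle", "TetrachoricError"]

_RHO_MAX = 1.0 - 1e-8
_CLAMP = 1.0 - 1e-6


class TetrachoricError(ValueError):
    """Degenerate table: a margin has only one level."""


def bvn_cdf(h: float, k: float, rho: float) -> float:
    """Standard bivariate normal P(X <= h, Y <= k) with correlation rho.

    Closed form via Owen's T (Owen 1956); exact limits at rho = +/-1.
    """
    if rho >= _RHO_MAX:
        return norm.cdf(min(h, k))
    if rho <= -_RHO_MAX:
        return max(0.0, norm.cdf(h) - norm.cdf(-k))
    if h == 0.0 and k == 0.0:
        return 0.25 + math.asin(rho) / (2.0 * math.pi)
    denom = math.sqrt(1.0 - rho * rho)

    def t_term(x: float, y: float) -> float:
        # T(x, (y - rho x) / (x sqrt(1-rho^2))), with the x -> 0 limit
        if x == 0.0:
            # T(0, a) = arctan(a)/(2 pi); a -> +/- inf by the sign of y
            return math.copysign(0.25, y)
        return float(owens_t(x, (y - rho * x) / (x * denom)))

    beta = 0.0
    if h * k < 0 or (h * k == 0.0 and (h + k) < 0):
        beta = 0.5
    return (0.5 * (norm.cdf(h) + norm.cdf(k))
            - t_term(h, k) - t_term(k, h) - beta)


def _orthant(tau1: float, tau2: float, rho: float) -> float:
    """P(X > tau1, Y > tau2)."""
    return (1.0 - norm.cdf(tau1) - norm.cdf(tau2)
            + bvn_cdf(tau1, tau2, rho))


def _loglik(rho: float, tau1: float, tau2: float, counts, p1: float, p2: float) -> float:
    n11, n10, n01, n00 = counts
    p11 = _orthant(tau1, tau2, rho)
    cells = (p11, p1 - p11, p2 - p11, 1.0 - p1 - p2 + p11)
    ll = 0.0
    for nc, pc in zip((n11, n10, n01, n00), cells):
        if nc > 0:
            if pc <= 0:
                return -np.inf
            ll += nc * math.log(pc)
    return ll


def tetrachoric_mle(n11: float, n10: float, n01: float, n00: float
                    ) -> Tuple[float, float]:
    """Return (rho_hat, se) for a 2x2 table of nonnegative (possibly
    fractional) counts.

    Perfect association (an empty off-diagonal or diagonal) is clamped to
    +/-(1 - 1e-6) with a warning; a degenerate margin raises
    :class:`TetrachoricError`.
    """
    n = n11 + n10 + n01 + n00
    if n <= 0:
        raise TetrachoricError("empty table")
    p1 = (n11 + n10) / n  # index-affected margin
    p2 = (n11 + n01) / n  # relative-affected margin
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        raise TetrachoricError("degenerate margin: both levels required on each axis")
    tau1 = norm.ppf(1.0 - p1)
    tau2 = norm.ppf(1.0 - p2)
    target = n11 / n

    lo = _orthant(tau1, tau2, -_CLAMP)
    hi = _orthant(tau1, tau2, _CLAMP)
    if target <= lo:
        warnings.warn("perfect negative association; rho clamped")
        rho = -_CLAMP
    elif target >= hi:
        warnings.warn("perfect association; rho clamped")
        rho = _CLAMP
    else:
        rho = float(brentq(lambda r: _orthant(tau1, tau2, r) - target,
                           -_CLAMP, _CLAMP, xtol=1e-12))

    # observed information in rho (numerical second derivative)
    counts = (n11, n10, n01, n00)
    h = 1e-4
    r0 = min(max(rho, -_CLAMP + 2 * h), _CLAMP - 2 * h)
    l_m, l_0, l_p = (_loglik(r0 - h, tau1, tau2, counts, p1, p2),
                     _loglik(r0, tau1, tau2, counts, p1, p2),
                     _loglik(r0 + h, tau1, tau2, counts, p1, p2))
    d2 = (l_p - 2.0 * l_0 + l_m) / (h * h)
    se = float(1.0 / math.sqrt(-d2)) if d2 < 0 else float("nan")
    return rho, se
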