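"""Asymptotic distribution theory behind the extended AIC.

The likelihood-ratio statistic for adding one parameter to a nested model,
``Delta_l = l1 - l0``, is asymptotically Gamma(1/2, 1) distributed (Wilks:
``2*Delta_l ~ chi2_1``). Scanning ``q`` independent such statistics and
rejecting whenever one exceeds a common bound ``x`` keeps the family-wise
error rate (FWER) at ``1 - F(x)**q`` where ``F`` is the Gamma(1/2, 1) CDF.

The critical bound

    x_{q, alpha} = log q - (1/2) log log q - log(-log(1 - alpha))
                   - (1/2) log pi

has the property that ``F(x_{q', alpha})**q -> 1 - alpha`` as ``q -> inf``
for any proxy ``q' ~ q``, i.e. it controls the asymptotic FWER at level
``alpha`` without knowing the exact number of implicit tests. This module
provides that bound, the exact finite-``q`` FWER, and the closed-form
levels at which the resulting information criterion coincides with the
RIC, the mAIC and the BIC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "ALPHA0",
    "CriticalBound",
    "half_chi2_cdf",
    "half_chi2_sf",
    "critical_bound",
    "family_max_cdf",
    "asymptotic_fwer",
    "alpha_ric",
    "alpha_maic",
    "c_eaic",
    "alpha_bic_equiv",
    "bic_fwer_approx",
    "mc_null_bound_check",
]

#: The level at which the critical bound simplifies to log q - (1/2) log log q:
#: the -log(-log(1 - alpha)) term cancels -(1/2) log pi exactly.
ALPHA0: float = 1.0 - math.exp(-1.0 / math.sqrt(math.pi))


@dataclass(frozen=True)
class CriticalBound:
    """A critical value for the max of ``q_proxy`` likelihood-ratio statistics.

    Attributes
    ----------
    q_proxy : int
        Proxy for the number of implicit one-parameter tests; in variable
        selection this is the number of candidate regressors ``p``.
    alpha : float
        Target asymptotic family-wise error rate, in (0, 1).
    x : float
        The bound on ``Delta_l`` (log-likelihood-difference units).
    """

    q_proxy: int
    alpha: float
    x: float


def _check_alpha(alpha: float) -> None:
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha!r}")


def _check_q(q: int) -> None:
    if q < 2:
        raise ValueError(f"q must be at least 2, got {q!r}")
    if q == 2:
        # log log 2 < 0: the bound is defined but outside its natural regime.
        warnings.warn(
            "q=2 gives log(log(q)) < 0; the critical bound is outside its "
            "intended large-q regime",
            stacklevel=3,
        )


def half_chi2_cdf(x: float) -> float:
    """CDF ``F`` of the Gamma(1/2, 1) law of ``Delta_l``: ``P(chi2_1 <= 2x)``.

    Evaluated as ``erf(sqrt(x))``.
    """
    if x < 0:
        raise ValueError(f"x must be nonnegative, got {x!r}")
    return float(special.erf(math.sqrt(x)))


def half_chi2_sf(x: float) -> float:
    """Upper tail ``1 - F(x)``, via ``erfc`` to retain precision for large x."""
    if x < 0:
        raise ValueError(f"x must be nonnegative, got {x!r}")
    return float(special.erfc(math.sqrt(x)))


def critical_bound(q_proxy: int, alpha: float) -> CriticalBound:
    """Critical bound ``x_{q, alpha}`` for ``q_proxy`` implicit tests at level ``alpha``.

    ``x = log q - (1/2) log log q - log(-log(1 - alpha)) - (1/2) log pi``.
    At ``alpha = ALPHA0`` the last two terms cancel and
    ``x = log q - (1/2) log log q``.
    """
    _check_q(q_proxy)
    _check_alpha(alpha)
    lq = math.log(q_proxy)
    x = lq - 0.5 * math.log(lq) - math.log(-math.log1p(-alpha)) - 0.5 * math.log(math.pi)
    return CriticalBound(q_proxy=q_proxy, alpha=alpha, x=x)


def family_max_cdf(x: float, q: int) -> float:
    """CDF of ``max(Delta_l_1, ..., Delta_l_q)`` for independent statistics: ``F(x)**q``.

    Computed in log space as ``exp(q * log1p(-sf))`` so that values remain
    accurate when ``1 - F(x)`` is tiny and ``q`` is large (e.g. q = 1e6).
    """
    if q < 0:
        raise ValueError(f"q must be nonnegative, got {q!r}")
    if q == 0:
        return 1.0
    sf = half_chi2_sf(x)
    if sf >= 1.0:
        return 0.0
    return float(math.exp(q * math.log1p(-sf)))


def asymptotic_fwer(q: int, x: float) -> float:
    """FWER of thresholding ``q`` independent ``Delta_l`` statistics at ``x``:
    ``1 - F(x)**q``.

    For ``x = critical_bound(q, alpha).x`` this converges to ``alpha`` as
    ``q`` grows.
    """
    if q < 0:
        raise ValueError(f"q must be nonnegative, got {q!r}")
    if q == 0:
        return 0.0
    if math.isinf(x):
        return 0.0
    sf = half_chi2_sf(x)
    if sf >= 1.0:
        return 1.0
    return float(-math.expm1(q * math.log1p(-sf)))


def alpha_ric(p: int) -> float:
    """Level at which the extended-AIC weight equals the RIC weight ``2 log p``.

    Solves ``log log p + 2 log(-log(1 - alpha)) + log pi = 0``:
    ``alpha = 1 - exp(-1 / sqrt(pi * log p))``. Strictly decreasing in p.
    """
    if p < 3:
        raise ValueError(f"p must be at least 3, got {p!r}")
    return float(-math.expm1(-1.0 / math.sqrt(math.pi * math.log(p))))


def alpha_maic(p: int, c: float = 0.5) -> float:
    """Level at which the extended AIC coincides with the mAIC of constant ``c``.

    The mAIC weight is ``2 + 2 log(p / c)``; equating it with the extended-AIC
    weight gives ``alpha = 1 - exp(-(c / e) / sqrt(pi * log p))``.
    """
    if p < 3:
        raise ValueError(f"p must be at least 3, got {p!r}")
    if c <= 0:
        raise ValueError(f"c must be positive, got {c!r}")
    return float(-math.expm1(-(c / math.e) / math.sqrt(math.pi * math.log(p))))


def c_eaic(p: int, alpha: float) -> float:
    """mAIC constant whose criterion coincides with the extended AIC at ``alpha``.

    Inverse of :func:`alpha_maic`: ``c = -e * sqrt(pi * log p) * log(1 - alpha)``.
    """
    if p < 3:
        raise ValueError(f"p must be at least 3, got {p!r}")
    _check_alpha(alpha)
    return float(-math.e * math.sqrt(math.pi * math.log(p)) * math.log1p(-alpha))


def alpha_bic_equiv(n: int, p: int) -> float:
    """Level at which the extended-AIC weight equals the BIC weight ``log n``.

    Closed-form inversion of the bound: ``2 * x_{p, alpha} = log n`` gives
    ``log(-log(1 - alpha)) = log p - (1/2) log log p - (1/2) log pi
    - (1/2) log n``. Raises if no solution exists in (0, 1).
    """
    if n < 2:
        raise ValueError(f"n must be at least 2, got {n!r}")
    if p < 3:
        raise ValueError(f"p must be at least 3, got {p!r}")
    lp = math.log(p)
    t = lp - 0.5 * math.log(lp) - 0.5 * math.log(math.pi) - 0.5 * math.log(n)
    alpha = float(-math.expm1(-math.exp(t)))
    if not 0.0 < alpha < 1.0:
        raise ValueError(
            f"no equivalence level in (0, 1) for n={n}, p={p} (log n out of range)"
        )
    return alpha


def bic_fwer_approx(n: int, p: int) -> float:
    """Approximate asymptotic FWER of BIC-based selection under a true sparse model.

    ``1 - exp(-p / sqrt(pi * n * log(n) / 2))``, valid when the compared
    models are much smaller than ``n / log n``. Tends to 1 when p grows
    like ``n**k`` with k > 1, and to 0 when p = O(n).
    """
    if n < 3:
        raise ValueError(f"n must be at least 3, got {n!r}")
    if p < 0:
        raise ValueError(f"p must be nonnegative, got {p!r}")
    if p == 0:
        return 0.0
    return float(-math.expm1(-p / math.sqrt(math.pi * n * math.log(n) / 2.0)))


def mc_null_bound_check(q: int, alpha: float, reps: int, seed: int) -> float:
    """Monte-Carlo estimate of ``P(max_i Delta_l_i > x_{q, alpha})``.

    Samples ``Delta_l_i ~ chi2_1 / 2`` i.i.d. and counts exceedances of the
    critical bound; a simulation oracle for :func:`asymptotic_fwer`.
    """
    if reps < 100:
        raise ValueError(f"reps must be at least 100, got {reps!r}")
    bound = critical_bound(q, alpha)
    rng = np.random.default_rng(seed)
    exceed = 0
    # Chunked so q=1e4 x reps=1e4 stays within memory.
    chunk = max(1, int(2e7) // q)
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        dl = 0.5 * rng.chisquare(df=1.0, size=(m, q))
        exceed += int(np.count_nonzero(dl.max(axis=1) > bound.x))
        done += m
    return exceed / reps
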