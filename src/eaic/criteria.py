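"""Information criteria for sparse model selection.

Every criterion has the form ``IC(A) = -2 l(A) + pen(|A|)`` where ``l(A)``
is the maximal unpenalized log-likelihood of the sub-model with support
``A`` and ``pen`` a penalty on model size. All criteria here except the
EBIC use a linear penalty ``pen(s) = w * s``:

========  ==============================================
AIC       w = 2
BIC       w = log n
RIC       w = 2 log p
mAIC      w = 2 + 2 log(p / c)              (default c = 1/2)
mBIC      w = log n + 2 log(p / E)          (default E = 4)
EAIC      w = 2 x_{p, alpha}                (default alpha = 0.05)
========  ==============================================

The EBIC uses ``pen(s) = log(n) * s + 2 * gamma * log C(p, s)`` (default
gamma = 1). Model size counts candidate regressors only; the intercept
(and, for linear models, the noise variance) is present in every model and
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Mapping

from scipy.special import gammaln

from .wilks import critical_bound

__all__ = ["CRITERION_NAMES", "CriterionSpec", "ScoredModel", "eaic_weight"]

CRITERION_NAMES = ("AIC", "BIC", "RIC", "mAIC", "mBIC", "EBIC", "EAIC")

_DEFAULT_CONSTANTS = {
    "mAIC": {"c": 0.5},
    "mBIC": {"E": 4.0},
    "EBIC": {"gamma": 1.0},
    "EAIC": {"alpha": 0.05},
}


def eaic_weight(p: int, alpha: float) -> float:
    """Extended-AIC penalty weight ``2 x_{p, alpha}`` for p candidate regressors."""
    return 2.0 * critical_bound(p, alpha).x


def _log_binom(p: int, k: int) -> float:
    return float(gammaln(p + 1) - gammaln(k + 1) - gammaln(p - k + 1))


@dataclass(frozen=True)
class CriterionSpec:
    """A named information criterion bound to an (n, p) selection context.

    Parameters
    ----------
    name : str
        One of ``AIC, BIC, RIC, mAIC, mBIC, EBIC, EAIC``.
    n : int
        Number of observations.
    p : int
        Number of candidate regressors (the multiplicity the extended
        criteria correct for).
    constants : mapping
        Criterion constants; missing entries get field defaults
        (``alpha=0.05`` for EAIC, ``c=1/2`` for mAIC, ``E=4`` for mBIC,
        ``gamma=1`` for EBIC). Unknown keys are rejected.
    """

    name: str
    n: int
    p: int
    constants: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.name not in CRITERION_NAMES:
            raise ValueError(
                f"unknown criterion {self.name!r}; expected one of {CRITERION_NAMES}"
            )
        if self.n < 1 or self.p < 1:
            raise ValueError(f"n and p must be positive, got n={self.n}, p={self.p}")
        allowed = _DEFAULT_CONSTANTS.get(self.name, {})
        extra = set(self.constants) - set(allowed)
        if extra:
            raise ValueError(f"{self.name} does not take constants {sorted(extra)}")
        merged = {**allowed, **dict(self.constants)}
        object.__setattr__(self, "constants", merged)

    @property
    def label(self) -> str:
        """Human-readable method name, e.g. ``EAIC(alpha=0.05)``."""
        if not self.constants:
            return self.name
        inner = ", ".join(f"{k}={v:g}" for k, v in sorted(self.constants.items()))
        return f"{self.name}({inner})"

    def weight(self) -> float:
        """Per-variable penalty weight for the linear-penalty criteria.

        Undefined for EBIC (nonlinear penalty) -> raises.
        """
        import math

        if self.name == "AIC":
            return 2.0
        if self.name == "BIC":
            return math.log(self.n)
        if self.name == "RIC":
            return 2.0 * math.log(self.p)
        if self.name == "mAIC":
            return 2.0 + 2.0 * math.log(self.p / self.constants["c"])
        if self.name == "mBIC":
            return math.log(self.n) + 2.0 * math.log(self.p / self.constants["E"])
        if self.name == "EAIC":
            return eaic_weight(self.p, self.constants["alpha"])
        raise ValueError(f"{self.name} has no per-variable weight (nonlinear penalty)")

    def penalty(self, size: int) -> float:
        """Penalty ``pen(size)``; zero at size 0 for every criterion."""
        import math

        if not 0 <= size <= self.p:
            raise ValueError(f"size must lie in [0, p={self.p}], got {size}")
        if self.name == "EBIC":
            gamma = self.constants["gamma"]
            return math.log(self.n) * size + 2.0 * gamma * _log_binom(self.p, size)
        return self.weight() * size

    def evaluate(self, loglik: float, size: int) -> float:
        """Criterion value ``-2 * loglik + penalty(size)``."""
        return -2.0 * loglik + self.penalty(size)


@dataclass(frozen=True)
class ScoredModel:
    """One candidate sub-model with its refit log-likelihood and criterion score."""

    support: FrozenSet[str]
    loglik: float
    score: float

    @property
    def size(self) -> int:
        return len(self.support)
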