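"""Unpenalized maximum-likelihood fits of linear and logistic sub-models.

All information criteria consume the *maximal unpenalized* log-likelihood
``l(A)`` of each candidate support: comparing penalized likelihoods would
add a shrinkage term to the likelihood-ratio statistic and break its
chi-square asymptotics. This module fits one support at a time (with the
intercept always included and never counted in model size) and also
provides vectorized single-column scans used by the null-hypothesis FWER
study.

Linear models use ordinary least squares with the noise variance profiled
at its MLE, so that ``l(A) = -(n/2) (log(2 pi RSS/n) + 1)`` and
``Delta_l`` between nested fits equals the classical likelihood-ratio
statistic ``(n/2) log(RSS_reduced / RSS_full)``. Logistic models are fit
by scikit-learn's unpenalized solver.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, Iterable, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

__all__ = ["Dataset", "FitResult", "fit_unpenalized", "delta_loglik"]

_FAMILIES = ("linear", "logistic")


@dataclass(frozen=True)
class Dataset:
    """A design matrix with named columns, an outcome and a GLM family.

    ``X`` is an (n, p) float array, ``columns`` the stable identifiers of
    its columns, ``y`` the outcome (real for ``linear``, 0/1 for
    ``logistic``). No missing values are allowed.
    """

    X: np.ndarray
    y: np.ndarray
    family: str
    columns: Tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be a 2-D matrix")
        if y.shape != (X.shape[0],):
            raise ValueError("y must be a vector of length n")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 observations")
        if self.family not in _FAMILIES:
            raise ValueError(f"family must be one of {_FAMILIES}, got {self.family!r}")
        if np.isnan(X).any() or np.isnan(y).any():
            raise ValueError("missing values are not supported")
        if self.family == "logistic" and not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("logistic outcome must contain only 0/1")
        cols = tuple(self.columns) or tuple(f"X{j + 1}" for j in range(X.shape[1]))
        if len(cols) != X.shape[1]:
            raise ValueError("columns must match the number of regressors")
        if len(set(cols)) != len(cols):
            raise ValueError("column identifiers must be unique")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "columns", cols)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def column_index(self, names: Iterable[str]) -> np.ndarray:
        lookup = {c: j for j, c in enumerate(self.columns)}
        try:
            return np.array([lookup[name] for name in names], dtype=int)
        except KeyError as err:
            raise KeyError(f"unknown column {err.args[0]!r}") from None

    @classmethod
    def from_csv(
        cls,
        path: Union[str, Path],
        outcome: str,
        family: str,
    ) -> "Dataset":
        """Load a dataset from a CSV with a header row of column identifiers."""
        frame = pd.read_csv(path)
        if outcome not in frame.columns:
            raise KeyError(f"outcome column {outcome!r} not found in {path}")
        y = frame.pop(outcome).to_numpy(dtype=float)
        return cls(
            X=frame.to_numpy(dtype=float),
            y=y,
            family=family,
            columns=tuple(str(c) for c in frame.columns),
        )


@dataclass(frozen=True)
class FitResult:
    """An unpenalized ML fit on one support: coefficients and maximal log-likelihood."""

    support: FrozenSet[str]
    intercept: float
    coefficients: Dict[str, float]
    loglik: float
    converged: bool = True

    @property
    def size(self) -> int:
        return len(self.support)


def _linear_loglik(rss: float, n: int) -> float:
    # Profiled-variance Gaussian log-likelihood; sigma^2_hat = RSS / n.
    rss = max(rss, 1e-300)
    return -0.5 * n * (math.log(2.0 * math.pi * rss / n) + 1.0)


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # sum y*eta - log(1 + exp(eta)), numerically stable.
    return float(np.sum(y * eta) - np.sum(np.logaddexp(0.0, eta)))


def fit_unpenalized(data: Dataset, support: Iterable[str]) -> FitResult:
    """Fit the sub-model on ``support`` by unpenalized maximum likelihood.

    The intercept is always included. Raises on a singular design (naming
    the offending columns); a logistic fit that hits the iteration cap
    (e.g. under complete separation) is returned with ``converged=False``
    at the likelihood the optimizer reached.
    """
    names = tuple(support)
    idx = data.column_index(names)
    n = data.n
    if len(names) + 1 >= n:
        raise ValueError(
            f"support of size {len(names)} leaves no residual degrees of freedom at n={n}"
        )
    Xs = data.X[:, idx]
    y = data.y

    if data.family == "linear":
        design = np.column_stack([np.ones(n), Xs])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(f"singular design for columns {sorted(names)}")
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        rss = float(resid @ resid)
        return FitResult(
            support=frozenset(names),
            intercept=float(coef[0]),
            coefficients=dict(zip(names, map(float, coef[1:]))),
            loglik=_linear_loglik(rss, n),
        )

    # logistic
    if len(names) == 0:
        phat = float(np.mean(y))
        if phat in (0.0, 1.0):
            return FitResult(frozenset(), math.inf if phat == 1.0 else -math.inf, {}, 0.0)
        ll = n * (phat * math.log(phat) + (1.0 - phat) * math.log(1.0 - phat))
        return FitResult(frozenset(), math.log(phat / (1.0 - phat)), {}, ll)
    design = np.column_stack([np.ones(n), Xs])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError(f"singular design for columns {sorted(names)}")
    model = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000, tol=1e-10)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Xs, y)
    converged = int(model.n_iter_[0]) < 1000
    eta = model.decision_function(Xs)
    return FitResult(
        support=frozenset(names),
        intercept=float(model.intercept_[0]),
        coefficients=dict(zip(names, map(float, model.coef_[0]))),
        loglik=_bernoulli_loglik(y, eta),
        converged=converged,
    )


def delta_loglik(full: FitResult, reduced: FitResult) -> float:
    """Likelihood-ratio increment ``Delta_l = l(full) - l(reduced)`` for nested fits.

    Requires ``reduced.support`` to be a subset of ``full.support``. Small
    negative values (numerical noise, tolerance 1e-8) are clipped to 0.
    """
    if not reduced.support <= full.support:
        raise ValueError("reduced model support must be nested within the full model")
    value = full.loglik - reduced.loglik
    if value < -1e-8:
        raise ValueError(
            f"full-model log-likelihood below reduced model by {-value:.3g}; "
            "fits are not maximal"
        )
    return max(value, 0.0)


# ---------------------------------------------------------------------------
# Vectorized single-column scans (null-hypothesis FWER study fast path).
# Equivalence with per-column fit_unpenalized is asserted in the test suite.
# ---------------------------------------------------------------------------


def null_loglik(data: Dataset) -> float:
    """Maximal log-likelihood of the intercept-only model."""
    return fit_unpenalized(data, ()).loglik


def single_column_logliks(
    data: Dataset, column_idx: Optional[Sequence[int]] = None
) -> np.ndarray:
    """Maximal log-likelihoods of all one-variable sub-models, vectorized.

    ``column_idx`` restricts the scan to a subset of columns (used with
    correlation screening); default is all columns.
    """
    idx = np.arange(data.p) if column_idx is None else np.asarray(column_idx, dtype=int)
    X = data.X[:, idx]
    y = data.y
    n = data.n
    if data.family == "linear":
        yc = y - y.mean()
        ss_y = float(yc @ yc)
        Xc = X - X.mean(axis=0)
        ss_x = np.einsum("ij,ij->j", Xc, Xc)
        cross = Xc.T @ yc
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(ss_x > 0, cross**2 / np.maximum(ss_x * ss_y, 1e-300), 0.0)
        r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
        return _linear_loglik(ss_y, n) - 0.5 * n * np.log1p(-r2)
    return _logistic_scan(X, y)


def _logistic_scan(X: np.ndarray, y: np.ndarray, n_iter: int = 60) -> np.ndarray:
    """Per-column 2-parameter (intercept + slope) logistic ML via damped Newton."""
    n, m = X.shape
    ybar = float(np.mean(y))
    ybar = min(max(ybar, 1e-12), 1.0 - 1e-12)
    a = np.full(m, math.log(ybar / (1.0 - ybar)))
    b = np.zeros(m)
    yc = y[:, None]
    for _ in range(n_iter):
        eta = a[None, :] + X * b[None, :]
        mu = 1.0 / (1.0 + np.exp(-eta))
        r = yc - mu
        w = mu * (1.0 - mu)
        g0 = r.sum(axis=0)
        g1 = np.einsum("ij,ij->j", r, X)
        h00 = w.sum(axis=0)
        h01 = np.einsum("ij,ij->j", w, X)
        h11 = np.einsum("ij,ij,ij->j", w, X, X)
        det = np.maximum(h00 * h11 - h01**2, 1e-300)
        da = (h11 * g0 - h01 * g1) / det
        db = (h00 * g1 - h01 * g0) / det
        # Damp huge steps (separation drives the optimum to infinity).
        step = np.sqrt(da**2 + db**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = np.where(step > 5.0, 5.0 / step, 1.0)
        a += scale * da
        b += scale * db
        if float(np.max(np.abs(g0)) + np.max(np.abs(g1))) < 1e-9 * n:
            break
    eta = a[None, :] + X * b[None, :]
    return (y[:, None] * eta - np.logaddexp(0.0, eta)).sum(axis=0)
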