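"""LASSO-path pre-selection and information-criterion model choice.

The full procedure: run the LASSO over a decreasing regularization grid to
obtain a nested-ish family of sparse candidate supports (the path), refit
every distinct support by *unpenalized* maximum likelihood, score each refit
with an information criterion, and keep the minimizer. Ties go to the
smaller support, then to the earlier path position.

Also provided: the oracle benchmark (first path support with at least the
true number of active variables), the univariate correlation screen, and
the null-scan selector (intercept-only model vs all single-variable
models) used to estimate FWER under a global null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression, lasso_path

from .criteria import CriterionSpec, ScoredModel
from .glm import Dataset, FitResult, fit_unpenalized, null_loglik, single_column_logliks

__all__ = [
    "PathFamily",
    "SelectionResult",
    "lasso_path_supports",
    "select_by_criterion",
    "oracle_select",
    "univariate_screen",
    "null_scan_select",
]


@dataclass(frozen=True)
class PathFamily:
    """Ordered distinct candidate supports, from sparsest (usually empty) up."""

    supports: Tuple[FrozenSet[str], ...]
    source: str = "lasso"

    def __post_init__(self) -> None:
        if len(set(self.supports)) != len(self.supports):
            raise ValueError("path supports must be pairwise distinct")

    def sizes(self) -> List[int]:
        return [len(s) for s in self.supports]


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of minimizing one criterion over a candidate family."""

    method: str
    chosen: ScoredModel
    table: pd.DataFrame
    chosen_fit: Optional[FitResult] = None


def _standardize(X: np.ndarray, columns: Sequence[str]) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    dead = np.flatnonzero(sd == 0.0)
    if dead.size:
        names = [columns[j] for j in dead]
        raise ValueError(f"constant columns cannot be standardized: {names}")
    return (X - mu) / sd


def lasso_path_supports(
    data: Dataset,
    dfmax: int = 100,
    n_lambdas: int = 100,
    eps: Optional[float] = None,
) -> PathFamily:
    """Extract the distinct supports along a LASSO regularization path.

    A geometric grid of ``n_lambdas`` values runs downward from
    ``lambda_max`` (the smallest penalty with an all-zero solution) to
    ``eps * lambda_max``; ``eps`` defaults to 1e-2 when n < p and 1e-4
    otherwise. Columns are standardized internally. The path is truncated
    at the first support whose size exceeds ``dfmax``.
    """
    Xs = _standardize(data.X, data.columns)
    y = data.y
    n = data.n
    if np.all(y == y[0]):
        raise ValueError("outcome is constant; the regularization path is undefined")
    if eps is None:
        eps = 1e-2 if n < data.p else 1e-4
    yc = y - y.mean()
    lam_max = float(np.max(np.abs(Xs.T @ yc)) / n)
    lambdas = np.geomspace(lam_max, lam_max * eps, n_lambdas)

    if data.family == "linear":
        _, coefs, _ = lasso_path(Xs, y, alphas=lambdas)
        active_per_lambda = [np.flatnonzero(coefs[:, k] != 0.0) for k in range(len(lambdas))]
    else:
        active_per_lambda = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            for lam in lambdas:
                model = LogisticRegression(
                    l1_ratio=1.0, C=1.0 / (n * lam), solver="liblinear", tol=1e-6, max_iter=500
                )
                model.fit(Xs, y)
                active_per_lambda.append(np.flatnonzero(model.coef_[0] != 0.0))

    supports: List[FrozenSet[str]] = []
    seen = set()
    for active in active_per_lambda:
        sup = frozenset(data.columns[j] for j in active)
        if len(sup) > dfmax:
            break
        if sup not in seen:
            seen.add(sup)
            supports.append(sup)
    if frozenset() not in seen:
        supports.insert(0, frozenset())
    return PathFamily(supports=tuple(supports), source="lasso")


def _argmin_with_ties(scores: Sequence[float], sizes: Sequence[int]) -> int:
    # Smallest score; ties -> smaller support, then earlier path position.
    best = 0
    for i in range(1, len(scores)):
        if (scores[i], sizes[i], i) < (scores[best], sizes[best], best):
            best = i
    return best


def refit_path(path: PathFamily, data: Dataset) -> List[Tuple[int, FitResult]]:
    """Unpenalized refit of every path support; failures are skipped with a warning.

    Returns (path position, fit) pairs; fits can be shared across criteria
    since the criteria differ only in how they penalize the refits.
    """
    out: List[Tuple[int, FitResult]] = []
    for i, sup in enumerate(path.supports):
        try:
            out.append((i, fit_unpenalized(data, sup)))
        except ValueError as err:
            warnings.warn(f"skipping support {sorted(sup)}: {err}", stacklevel=2)
    if not out:
        raise ValueError("no candidate support could be fit")
    return out


def select_by_criterion(
    path: PathFamily,
    data: Dataset,
    spec: CriterionSpec,
    fits: Optional[List[Tuple[int, FitResult]]] = None,
) -> SelectionResult:
    """Refit every path support without penalty and keep the criterion minimizer.

    ``fits`` may carry precomputed :func:`refit_path` output to avoid
    refitting when several criteria score the same path.
    """
    if not path.supports:
        raise ValueError("empty candidate family")
    if fits is None:
        fits = refit_path(path, data)
    rows = []
    for i, fit in fits:
        rows.append(
            {"support": tuple(sorted(fit.support)), "size": fit.size,
             "loglik": fit.loglik, "score": spec.evaluate(fit.loglik, fit.size),
             "path_index": i}
        )
    table = pd.DataFrame(rows)
    k = _argmin_with_ties(table["score"].tolist(), table["size"].tolist())
    fit = fits[k][1]
    chosen = ScoredModel(
        support=frozenset(table.loc[k, "support"]),
        loglik=float(table.loc[k, "loglik"]),
        score=float(table.loc[k, "score"]),
    )
    return SelectionResult(method=spec.label, chosen=chosen, table=table, chosen_fit=fit)


def oracle_select(path: PathFamily, k: int = 10) -> FrozenSet[str]:
    """First path support with at least ``k`` variables (benchmark selector).

    Falls back to the last support (with a warning) when the path never
    reaches size ``k``.
    """
    if not path.supports:
        raise ValueError("empty candidate family")
    for sup in path.supports:
        if len(sup) >= k:
            return sup
    warnings.warn(
        f"no support of size >= {k} on the path; returning the last support",
        stacklevel=2,
    )
    return path.supports[-1]


def univariate_screen(data: Dataset, fraction: float = 0.9) -> FrozenSet[str]:
    """Columns whose |Pearson correlation with y| is within ``fraction`` of the max.

    Zero-variance columns count as correlation 0.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction!r}")
    yc = data.y - data.y.mean()
    ss_y = float(yc @ yc)
    Xc = data.X - data.X.mean(axis=0)
    ss_x = np.einsum("ij,ij->j", Xc, Xc)
    with np.errstate(divide="ignore", invalid="ignore"):
        cor = np.where(ss_x > 0, np.abs(Xc.T @ yc) / np.sqrt(np.maximum(ss_x * ss_y, 1e-300)), 0.0)
    cmax = float(cor.max()) if cor.size else 0.0
    keep = np.flatnonzero(cor >= fraction * cmax - 1e-15)
    return frozenset(data.columns[j] for j in keep)


def null_scan_select(
    data: Dataset,
    spec: CriterionSpec,
    screening: Optional[float] = None,
) -> SelectionResult:
    """Minimize a criterion over the null model and all single-variable models.

    With ``screening`` set, only columns passing :func:`univariate_screen`
    at that fraction are scanned (the null model is always a candidate).
    Equivalent to rejecting the global null iff ``max_j Delta_l_j``
    exceeds half the criterion's per-variable weight.
    """
    if screening is not None:
        kept = sorted(univariate_screen(data, screening))
        idx = data.column_index(kept)
    else:
        kept = list(data.columns)
        idx = np.arange(data.p)
    ll0 = null_loglik(data)
    lls = single_column_logliks(data, idx)
    score0 = spec.evaluate(ll0, 0)
    pen1 = spec.penalty(1)
    scores = -2.0 * lls + pen1

    rows = [{"support": (), "size": 0, "loglik": ll0, "score": score0, "path_index": 0}]
    for i, (name, ll, sc) in enumerate(zip(kept, lls, scores), start=1):
        rows.append({"support": (name,), "size": 1, "loglik": float(ll),
                     "score": float(sc), "path_index": i})
    table = pd.DataFrame(rows)
    k = _argmin_with_ties(table["score"].tolist(), table["size"].tolist())
    chosen = ScoredModel(
        support=frozenset(table.loc[k, "support"]),
        loglik=float(table.loc[k, "loglik"]),
        score=float(table.loc[k, "score"]),
    )
    return SelectionResult(method=spec.label, chosen=chosen, table=table)
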