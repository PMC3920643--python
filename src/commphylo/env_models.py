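"""Explaining mean family age: bagged-tree importance and GLM variance partition.

``ensemble_importance`` fits a bagged ensemble of regression trees (the
random-forest protocol of the source analyses: 100 trees, bootstrap samples of
size n) and reports out-of-bag permutation importance per predictor, rescaled
so the top predictor scores exactly 1, together with the out-of-bag mean
squared error as the test risk estimate.  ``variance_partition`` contrasts the
OLS :math:`R^2` of the single most important predictor against the full model;
the increase is the contribution of the remaining, non-collinear predictors.

Categorical predictors are one-hot encoded internally; their column
importances are summed back to the original variable before rescaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor

from .errors import DegenerateTraitError, ValidationError

__all__ = ["ImportanceResult", "VariancePartition", "ensemble_importance", "variance_partition"]

log = logging.getLogger(__name__)


@dataclass
class ImportanceResult:
    """Permutation importances (max = 1), OOB risk (Myr^2), and OOB predictions."""

    importance: dict
    risk: float
    n_trees: int
    seed: int | None
    oob_prediction: np.ndarray = field(repr=False, default=None)

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.importance.items(), key=lambda kv: -kv[1])

    @property
    def top_predictor(self) -> str:
        return self.ranked()[0][0]


@dataclass
class VariancePartition:
    """OLS R^2 of the top predictor alone vs the full predictor set."""

    r2_single: float
    r2_full: float

    @property
    def delta(self) -> float:
        return self.r2_full - self.r2_single


def _design(X: pd.DataFrame) -> tuple[np.ndarray, list[str], dict]:
    """One-hot encode categoricals; map design columns back to source predictors."""
    X = pd.DataFrame(X)
    enc = pd.get_dummies(X, dtype=float)
    col_to_var = {}
    for col in enc.columns:
        src = col
        for var in X.columns:
            if col == var or str(col).startswith(str(var) + "_"):
                src = var
                break
        col_to_var[col] = src
    return enc.to_numpy(dtype=float), list(enc.columns), col_to_var


def ensemble_importance(
    y,
    X: pd.DataFrame,
    n_trees: int = 100,
    seed: int | None = None,
    min_samples_leaf: int = 5,
) -> ImportanceResult:
    """Bagged regression trees with out-of-bag permutation importance.

    For each tree, the increase in squared error when a predictor's values are
    permuted among that tree's out-of-bag rows is averaged over trees, summed
    over the one-hot columns of categorical predictors, floored at 0 and
    rescaled so the maximum is exactly 1.  The risk estimate is the mean
    squared error of out-of-bag-aggregated predictions.  Deterministic under
    ``seed``.
    """
    y = pd.Series(y).astype(float)
    X = pd.DataFrame(X)
    if X.shape[1] < 2:
        raise ValidationError("need at least 2 predictors")
    ok = y.notna() & X.notna().all(axis=1)
    dropped = int((~ok).sum())
    if dropped:
        log.info("ensemble_importance: listwise deletion dropped %d rows", dropped)
    y, X = y[ok], X[ok]
    yv = y.to_numpy()
    if np.ptp(yv) == 0:
        raise DegenerateTraitError("response is constant")
    M, cols, col_to_var = _design(X)
    n, p = M.shape

    rng = np.random.default_rng(seed)
    increases = np.zeros(p)
    oob_sum = np.zeros(n)
    oob_count = np.zeros(n)

    for t in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0:
            continue
        tree = DecisionTreeRegressor(
            min_samples_leaf=min_samples_leaf,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(M[boot], yv[boot])
        pred = tree.predict(M[oob])
        oob_sum[oob] += pred
        oob_count[oob] += 1
        base_err = np.mean((yv[oob] - pred) ** 2)
        perm = rng.permutation(oob.size)
        for j in range(p):
            Mp = M[oob].copy()
            Mp[:, j] = Mp[perm, j]
            err = np.mean((yv[oob] - tree.predict(Mp)) ** 2)
            increases[j] += err - base_err
    increases /= n_trees

    per_var: dict[str, float] = {}
    for j, col in enumerate(cols):
        var = col_to_var[col]
        per_var[var] = per_var.get(var, 0.0) + increases[j]
    vals = {k: max(v, 0.0) for k, v in per_var.items()}
    top = max(vals.values())
    if top <= 0:
        raise DegenerateTraitError("no predictor has positive permutation importance")
    importance = {k: float(v / top) for k, v in vals.items()}

    seen = oob_count > 0
    oob_pred = np.full(n, np.nan)
    oob_pred[seen] = oob_sum[seen] / oob_count[seen]
    risk = float(np.mean((yv[seen] - oob_pred[seen]) ** 2))
    return ImportanceResult(
        importance=importance,
        risk=risk,
        n_trees=n_trees,
        seed=seed,
        oob_prediction=pd.Series(oob_pred, index=y.index).to_numpy(),
    )


def _ols_r2(y: np.ndarray, M: np.ndarray) -> float:
    """R^2 of OLS with intercept; rank-deficient designs handled by lstsq."""
    A = np.column_stack([np.ones(y.size), M])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        log.warning("variance_partition: rank-deficient design; aliased columns ignored")
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - ss_res / ss_tot


def variance_partition(y, X: pd.DataFrame, top_predictor: str) -> VariancePartition:
    """OLS R^2 for the top predictor alone vs all predictors together."""
    y = pd.Series(y).astype(float)
    X = pd.DataFrame(X)
    if top_predictor not in X.columns:
        raise ValidationError(f"unknown predictor {top_predictor!r}")
    ok = y.notna() & X.notna().all(axis=1)
    y, X = y[ok], X[ok]
    yv = y.to_numpy()
    M_single, _, _ = _design(X[[top_predictor]])
    M_full, _, _ = _design(X)
    return VariancePartition(
        r2_single=_ols_r2(yv, M_single),
        r2_full=_ols_r2(yv, M_full),
    )
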