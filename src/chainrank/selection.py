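"""Importance-based feature selection via L2-penalized logistic regression.

A logistic-regression model with an L2 (ridge) penalty is fitted on
per-column standardized features; each feature's importance score is the
absolute value of its coefficient, and features whose score exceeds a
fixed threshold (default 0.1) are retained. An L1 penalty is available as
an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.linear_model import LogisticRegression
from sklearn.utils.validation import check_is_fitted, check_X_y

from .containers import EngineeredDataset, FeatureMatrix

__all__ = [
    "SelectionResult",
    "RidgeImportanceSelector",
    "ridge_importance",
    "select_features",
    "apply_selection",
]


@dataclass
class SelectionResult:
    """Per-feature importance scores and the surviving feature indices."""

    scores: np.ndarray
    threshold: float
    selected: np.ndarray  # ordered original-position indices

    @property
    def n_in(self) -> int:
        return len(self.scores)

    @property
    def n_out(self) -> int:
        return len(self.selected)


class RidgeImportanceSelector(SelectorMixin, BaseEstimator):
    """Select features whose penalized-model |coefficient| exceeds a threshold.

    Parameters
    ----------
    threshold : float, default 0.1
        Importance cut-off. With ``strict=True`` (default) a feature must
        score strictly above the threshold to survive.
    reg_strength : float, default 1.0
        Penalty weight; the underlying logistic regression uses
        ``C = 1 / reg_strength``.
    penalty : {"l2", "l1"}, default "l2"
    fallback_topk : int or None
        If no feature survives the threshold, keep the ``k`` best instead
        of raising.
    standardize : bool, default True
        Standardize columns (population moments, computed on the data
        given to ``fit``) before fitting, so coefficients are comparable
        across features on different scales.
    random_state : int or None
        Seed for the solver where stochastic (saga).
    """

    def __init__(
        self,
        threshold: float = 0.1,
        reg_strength: float = 1.0,
        penalty: str = "l2",
        fallback_topk: int | None = None,
        strict: bool = True,
        standardize: bool = True,
        max_iter: int = 1000,
        random_state: int | None = None,
    ):
        self.threshold = threshold
        self.reg_strength = reg_strength
        self.penalty = penalty
        self.fallback_topk = fallback_topk
        self.strict = strict
        self.standardize = standardize
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("both classes must be present to score features")
        if self.standardize:
            mu = X.mean(axis=0)
            sd = X.std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            X = (X - mu) / sd
        if self.penalty not in ("l2", "l1"):
            raise ValueError("penalty must be 'l2' or 'l1'")
        clf = LogisticRegression(
            l1_ratio=0 if self.penalty == "l2" else 1,
            C=1.0 / self.reg_strength,
            solver="lbfgs" if self.penalty == "l2" else "liblinear",
            max_iter=self.max_iter,
            random_state=self.random_state,
        )
        clf.fit(X, y)
        self.scores_ = np.abs(clf.coef_.ravel())
        self.n_features_in_ = X.shape[1]
        self._resolve_support()
        return self

    def _resolve_support(self) -> None:
        above = (
            self.scores_ > self.threshold
            if self.strict
            else self.scores_ >= self.threshold
        )
        if not above.any():
            if self.fallback_topk is None:
                raise ValueError(
                    "no feature scored above the threshold "
                    f"{self.threshold} (max observed score: {self.scores_.max():.6g}); "
                    "lower the threshold or set fallback_topk"
                )
            k = min(self.fallback_topk, len(self.scores_))
            top = np.argsort(self.scores_)[::-1][:k]
            above = np.zeros_like(above)
            above[top] = True
        self.support_ = above

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_

    def selection_result(self) -> SelectionResult:
        check_is_fitted(self, "support_")
        return SelectionResult(
            self.scores_, self.threshold, np.where(self.support_)[0]
        )


def ridge_importance(
    x: FeatureMatrix | np.ndarray,
    y: np.ndarray,
    reg_strength: float = 1.0,
    seed: int | None = None,
    penalty: str = "l2",
) -> np.ndarray:
    """Per-feature importance scores (|coefficient| of the penalized model)."""
    values = x.values if isinstance(x, FeatureMatrix) else np.asarray(x, float)
    sel = RidgeImportanceSelector(
        threshold=0.0,
        reg_strength=reg_strength,
        penalty=penalty,
        random_state=seed,
        fallback_topk=values.shape[1],
    )
    sel.fit(values, y)
    return sel.scores_


def select_features(
    scores: np.ndarray,
    threshold: float = 0.1,
    strict: bool = True,
    fallback_topk: int | None = None,
) -> SelectionResult:
    """Retain features scoring above the threshold, in original order."""
    scores = np.asarray(scores, dtype=float)
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    mask = scores > threshold if strict else scores >= threshold
    if not mask.any():
        if fallback_topk is None:
            raise ValueError(
                f"no feature scored above {threshold} "
                f"(max observed score: {scores.max():.6g}); "
                "lower the threshold or use fallback_topk"
            )
        k = min(fallback_topk, len(scores))
        selected = np.sort(np.argsort(scores)[::-1][:k])
    else:
        selected = np.where(mask)[0]
    return SelectionResult(scores, threshold, selected)


def apply_selection(
    ds: EngineeredDataset, sel: SelectionResult
) -> EngineeredDataset:
    """Column-slice an engineered dataset to the selected features."""
    idx = np.asarray(sel.selected, dtype=int)
    if len(idx) == 0:
        raise ValueError("selection is empty; refusing to produce a 0-feature table")
    if idx.min() < 0 or idx.max() >= ds.matrix.n_features:
        raise IndexError("selected indices out of range for this dataset")
    matrix = FeatureMatrix(
        ds.matrix.values[:, idx],
        list(ds.matrix.sample_ids),
        [ds.matrix.feature_ids[j] for j in idx],
    )
    origins = [ds.column_origins[j] for j in idx]
    return EngineeredDataset(matrix, ds.variant, ds.chain, origins)
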