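"""Classification metrics, distribution summaries, and significance testing.

Metrics follow the standard convention for a binary disease classifier
with the disease class (CRC) as the positive label:

- sensitivity (TPR) = TP / (TP + FN)
- specificity (TNR) = TN / (TN + FP)
- false-positive rate = FP / (FP + TN) = 1 - specificity
- AUC = area under the ROC curve, equal to the probability that a random
  case outscores a random control (ties counted 1/2).

Distribution summaries capture nine attributes of a matrix's pooled
entries (kurtosis, skewness, std, max, min, mean and the 25th/50th/75th
percentiles); an OLS regression of AUC on chosen attributes quantifies
how the shape of the engineered data associates with performance.
Between-method significance uses two-sided Wilcoxon tests (rank-sum for
independent groups, signed-rank for paired fold-level AUCs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score

from .containers import FeatureMatrix

__all__ = [
    "ConfusionCounts",
    "DistributionSummary",
    "confusion",
    "sensitivity",
    "specificity",
    "fpr",
    "roc_auc",
    "distribution_summary",
    "auc_distribution_regression",
    "compare_methods",
    "ComparisonResult",
]

DIST_ATTRIBUTES = (
    "kurtosis",
    "skewness",
    "std",
    "max",
    "min",
    "mean",
    "p25",
    "p50",
    "p75",
)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(
    y_true: np.ndarray, y_prob: np.ndarray, threshold: float = 0.5
) -> ConfusionCounts:
    """Two-by-two confusion counts; prediction is positive iff prob >= threshold."""
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob, dtype=float)
    if y_true.shape != y_prob.shape:
        raise ValueError("y_true and y_prob must have equal length")
    if np.any((y_prob < 0) | (y_prob > 1)):
        raise ValueError("y_prob must lie in [0, 1]")
    pred = y_prob >= threshold
    pos = y_true == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
    )


def sensitivity(c: ConfusionCounts) -> float | None:
    """TP / (TP + FN); None when no positives were evaluated."""
    denom = c.tp + c.fn
    return c.tp / denom if denom > 0 else None


def specificity(c: ConfusionCounts) -> float | None:
    """TN / (TN + FP); None when no negatives were evaluated."""
    denom = c.tn + c.fp
    return c.tn / denom if denom > 0 else None


def fpr(c: ConfusionCounts) -> float | None:
    """FP / (FP + TN); None when no negatives were evaluated."""
    denom = c.tn + c.fp
    return c.fp / denom if denom > 0 else None


def roc_auc(y_true: np.ndarray, y_prob: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney pair-counting statistic)."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("both classes must be present to compute AUC")
    return float(roc_auc_score(y_true, np.asarray(y_prob, dtype=float)))


@dataclass(frozen=True)
class DistributionSummary:
    kurtosis: float
    skewness: float
    std: float
    max: float
    min: float
    mean: float
    p25: float
    p50: float
    p75: float

    def as_dict(self) -> dict[str, float]:
        return {a: getattr(self, a) for a in DIST_ATTRIBUTES}


def distribution_summary(
    m: FeatureMatrix | np.ndarray,
    excess_kurtosis: bool = True,
    per_column: bool = False,
) -> DistributionSummary:
    """Nine distribution attributes of the matrix entries.

    By default entries are pooled across the whole matrix; with
    ``per_column=True`` each attribute is the mean of its per-column
    values. Kurtosis defaults to the excess convention (normal -> 0);
    skewness is the standardized third moment.
    """
    values = m.values if isinstance(m, FeatureMatrix) else np.asarray(m, float)
    if values.size == 0:
        raise ValueError("empty matrix")
    axis = 0 if per_column else None
    flat = values if per_column else values.ravel()
    kurt = stats.kurtosis(flat, axis=axis, fisher=excess_kurtosis)
    skew = stats.skew(flat, axis=axis)
    out = dict(
        kurtosis=float(np.mean(kurt)),
        skewness=float(np.mean(skew)),
        std=float(np.mean(flat.std(axis=axis))),
        max=float(np.mean(flat.max(axis=axis))),
        min=float(np.mean(flat.min(axis=axis))),
        mean=float(np.mean(flat.mean(axis=axis))),
        p25=float(np.mean(np.percentile(flat, 25, axis=axis))),
        p50=float(np.mean(np.percentile(flat, 50, axis=axis))),
        p75=float(np.mean(np.percentile(flat, 75, axis=axis))),
    )
    return DistributionSummary(**out)


def auc_distribution_regression(
    records: pd.DataFrame | list[dict],
    predictors: tuple[str, ...] = ("kurtosis", "skewness"),
    response: str = "auc",
) -> dict:
    """OLS of AUC on distribution attributes, plus the full correlation matrix.

    ``records`` rows need the response column plus the predictor columns
    (typically the nine distribution attributes and a ``time_s`` column).
    Returns per-coefficient estimates/t/p, residual SE, R², adjusted R²,
    F statistic and p-value, and the correlation matrix among the response
    and every available numeric attribute.
    """
    df = pd.DataFrame(records)
    missing = [c for c in (response, *predictors) if c not in df.columns]
    if missing:
        raise ValueError(f"records lack column(s): {missing}")
    if len(df) < len(predictors) + 2:
        raise ValueError("need at least p + 2 records for the regression")
    X = sm.add_constant(df[list(predictors)].astype(float))
    fit = sm.OLS(df[response].astype(float), X).fit()
    corr_cols = [
        c
        for c in (response, "time_s", *DIST_ATTRIBUTES)
        if c in df.columns and pd.api.types.is_numeric_dtype(df[c])
    ]
    return {
        "coefficients": {
            name: {
                "estimate": float(fit.params[name]),
                "t_value": float(fit.tvalues[name]),
                "p_value": float(fit.pvalues[name]),
            }
            for name in fit.params.index
        },
        "residual_se": float(np.sqrt(fit.mse_resid)) if fit.df_resid > 0 else 0.0,
        "r_squared": float(fit.rsquared),
        "adj_r_squared": float(fit.rsquared_adj),
        "f_statistic": float(fit.fvalue) if fit.df_resid > 0 else float("nan"),
        "f_p_value": float(fit.f_pvalue) if fit.df_resid > 0 else float("nan"),
        "n": int(fit.nobs),
        "correlations": df[corr_cols].corr(),
    }


@dataclass(frozen=True)
class ComparisonResult:
    p_value: float
    statistic: float
    test: str  # "rank-sum" or "signed-rank"
    degenerate: bool = False

    def __float__(self) -> float:
        return self.p_value


def compare_methods(
    aucs_a: np.ndarray,
    aucs_b: np.ndarray,
    paired: bool = True,
    alternative: str = "two-sided",
) -> ComparisonResult:
    """Wilcoxon significance test between two sets of performance scores.

    ``paired=True`` runs the signed-rank test (scores share folds/seeds),
    ``paired=False`` the rank-sum (Mann-Whitney) test. Exact p-values are
    used where the sample size and tie structure permit, with the
    tie-corrected normal approximation otherwise. All-zero differences in
    paired mode return a flagged degenerate result (p = 1).
    """
    a = np.asarray(aucs_a, dtype=float)
    b = np.asarray(aucs_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per group")
    if paired:
        if len(a) != len(b):
            raise ValueError("paired comparison needs equal-length vectors")
        if np.allclose(a, b):
            return ComparisonResult(1.0, 0.0, "signed-rank", degenerate=True)
        res = stats.wilcoxon(a, b, alternative=alternative, method="auto")
        return ComparisonResult(float(res.pvalue), float(res.statistic), "signed-rank")
    res = stats.mannwhitneyu(a, b, alternative=alternative, method="auto")
    return ComparisonResult(float(res.pvalue), float(res.statistic), "rank-sum")
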