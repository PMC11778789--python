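"""Column-wise normalization methods, sequential chaining and rank transformation.

Every method operates independently on each feature column. Writing a
column as :math:`a_{\\cdot j}` with population mean :math:`\\mu_j` and
population standard deviation :math:`\\sigma_j`:

- ``zsn``  — z-score: :math:`(a_{ij}-\\mu_j)/\\sigma_j` (mean 0, variance 1)
- ``psn``  — Pareto scaling: :math:`(a_{ij}-\\mu_j)/\\sqrt{\\sigma_j}`
- ``vss``  — variable stability scaling: the z-score multiplied by the
  coefficient-of-variation factor :math:`\\mu_j/\\sigma_j`
- ``mmn``  — min-max: :math:`(a_{ij}-\\min_j)/(\\max_j-\\min_j)`
- ``sigmoid`` — logistic squashing of the z-score, range (0, 1)
- ``mmadn``   — robust scaling :math:`(a_{ij}-\\mathrm{med}_j)/\\mathrm{MAD}_j`

Degenerate columns (zero variance / range / MAD) map to all-zero columns
with a warning rather than raising: chained pipelines routinely create
constant columns (e.g. ``zsn`` followed by ``vss``) and must survive them.

Rank transformation replaces each column by its ascending ranks in
``1..n`` with average ranks for ties, making any downstream model
invariant to strictly increasing per-column distortions of the input.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .containers import DEFAULT_METHODS, VALID_METHODS, ChainSpec, FeatureMatrix

__all__ = [
    "zsn",
    "psn",
    "vss",
    "mmn",
    "sigmoid_norm",
    "mmadn",
    "apply_chain",
    "rank_transform",
    "ChainNormalizer",
    "RankTransformer",
]


def _as_matrix(x: np.ndarray) -> tuple[np.ndarray, bool]:
    """Promote a column vector to a 1-column matrix; remember the shape."""
    a = np.asarray(x, dtype=float)
    if a.ndim == 1:
        return a[:, None], True
    if a.ndim != 2:
        raise ValueError("input must be a vector or a 2-D matrix")
    return a, False


def _check_input(a: np.ndarray, feature_ids: list[str] | None) -> None:
    if a.shape[0] < 2:
        raise ValueError("normalization needs at least 2 samples per column")
    finite = np.isfinite(a).all(axis=0)
    if not finite.all():
        bad = np.where(~finite)[0]
        names = (
            [feature_ids[j] for j in bad[:5]]
            if feature_ids is not None
            else bad[:5].tolist()
        )
        raise ValueError(f"non-finite values in column(s): {names}")


def _warn_degenerate(
    mask: np.ndarray, method: str, feature_ids: list[str] | None
) -> None:
    if mask.any():
        idx = np.where(mask)[0]
        names = (
            [feature_ids[j] for j in idx[:5]]
            if feature_ids is not None
            else idx[:5].tolist()
        )
        warnings.warn(
            f"{method}: {mask.sum()} constant column(s) mapped to zeros "
            f"(first: {names})",
            stacklevel=3,
        )


def _normalize(
    x: np.ndarray, method: str, feature_ids: list[str] | None = None
) -> np.ndarray:
    a, was_vector = _as_matrix(x)
    _check_input(a, feature_ids)
    mu = a.mean(axis=0)
    sd = a.std(axis=0)  # population std (divide by n)
    if method == "zsn":
        degenerate = sd == 0
        scale = np.where(degenerate, 1.0, sd)
        out = np.where(degenerate, 0.0, (a - mu) / scale)
    elif method == "psn":
        degenerate = sd == 0
        scale = np.where(degenerate, 1.0, np.sqrt(sd))
        out = np.where(degenerate, 0.0, (a - mu) / scale)
    elif method == "vss":
        degenerate = sd == 0
        scale = np.where(degenerate, 1.0, sd)
        # a mean that is zero up to rounding (e.g. a z-scored column) must
        # give an exactly-zero coefficient of variation, not 1e-16 noise
        eff_mu = np.where(np.abs(mu) < 1e-12 * scale, 0.0, mu)
        out = np.where(degenerate, 0.0, (a - mu) / scale * (eff_mu / scale))
    elif method == "mmn":
        lo, hi = a.min(axis=0), a.max(axis=0)
        degenerate = hi == lo
        rng = np.where(degenerate, 1.0, hi - lo)
        out = np.where(degenerate, 0.0, (a - lo) / rng)
    elif method == "sigmoid":
        degenerate = sd == 0
        scale = np.where(degenerate, 1.0, sd)
        z = np.where(degenerate, 0.0, (a - mu) / scale)
        out = 1.0 / (1.0 + np.exp(-z))
        degenerate = np.zeros_like(degenerate)  # constant -> 0.5, not a failure
    elif method == "mmadn":
        med = np.median(a, axis=0)
        mad = np.median(np.abs(a - med), axis=0)
        degenerate = mad == 0
        scale = np.where(degenerate, 1.0, mad)
        out = np.where(degenerate, 0.0, (a - med) / scale)
    else:
        raise ValueError(f"unknown method {method!r}; valid: {VALID_METHODS}")
    _warn_degenerate(degenerate, method, feature_ids)
    return out[:, 0] if was_vector else out


def zsn(col: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance standardization (population moments)."""
    return _normalize(col, "zsn")


def psn(col: np.ndarray) -> np.ndarray:
    """Pareto scaling: center, then divide by the square root of the std."""
    return _normalize(col, "psn")


def vss(col: np.ndarray) -> np.ndarray:
    """Variable stability scaling: z-score times the factor mu/sigma."""
    return _normalize(col, "vss")


def mmn(col: np.ndarray) -> np.ndarray:
    """Min-max normalization to [0, 1]."""
    return _normalize(col, "mmn")


def sigmoid_norm(col: np.ndarray) -> np.ndarray:
    """Logistic squashing of the z-score; output in (0, 1)."""
    return _normalize(col, "sigmoid")


def mmadn(col: np.ndarray) -> np.ndarray:
    """Median/MAD robust scaling."""
    return _normalize(col, "mmadn")


def apply_chain(
    m: FeatureMatrix | np.ndarray, chain: ChainSpec | list[str] | str
) -> FeatureMatrix | np.ndarray:
    """Apply the chain's methods sequentially, column-wise.

    Each method consumes the previous method's output; statistics are
    recomputed on the intermediate matrix at every step. Shape and
    identifiers are preserved. Accepts a ``FeatureMatrix`` or a bare
    array and returns the same kind.
    """
    if isinstance(chain, str):
        chain = ChainSpec.parse(chain)
    elif not isinstance(chain, ChainSpec):
        chain = ChainSpec(tuple(chain))
    if isinstance(m, FeatureMatrix):
        values = m.values
        ids = m.feature_ids
    else:
        values = np.asarray(m, dtype=float)
        ids = None
    for method in chain:
        values = _normalize(values, method, feature_ids=ids)
    if isinstance(m, FeatureMatrix):
        return m.with_values(values)
    return values


def rank_transform(m: FeatureMatrix | np.ndarray) -> FeatureMatrix | np.ndarray:
    """Replace each column by ascending ranks in 1..n, average ranks for ties."""
    if isinstance(m, FeatureMatrix):
        return m.with_values(rankdata(m.values, axis=0, method="average"))
    a, was_vector = _as_matrix(m)
    ranks = rankdata(a, axis=0, method="average")
    return ranks[:, 0] if was_vector else ranks


class ChainNormalizer(TransformerMixin, BaseEstimator):
    """Sequential column-wise normalization as a scikit-learn transformer.

    Parameters
    ----------
    methods : sequence of str, default ``("zsn", "psn", "vss", "mmn")``
        Chain applied in order; valid names are ``zsn``, ``psn``, ``vss``,
        ``mmn``, ``sigmoid``, ``mmadn``.
    refit : bool, default True
        If True (the default, matching the whole-dataset preprocessing the
        pipeline is defined with), statistics are recomputed on whatever
        matrix ``transform`` receives. If False, each step's column
        statistics are frozen on the data seen by ``fit`` and replayed on
        new data, giving a leakage-free train/test mode.
    """

    def __init__(self, methods=DEFAULT_METHODS, refit: bool = True):
        self.methods = methods
        self.refit = refit

    def _chain(self) -> ChainSpec:
        return (
            self.methods
            if isinstance(self.methods, ChainSpec)
            else ChainSpec(tuple(self.methods))
        )

    def fit(self, X, y=None):
        X = check_array(X, ensure_min_samples=2)
        self.n_features_in_ = X.shape[1]
        if not self.refit:
            # replay mode: record each step's statistics on the training data
            steps = []
            a = X.astype(float)
            for method in self._chain():
                stats = self._column_stats(a, method)
                steps.append((method, stats))
                a = self._apply_stats(a, method, stats)
            self.steps_ = steps
        else:
            self.steps_ = None
            self._chain()  # validate method names eagerly
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X, ensure_min_samples=2 if self.refit else 1)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count changed between fit and transform")
        if self.refit:
            return apply_chain(X.astype(float), self._chain())
        a = X.astype(float)
        for method, stats in self.steps_:
            a = self._apply_stats(a, method, stats)
        return a

    @staticmethod
    def _column_stats(a: np.ndarray, method: str) -> dict:
        mu, sd = a.mean(axis=0), a.std(axis=0)
        lo, hi = a.min(axis=0), a.max(axis=0)
        med = np.median(a, axis=0)
        mad = np.median(np.abs(a - med), axis=0)
        return {"mu": mu, "sd": sd, "lo": lo, "hi": hi, "med": med, "mad": mad}

    @staticmethod
    def _apply_stats(a: np.ndarray, method: str, s: dict) -> np.ndarray:
        mu, sd = s["mu"], s["sd"]
        if method in ("zsn", "sigmoid"):
            z = np.where(sd == 0, 0.0, (a - mu) / np.where(sd == 0, 1.0, sd))
            return 1.0 / (1.0 + np.exp(-z)) if method == "sigmoid" else z
        if method == "psn":
            scale = np.where(sd == 0, 1.0, np.sqrt(sd))
            return np.where(sd == 0, 0.0, (a - mu) / scale)
        if method == "vss":
            scale = np.where(sd == 0, 1.0, sd)
            eff_mu = np.where(np.abs(mu) < 1e-12 * scale, 0.0, mu)
            return np.where(sd == 0, 0.0, (a - mu) / scale * (eff_mu / scale))
        if method == "mmn":
            lo, hi = s["lo"], s["hi"]
            rng = np.where(hi == lo, 1.0, hi - lo)
            return np.where(hi == lo, 0.0, (a - lo) / rng)
        if method == "mmadn":
            med, mad = s["med"], s["mad"]
            scale = np.where(mad == 0, 1.0, mad)
            return np.where(mad == 0, 0.0, (a - med) / scale)
        raise ValueError(f"unknown method {method!r}")


class RankTransformer(TransformerMixin, BaseEstimator):
    """Column-wise ascending rank transformation (ties get average ranks)."""

    def fit(self, X, y=None):
        X = check_array(X)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "n_features_in_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count changed between fit and transform")
        return rankdata(X, axis=0, method="average")
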