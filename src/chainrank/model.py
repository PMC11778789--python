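"""Dense neural-network classifier and its cross-validated evaluation protocol.

The classifier is a 4-layer feed-forward network: input -> 512 ReLU units
-> 256 ReLU units -> 1 sigmoid output, trained with Adam (learning rate
0.001) on binary cross-entropy. It is backed by scikit-learn's
:class:`~sklearn.neural_network.MLPClassifier`, whose binary mode is
exactly this architecture (logistic output unit, log-loss).

Evaluation uses stratified k-fold cross-validation (default k=5):
out-of-fold predicted probabilities, per-fold AUC, and a pooled confusion
matrix at probability threshold 0.5. Everything is seeded: the fold split
and the weight initialization use seeds recorded in the result.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_is_fitted, check_X_y

from .containers import EngineeredDataset, FeatureMatrix
from .evaluation import confusion, fpr, roc_auc, sensitivity, specificity

__all__ = [
    "DNNConfig",
    "CVProtocol",
    "DNNClassifier",
    "build_dnn",
    "parameter_count",
    "train_eval_cv",
    "CVResult",
]


@dataclass
class DNNConfig:
    """Hyperparameters of the dense network.

    The hidden widths (512, 256), activations and Adam learning rate 0.001
    are the reference architecture; epochs and batch size are training
    knobs with tabular-scale defaults.
    """

    hidden_sizes: tuple[int, int] = (512, 256)
    learning_rate: float = 0.001
    epochs: int = 100
    batch_size: int = 16
    class_weight: str | None = None  # None or "balanced"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass
class CVProtocol:
    """Stratified k-fold protocol (every fold must contain both classes)."""

    k: int = 5
    repeats: int = 1
    seed: int = 0


def parameter_count(input_dim: int, hidden_sizes: tuple[int, int] = (512, 256)) -> int:
    """Trainable parameters of the input -> h1 -> h2 -> 1 network."""
    h1, h2 = hidden_sizes
    return input_dim * h1 + h1 + h1 * h2 + h2 + h2 * 1 + 1


class DNNClassifier(ClassifierMixin, BaseEstimator):
    """Feed-forward binary classifier (512/256 ReLU hidden, sigmoid output).

    A scikit-learn estimator: ``fit(X, y)``, ``predict_proba(X)``,
    ``predict(X)``. After fitting, ``n_parameters_`` holds the trainable
    parameter count of the realized network.
    """

    def __init__(
        self,
        hidden_sizes: tuple[int, int] = (512, 256),
        learning_rate: float = 0.001,
        epochs: int = 100,
        batch_size: int = 16,
        random_state: int | None = 0,
        expected_input_dim: int | None = None,
    ):
        self.hidden_sizes = hidden_sizes
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.random_state = random_state
        self.expected_input_dim = expected_input_dim

    def _backend(self, n_samples: int) -> MLPClassifier:
        return MLPClassifier(
            hidden_layer_sizes=tuple(self.hidden_sizes),
            activation="relu",
            solver="adam",
            learning_rate_init=self.learning_rate,
            max_iter=self.epochs,
            batch_size=min(self.batch_size, n_samples),
            n_iter_no_change=self.epochs,  # train the full epoch budget
            random_state=self.random_state,
        )

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        if (
            self.expected_input_dim is not None
            and X.shape[1] != self.expected_input_dim
        ):
            raise ValueError(
                f"network was built for input_dim={self.expected_input_dim} "
                f"but got {X.shape[1]} features"
            )
        self._mlp = self._backend(X.shape[0])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self._mlp.fit(X, y)
        self.classes_ = self._mlp.classes_
        self.n_features_in_ = X.shape[1]
        self.n_parameters_ = sum(c.size for c in self._mlp.coefs_) + sum(
            b.size for b in self._mlp.intercepts_
        )
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "classes_")
        return self._mlp.predict_proba(X)

    def predict(self, X):
        check_is_fitted(self, "classes_")
        return self._mlp.predict(X)


def build_dnn(input_dim: int, cfg: DNNConfig | None = None) -> DNNClassifier:
    """Instantiate the network for a known input width."""
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    cfg = cfg or DNNConfig()
    return DNNClassifier(
        hidden_sizes=tuple(cfg.hidden_sizes),
        learning_rate=cfg.learning_rate,
        epochs=cfg.epochs,
        batch_size=cfg.batch_size,
        random_state=cfg.seed,
        expected_input_dim=input_dim,
    )


@dataclass
class CVResult:
    """Cross-validated evaluation summary."""

    fold_aucs: list[float]
    mean_auc: float
    auc: float  # pooled out-of-fold AUC
    sensitivity: float | None
    specificity: float | None
    fpr: float | None
    confusion: dict
    oof_prob: np.ndarray
    fold_assignment: np.ndarray
    time_s: float
    split_seed: int
    weight_seed: int

    def summary(self) -> dict:
        d = asdict(self)
        d["oof_prob"] = None
        d["fold_assignment"] = None
        return {k: v for k, v in d.items() if v is not None or k in ("sensitivity", "specificity", "fpr")}


def _positive_proba(clf, X) -> np.ndarray:
    proba = clf.predict_proba(X)
    pos = list(clf.classes_).index(1)
    return proba[:, pos]


def train_eval_cv(
    ds: EngineeredDataset | FeatureMatrix | np.ndarray,
    y: np.ndarray,
    cfg: DNNConfig | None = None,
    cv: CVProtocol | None = None,
    estimator: BaseEstimator | None = None,
) -> CVResult:
    """Stratified-CV evaluation with out-of-fold predictions.

    ``estimator`` overrides the default network — pass e.g. a
    ``LogisticRegression`` to run the linear baseline under the identical
    protocol and fold split.
    """
    if isinstance(ds, EngineeredDataset):
        X = ds.matrix.values
    elif isinstance(ds, FeatureMatrix):
        X = ds.values
    else:
        X = np.asarray(ds, dtype=float)
    y = np.asarray(y, dtype=int)
    cfg = cfg or DNNConfig()
    cv = cv or CVProtocol()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if counts.min() < cv.k:
        raise ValueError(
            f"minority class has {counts.min()} samples; cannot stratify into {cv.k} folds"
        )

    t0 = time.perf_counter()
    fold_aucs: list[float] = []
    oof = np.full(len(y), np.nan)
    assignment = np.full(len(y), -1, dtype=int)
    for rep in range(cv.repeats):
        split_seed = cv.seed + rep
        skf = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=split_seed)
        for fold, (tr, te) in enumerate(skf.split(X, y)):
            if len(np.unique(y[tr])) < 2 or len(np.unique(y[te])) < 2:
                raise ValueError(f"fold {fold} does not contain both classes")
            if estimator is not None:
                clf = clone(estimator)
            else:
                clf = build_dnn(X.shape[1], cfg)
            clf.fit(X[tr], y[tr])
            p = _positive_proba(clf, X[te])
            fold_aucs.append(roc_auc(y[te], p))
            if rep == 0:
                oof[te] = p
                assignment[te] = fold
    elapsed = time.perf_counter() - t0

    cm = confusion(y, oof, threshold=0.5)
    return CVResult(
        fold_aucs=fold_aucs,
        mean_auc=float(np.mean(fold_aucs)),
        auc=roc_auc(y, oof),
        sensitivity=sensitivity(cm),
        specificity=specificity(cm),
        fpr=fpr(cm),
        confusion={"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn},
        oof_prob=oof,
        fold_assignment=assignment,
        time_s=elapsed,
        split_seed=cv.seed,
        weight_seed=cfg.seed,
    )


def logistic_baseline(seed: int = 0) -> LogisticRegression:
    """The linear reference model evaluated under the same CV protocol."""
    return LogisticRegression(max_iter=2000, random_state=seed)
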