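"""Core data containers and tabular I/O.

An abundance table is a samples-by-features numeric matrix with unique
sample and feature identifiers and, optionally, a binary disease label per
sample (1 = case). Tables are exchanged on disk as TSV/CSV with a header
row of feature IDs, sample IDs in the first column and the label in a
final ``label`` column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

VALID_METHODS = ("zsn", "psn", "vss", "mmn", "sigmoid", "mmadn")
DEFAULT_METHODS = ("zsn", "psn", "vss", "mmn")

LABEL_COLUMN = "label"


@dataclass(frozen=True)
class ChainSpec:
    """An ordered list of normalization-method names applied sequentially."""

    methods: tuple[str, ...]

    def __post_init__(self) -> None:
        methods = tuple(self.methods)
        object.__setattr__(self, "methods", methods)
        if not methods:
            raise ValueError("a chain must contain at least one method")
        if len(set(methods)) != len(methods):
            raise ValueError(f"duplicate method names in chain: {methods}")
        # name validity is checked where methods are applied, so chains over
        # arbitrary tokens can be enumerated and inspected

    def __iter__(self):
        return iter(self.methods)

    def __len__(self) -> int:
        return len(self.methods)

    @classmethod
    def parse(cls, text: str) -> "ChainSpec":
        """Parse a comma-separated chain such as ``"vss,psn"``."""
        return cls(tuple(t.strip() for t in text.split(",") if t.strip()))

    def __str__(self) -> str:
        return ",".join(self.methods)


@dataclass
class FeatureMatrix:
    """A samples-by-features real matrix with identifiers.

    Invariants: finite values, at least 2 samples and 1 feature, unique
    sample and feature identifiers.
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n < 2:
            raise ValueError("a feature matrix needs at least 2 samples")
        if p < 1:
            raise ValueError("a feature matrix needs at least 1 feature")
        if len(self.sample_ids) != n or len(self.feature_ids) != p:
            raise ValueError("identifier lengths do not match matrix shape")
        if len(set(self.feature_ids)) != p:
            raise ValueError("feature_ids must be unique")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample_ids must be unique")
        if not np.all(np.isfinite(self.values)):
            bad = np.where(~np.isfinite(self.values).all(axis=0))[0]
            names = [self.feature_ids[j] for j in bad[:5]]
            raise ValueError(f"non-finite values in column(s): {names}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.values.copy(), list(self.sample_ids), list(self.feature_ids)
        )

    def with_values(self, values: np.ndarray) -> "FeatureMatrix":
        """Same identifiers, new values (shape must match)."""
        if values.shape != self.values.shape:
            raise ValueError("replacement values must keep the matrix shape")
        return FeatureMatrix(values, list(self.sample_ids), list(self.feature_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.feature_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))


@dataclass
class AbundanceTable:
    """A feature matrix together with a binary label per sample (1 = case)."""

    matrix: FeatureMatrix
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (self.matrix.n_samples,):
            raise ValueError("labels must have one entry per sample")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be binary (0 = control, 1 = case)")


@dataclass
class EngineeredDataset:
    """A derived matrix plus provenance of how it was built.

    ``column_origins`` tags every column as coming from the raw matrix
    (``raw``), the rank-then-normalize path (``pre``) or the
    normalize-then-rank path (``post``).
    """

    matrix: FeatureMatrix
    variant: str
    chain: ChainSpec | None
    column_origins: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.column_origins) != self.matrix.n_features:
            raise ValueError("column_origins must tag every column")
        bad = set(self.column_origins) - {"raw", "pre", "post"}
        if bad:
            raise ValueError(f"unknown origin tag(s): {sorted(bad)}")


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_table(path: str | Path, delimiter: str | None = None) -> AbundanceTable:
    """Read a sample-by-feature table with a final ``label`` column.

    The delimiter is inferred from the extension (``.csv`` -> comma,
    anything else -> tab) unless given explicitly.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter), index_col=0)
    if LABEL_COLUMN not in df.columns:
        raise ValueError(f"{path} has no '{LABEL_COLUMN}' column")
    labels = df[LABEL_COLUMN].to_numpy()
    feats = df.drop(columns=[LABEL_COLUMN])
    if feats.isna().any().any():
        bad = feats.columns[feats.isna().any()].tolist()[:5]
        raise ValueError(f"missing values in column(s): {bad}")
    return AbundanceTable(FeatureMatrix.from_frame(feats), labels)


def write_table(
    table: AbundanceTable | FeatureMatrix,
    path: str | Path,
    labels: Sequence[int] | None = None,
    delimiter: str | None = None,
) -> None:
    """Write a table in the same dialect ``read_table`` accepts."""
    path = Path(path)
    if isinstance(table, AbundanceTable):
        matrix, labels = table.matrix, table.labels
    else:
        matrix = table
    df = matrix.to_frame()
    if labels is not None:
        df[LABEL_COLUMN] = np.asarray(labels, dtype=int)
    df.to_csv(path, sep=_delimiter_for(path, delimiter), index_label="sample_id")
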