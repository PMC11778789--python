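"""Grid orchestration: chains x variants x feature selection on/off.

``run_grid`` evaluates every cell of the experimental grid on one
abundance table, producing a flat list of records that the reporting and
association analyses consume. Each record carries full provenance (chain,
variant, selection flag, seeds), the cross-validated metrics, the
distribution summary of the engineered matrix, and wall time
(informational only). A failing cell is recorded with its error and never
aborts the rest of the grid.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import AbundanceTable, ChainSpec, DEFAULT_METHODS, FeatureMatrix
from .evaluation import distribution_summary
from .feature_engineering import VARIANTS, build_variant, enumerate_chains
from .model import CVProtocol, DNNConfig, train_eval_cv
from .selection import RidgeImportanceSelector, apply_selection

__all__ = ["ExperimentGrid", "run_grid", "save_results", "load_results"]


@dataclass
class ExperimentGrid:
    """The axes of one experiment run."""

    methods: tuple[str, ...] = DEFAULT_METHODS
    chains: list[ChainSpec] | None = None  # None -> all 2^n - 1 chains
    variants: tuple[str, ...] = VARIANTS
    fs: str = "both"  # "on", "off" or "both"
    fs_threshold: float = 0.1
    fs_fallback_topk: int | None = 16
    dnn: DNNConfig = field(default_factory=DNNConfig)
    cv: CVProtocol = field(default_factory=CVProtocol)
    seed: int = 0

    def resolved_chains(self) -> list[ChainSpec]:
        if self.chains is not None:
            return list(self.chains)
        return enumerate_chains(list(self.methods))

    def fs_settings(self) -> list[bool]:
        if self.fs == "both":
            return [False, True]
        if self.fs == "on":
            return [True]
        if self.fs == "off":
            return [False]
        raise ValueError("fs must be 'on', 'off' or 'both'")


def _cells(grid: ExperimentGrid):
    """Grid cells in stable order; the chainless raw variant is deduplicated."""
    chains = grid.resolved_chains()
    for fs_on in grid.fs_settings():
        for variant in grid.variants:
            if variant == "raw":
                yield variant, None, fs_on
            else:
                for chain in chains:
                    yield variant, chain, fs_on


def run_grid(
    table: FeatureMatrix | AbundanceTable,
    labels: np.ndarray | None = None,
    grid: ExperimentGrid | None = None,
) -> list[dict]:
    """Evaluate every grid cell; one record per cell, errors recorded in place."""
    if isinstance(table, AbundanceTable):
        labels = table.labels
        table = table.matrix
    if labels is None:
        raise ValueError("labels are required")
    grid = grid or ExperimentGrid()
    records: list[dict] = []
    for variant, chain, fs_on in _cells(grid):
        rec = {
            "variant": variant,
            "chain": str(chain) if chain is not None else None,
            "fs": fs_on,
            "split_seed": grid.cv.seed,
            "weight_seed": grid.dnn.seed,
            "error": None,
        }
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                ds = build_variant(table, chain, variant)
                rec["n_features_engineered"] = ds.matrix.n_features
                if fs_on:
                    sel = RidgeImportanceSelector(
                        threshold=grid.fs_threshold,
                        fallback_topk=grid.fs_fallback_topk,
                        random_state=grid.seed,
                    )
                    sel.fit(ds.matrix.values, labels)
                    ds = apply_selection(ds, sel.selection_result())
                rec["n_features_used"] = ds.matrix.n_features
                dist = distribution_summary(ds.matrix)
                rec.update(dist.as_dict())
                res = train_eval_cv(ds, labels, cfg=grid.dnn, cv=grid.cv)
            rec.update(
                fold_aucs=res.fold_aucs,
                mean_auc=res.mean_auc,
                auc=res.auc,
                sensitivity=res.sensitivity,
                specificity=res.specificity,
                fpr=res.fpr,
                confusion=res.confusion,
                time_s=res.time_s,
            )
        except Exception as exc:  # partial-failure policy: record, continue
            rec["error"] = f"{type(exc).__name__}: {exc}"
        records.append(rec)
    return records


def save_results(
    records: list[dict], grid: ExperimentGrid, path: str | Path
) -> None:
    """Persist one run as a single JSON document (grid echo + records)."""
    doc = {
        "grid": {
            "methods": list(grid.methods),
            "chains": (
                [str(c) for c in grid.chains] if grid.chains is not None else "all"
            ),
            "variants": list(grid.variants),
            "fs": grid.fs,
            "fs_threshold": grid.fs_threshold,
            "epochs": grid.dnn.epochs,
            "batch_size": grid.dnn.batch_size,
            "k": grid.cv.k,
            "repeats": grid.cv.repeats,
            "seed": grid.seed,
        },
        "records": records,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def load_results(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
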