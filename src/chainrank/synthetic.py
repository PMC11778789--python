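"""Synthetic case/control compositional abundance tables.

Generates sample-by-feature relative-abundance tables with the statistical
pathologies of real gut-microbiome profiles — compositionality (rows sum
to 1), sparsity, and heavy-tailed feature abundances — plus a planted
subset of differentially abundant features distinguishing cases from
controls.

Generative model: base taxon proportions are drawn log-normally (heavy
tail), per-sample proportions are Dirichlet with concentration
``base_concentration`` around the class's expected composition
(overdispersion), counts are multinomial with a log-normally varying
library size, zero inflation thins entries to the target sparsity, and
counts are closed to relative abundances. In cases, the expected
proportions of the informative features are multiplied by
``exp(log_fold_change)`` before renormalization.

Two presets mirror the shapes of typical study cohorts:
``dataset1-like`` (112 samples x 324 features, 33 cases; an amplicon-scale
cohort) and ``dataset2-like`` (884 x 2031, 368 cases / 516 controls; a
shotgun-scale cohort).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .containers import AbundanceTable, FeatureMatrix

__all__ = ["SimConfig", "SimResult", "simulate", "monotone_distort", "preset"]


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults give a dataset1-like cohort."""

    n_samples: int = 112
    n_features: int = 324
    n_cases: int = 33
    n_informative: int = 10
    log_fold_change: float = 2.0
    sparsity: float = 0.6
    base_concentration: float = 50.0
    base_sigma: float = 2.0  # log-normal spread of base proportions
    library_size_mean: float = 50_000.0
    library_size_cv: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_cases < self.n_samples:
            raise ValueError("need 0 < n_cases < n_samples")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must be within [0, n_features]")
        if not 0 <= self.sparsity < 1:
            raise ValueError("sparsity must lie in [0, 1)")
        if self.base_concentration <= 0:
            raise ValueError("base_concentration must be positive")
        if self.library_size_mean < 100:
            raise ValueError("library_size_mean too small to be meaningful")


@dataclass
class SimResult:
    table: FeatureMatrix
    labels: np.ndarray
    informative_ids: list[str]
    config: SimConfig = field(repr=False, default=None)

    @property
    def informative_indices(self) -> np.ndarray:
        lookup = {f: j for j, f in enumerate(self.table.feature_ids)}
        return np.array([lookup[f] for f in self.informative_ids], dtype=int)

    def as_abundance_table(self) -> AbundanceTable:
        return AbundanceTable(self.table, self.labels)


PRESETS = {
    "dataset1-like": SimConfig(n_samples=112, n_features=324, n_cases=33),
    "dataset2-like": SimConfig(n_samples=884, n_features=2031, n_cases=368),
}


def preset(name: str, **overrides) -> SimConfig:
    """A named cohort-shaped configuration, optionally overridden."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; valid: {sorted(PRESETS)}")
    cfg = PRESETS[name]
    return replace(cfg, **overrides) if overrides else cfg


def simulate(cfg: SimConfig | None = None, **overrides) -> SimResult:
    """Draw one case/control cohort table; deterministic given the seed."""
    cfg = cfg or SimConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    rng = np.random.default_rng(cfg.seed)

    # heavy-tailed base composition shared by both classes
    base = rng.lognormal(mean=0.0, sigma=cfg.base_sigma, size=cfg.n_features)
    base /= base.sum()

    # plant effects on detectable taxa: the heavy log-normal tail makes many
    # features too rare to ever discriminate, so informative features are
    # drawn from the upper half of base abundance
    eligible = np.where(base >= np.median(base))[0]
    if cfg.n_informative > len(eligible):
        raise ValueError("n_informative exceeds the number of detectable features")
    informative = np.sort(
        rng.choice(eligible, size=cfg.n_informative, replace=False)
    )
    case_base = base.copy()
    case_base[informative] *= np.exp(cfg.log_fold_change)
    case_base /= case_base.sum()

    labels = np.zeros(cfg.n_samples, dtype=int)
    labels[: cfg.n_cases] = 1
    labels = labels[rng.permutation(cfg.n_samples)]

    # per-sample Dirichlet-multinomial counts
    sigma_lib = np.sqrt(np.log(1 + cfg.library_size_cv**2))
    mu_lib = np.log(cfg.library_size_mean) - sigma_lib**2 / 2
    counts = np.empty((cfg.n_samples, cfg.n_features))
    for i in range(cfg.n_samples):
        expected = case_base if labels[i] == 1 else base
        props = rng.dirichlet(expected * cfg.base_concentration)
        depth = max(100, int(np.round(rng.lognormal(mu_lib, sigma_lib))))
        counts[i] = rng.multinomial(depth, props)

    # zero-inflate toward the target overall sparsity
    zero_now = float(np.mean(counts == 0))
    if zero_now < cfg.sparsity:
        q = (cfg.sparsity - zero_now) / (1 - zero_now)
        counts *= rng.random(counts.shape) >= q
    row_tot = counts.sum(axis=1)
    if np.any(row_tot == 0):
        raise ValueError(
            "sparsity/effect combination produced an all-zero sample; "
            "lower sparsity or raise library_size_mean"
        )
    rel = counts / row_tot[:, None]

    fm = FeatureMatrix(
        rel,
        [f"S{i:04d}" for i in range(cfg.n_samples)],
        [f"F{j:04d}" for j in range(cfg.n_features)],
    )
    return SimResult(
        table=fm,
        labels=labels,
        informative_ids=[fm.feature_ids[j] for j in informative],
        config=cfg,
    )


def monotone_distort(
    table: FeatureMatrix | np.ndarray, family: str, seed: int = 0
) -> FeatureMatrix | np.ndarray:
    """Apply a random strictly increasing map per column.

    Families (all strictly increasing on non-negative data):
    ``power`` — x^g with g drawn in [0.5, 3]; ``log1p`` — log(1 + c x)
    with c in [0.5, 20]; ``affine`` — a x + b with a > 0; ``identity``.
    Per-column ranks are preserved exactly by construction.
    """
    values = table.values if isinstance(table, FeatureMatrix) else np.asarray(table, float)
    rng = np.random.default_rng(seed)
    p = values.shape[1]
    if family == "identity":
        out = values.copy()
    elif family == "power":
        if np.any(values < 0):
            raise ValueError("power distortion needs non-negative data")
        g = rng.uniform(0.5, 3.0, size=p)
        out = values**g
    elif family == "log1p":
        if np.any(values < 0):
            raise ValueError("log1p distortion needs non-negative data")
        c = rng.uniform(0.5, 20.0, size=p)
        out = np.log1p(c * values)
    elif family == "affine":
        a = rng.uniform(0.1, 5.0, size=p)
        b = rng.uniform(-1.0, 1.0, size=p)
        out = a * values + b
    else:
        raise ValueError(
            f"unknown family {family!r}; valid: power, log1p, affine, identity"
        )
    if isinstance(table, FeatureMatrix):
        return table.with_values(out)
    return out
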