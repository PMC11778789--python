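"""Dual-path feature generation and feature extension.

Two parallel paths derive new feature sets from a raw abundance table:

- **Post-Rank** — chained normalization of the raw matrix, then column-wise
  rank transformation;
- **Pre-Rank**  — column-wise rank transformation first, then chained
  normalization of the ranks.

Every chain starts from the pristine raw matrix (Post-Rank path) or the
pristine rank-transformed matrix (Pre-Rank path). The six dataset variants
combine these paths with the raw features by horizontal merging (feature
extension): ``raw``, ``pre_rank``, ``post_rank``, ``raw_and_pre``,
``raw_and_post``, ``pre_and_post``.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .containers import ChainSpec, EngineeredDataset, FeatureMatrix
from .transforms import apply_chain, rank_transform

VARIANTS = (
    "raw",
    "pre_rank",
    "post_rank",
    "raw_and_pre",
    "raw_and_post",
    "pre_and_post",
)

_ORIGIN_PREFIX = {"raw": "raw::", "pre": "pre::", "post": "post::"}


def enumerate_chains(methods: list[str] | tuple[str, ...]) -> list[ChainSpec]:
    """All non-empty subsets of ``methods``, each ordered by the input order.

    Enumeration is by subset size, then lexicographically on input
    positions, yielding ``2**n - 1`` chains for ``n`` methods.
    """
    methods = list(methods)
    if not 1 <= len(methods) <= 8:
        raise ValueError("between 1 and 8 methods are supported")
    if len(set(methods)) != len(methods):
        raise ValueError(f"duplicate method names: {methods}")
    chains = []
    for r in range(1, len(methods) + 1):
        for combo in combinations(methods, r):
            chains.append(ChainSpec(combo))
    return chains


def post_rank_features(
    raw: FeatureMatrix, chain: ChainSpec | list[str] | str
) -> FeatureMatrix:
    """Normalize the raw matrix through the chain, then rank each column."""
    return rank_transform(apply_chain(raw, chain))


def pre_rank_features(
    raw: FeatureMatrix, chain: ChainSpec | list[str] | str
) -> FeatureMatrix:
    """Rank each raw column, then normalize the ranks through the chain."""
    return apply_chain(rank_transform(raw), chain)


def merge_features(
    parts: list[FeatureMatrix],
    tags: list[str],
    variant: str = "merged",
    chain: ChainSpec | None = None,
) -> EngineeredDataset:
    """Horizontally concatenate feature sets over identical samples.

    Feature IDs are prefixed with their origin tag (``raw::``, ``pre::``,
    ``post::``) so merged IDs stay unique and traceable.
    """
    if not parts:
        raise ValueError("nothing to merge")
    if len(parts) != len(tags):
        raise ValueError("one origin tag per part is required")
    ref = parts[0].sample_ids
    for part in parts[1:]:
        if part.sample_ids != ref:
            offending = next(
                (a for a, b in zip(ref, part.sample_ids) if a != b),
                f"length {len(ref)} vs {len(part.sample_ids)}",
            )
            raise ValueError(
                f"sample IDs differ between merged parts (first mismatch: {offending})"
            )
    values = np.hstack([p.values for p in parts])
    feature_ids: list[str] = []
    origins: list[str] = []
    for part, tag in zip(parts, tags):
        prefix = _ORIGIN_PREFIX[tag]
        feature_ids.extend(prefix + f for f in part.feature_ids)
        origins.extend([tag] * part.n_features)
    matrix = FeatureMatrix(values, list(ref), feature_ids)
    return EngineeredDataset(matrix, variant, chain, origins)


def build_variant(
    raw: FeatureMatrix,
    chain: ChainSpec | list[str] | str | None,
    variant: str,
) -> EngineeredDataset:
    """Build one of the six dataset variants from the raw matrix."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; valid: {VARIANTS}")
    if variant == "raw":
        return merge_features([raw], ["raw"], variant, None)
    if chain is None:
        raise ValueError(f"variant {variant!r} requires a chain")
    if isinstance(chain, str):
        chain = ChainSpec.parse(chain)
    elif not isinstance(chain, ChainSpec):
        chain = ChainSpec(tuple(chain))
    if variant == "pre_rank":
        return merge_features([pre_rank_features(raw, chain)], ["pre"], variant, chain)
    if variant == "post_rank":
        return merge_features(
            [post_rank_features(raw, chain)], ["post"], variant, chain
        )
    if variant == "raw_and_pre":
        return merge_features(
            [raw, pre_rank_features(raw, chain)], ["raw", "pre"], variant, chain
        )
    if variant == "raw_and_post":
        return merge_features(
            [raw, post_rank_features(raw, chain)], ["raw", "post"], variant, chain
        )
    # pre_and_post
    return merge_features(
        [pre_rank_features(raw, chain), post_rank_features(raw, chain)],
        ["pre", "post"],
        variant,
        chain,
    )
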