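"""Site/genotype quality exclusions and the variant-cluster filter.

A variant is excluded when it sits in a dense local cluster (>= 3 variant
positions inside any 10-bp genomic window by default — a signature of
alignment artefacts), or when its site mapping quality, read depth or
genotype quality falls below threshold. Thresholds are strict "less than"
exclusions: a value exactly at the threshold is retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .formats import ContractError, FilterParams, Variant


@dataclass(frozen=True)
class RemovedVariant:
    """A removed variant with the reason tag for the removal."""

    variant: Variant
    reason: str  # "cluster" | "depth" | "mq" | "gq"


def _check_sorted(variants: Sequence[Variant]) -> None:
    keys = [(v.chrom, v.pos) for v in variants]
    if keys != sorted(keys):
        raise ContractError("variants must be sorted by (chrom, pos)")


def filter_cluster(
    variants: Sequence[Variant],
    window_bp: int = 10,
    min_count: int = 3,
) -> tuple[list[Variant], list[RemovedVariant]]:
    """Remove variants lying in any ``window_bp`` window with >= ``min_count``
    variant positions on the same chromosome.

    A window spans positions x .. x+window_bp-1; a variant is removed iff it
    belongs to at least one qualifying window (not only maximal clusters).
    The relative input order of kept and removed variants is preserved.
    """
    _check_sorted(variants)
    removed_idx: set[int] = set()
    # any qualifying window can be shifted left until its leftmost variant
    # sits at the window start, so windows anchored at variants suffice
    by_chrom: dict[str, list[int]] = {}
    for i, v in enumerate(variants):
        by_chrom.setdefault(v.chrom, []).append(i)
    for idxs in by_chrom.values():
        positions = [variants[i].pos for i in idxs]
        n = len(idxs)
        right = 0
        for left in range(n):
            if right < left:
                right = left
            while right + 1 < n and positions[right + 1] <= positions[left] + window_bp - 1:
                right += 1
            # distinct positions matter (split multiallelics share a POS)
            window = {positions[j] for j in range(left, right + 1)}
            if len(window) >= min_count:
                removed_idx.update(idxs[left : right + 1])
    kept = [v for i, v in enumerate(variants) if i not in removed_idx]
    removed = [
        RemovedVariant(variant=v, reason="cluster")
        for i, v in enumerate(variants)
        if i in removed_idx
    ]
    return kept, removed


def quality_failure(
    variant: Variant,
    params: FilterParams,
    sample_ids: Sequence[str] | None = None,
) -> str | None:
    """Reason tag for the first failed quality criterion, or None if it passes.

    Missing MQ/DP/GQ fields count as failures (conservative). Missing
    genotypes are skipped: they carry no call to judge. When ``sample_ids``
    is given, only those samples' genotypes are judged (per-family
    filtering on a merged file).
    """
    if variant.site_mq is None or variant.site_mq < params.min_site_mq:
        return "mq"
    for g in variant.genotypes:
        if sample_ids is not None and g.sample_id not in sample_ids:
            continue
        if g.is_missing:
            continue
        if g.depth is None or g.depth < params.min_depth:
            return "depth"
        if g.gq is None or g.gq < params.min_gq:
            return "gq"
    return None


def filter_quality(
    variants: Sequence[Variant],
    params: FilterParams,
    sample_ids: Sequence[str] | None = None,
) -> tuple[list[Variant], list[RemovedVariant]]:
    """Keep variants whose site MQ and every judged genotype's DP/GQ pass."""
    kept: list[Variant] = []
    removed: list[RemovedVariant] = []
    for v in variants:
        reason = quality_failure(v, params, sample_ids)
        if reason is None:
            kept.append(v)
        else:
            removed.append(RemovedVariant(variant=v, reason=reason))
    return kept, removed
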