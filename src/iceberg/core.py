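"""The aggregation decision rule producing the final exhaustive peak set.

Pipeline: equal-depth downsampling of every replicate into k splits ->
pooling each split into an aggregate -> calling each aggregate against
the pooled IgG at q < 0.05 -> keeping regions called in at least 2 of
the k aggregates (exact coverage segments, merged) -> dropping
candidates with no support from any individual replicate called at the
relaxed p < 0.01 stringency against the downsampled IgG.

The majority step finds everything the pooled evidence supports, even
binding events too rare to reach significance in any one replicate; the
relaxed support filter removes pooling artifacts that no single
replicate shows any evidence for.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .aggregation import AggregationPlan, aggregate_control, build_splits, \
    pool_fragments
from .calling import PeakCallParams, ScoredPeakSet, call_peaks
from .fragments import FragmentSet
from .genome import GenomeModel
from .intervals import (
    IntervalError,
    IntervalSet,
    overlap_mask,
    overlap_matrix,
    regions_at_least,
)

__all__ = ["IcebergConfig", "IcebergResult", "majority_regions", "support_filter",
           "run_iceberg"]

logger = logging.getLogger("iceberg")


@dataclass(frozen=True)
class IcebergConfig:
    """Thresholds and geometry of the aggregation decision rule.

    ``igg_downsample=None`` means "min(5,000,000, pooled IgG depth)":
    the individual-replicate control is capped at 5 million fragments
    but never requested beyond what the pooled controls contain. An
    explicit integer is strict and errors if unattainable.
    """

    aggregate_mode: str = "q"
    aggregate_cutoff: float = 0.05
    support_mode: str = "p"
    support_cutoff: float = 0.01
    majority_min: int = 2
    n_splits: int = 3
    depth: int | None = None  # None -> min replicate depth
    igg_downsample: int | None = None
    caller_params: PeakCallParams = field(default_factory=PeakCallParams)

    def __post_init__(self) -> None:
        if not 1 <= self.majority_min <= self.n_splits:
            raise IntervalError(
                f"majority_min must be in [1, n_splits={self.n_splits}], "
                f"got {self.majority_min}"
            )
        for mode, cutoff in (
            (self.aggregate_mode, self.aggregate_cutoff),
            (self.support_mode, self.support_cutoff),
        ):
            if mode not in ("q", "p") or not 0 < cutoff < 1:
                raise IntervalError(f"invalid threshold ({mode!r}, {cutoff})")


@dataclass
class IcebergResult:
    """Final peak set with full provenance.

    ``n_aggregates[i]`` / ``n_support[i]`` count, for final peak *i* (in
    sorted order), the aggregates that called it and the replicates
    supporting it at the relaxed stringency. Invariant: every final
    peak has n_aggregates >= majority_min and n_support >= 1.
    """

    peaks: IntervalSet
    n_aggregates: np.ndarray
    n_support: np.ndarray
    config: IcebergConfig
    plan: AggregationPlan
    aggregate_calls: list[ScoredPeakSet]
    replicate_calls: list[ScoredPeakSet]  # relaxed-stringency, carries p and q
    majority: IntervalSet
    seed: int


def majority_regions(
    aggregate_peaksets: Sequence[IntervalSet], majority_min: int
) -> IntervalSet:
    """Regions called in at least ``majority_min`` of the aggregate sets.

    Candidate coordinates are the exact >= majority_min coverage
    segments of the union-breakpoint segmentation, merged gap 0 — not
    any single aggregate's peak boundaries.
    """
    k = len(aggregate_peaksets)
    if not 1 <= majority_min <= k:
        raise IntervalError(f"majority_min must be in [1, {k}], got {majority_min}")
    matrix = overlap_matrix(list(aggregate_peaksets))
    return regions_at_least(matrix, majority_min)


def support_filter(
    candidates: IntervalSet, relaxed_replicate_sets: Sequence[IntervalSet]
) -> IntervalSet:
    """Drop candidates with no >= 1 bp overlap in any relaxed replicate set."""
    if not relaxed_replicate_sets:
        return IntervalSet([], genome=candidates.genome)
    support = np.zeros(len(candidates), dtype=bool)
    for rep_set in relaxed_replicate_sets:
        support |= overlap_mask(candidates, rep_set)
    kept = [iv for iv, ok in zip(candidates, support) if ok]
    return IntervalSet(kept, genome=candidates.genome)


def run_iceberg(
    replicates: Sequence[FragmentSet],
    igg_replicates: Sequence[FragmentSet],
    genome: GenomeModel,
    config: IcebergConfig | None = None,
    seed: int = 0,
) -> IcebergResult:
    """Run the full aggregation pipeline; deterministic given (inputs, seed)."""
    if config is None:
        config = IcebergConfig()
    if not replicates:
        raise IntervalError("need at least one treatment replicate")
    if not igg_replicates:
        raise IntervalError("need at least one IgG control replicate")
    if len(replicates) == 1:
        logger.warning(
            "only one replicate: aggregates are resamples of a single replicate "
            "and the majority rule loses its meaning"
        )
    if config.n_splits < 3:
        logger.warning("n_splits=%d < 3: majority voting is weakened", config.n_splits)

    depth = config.depth if config.depth is not None else min(r.depth for r in replicates)
    plan = AggregationPlan(
        n_replicates=len(replicates),
        depth=depth,
        n_splits=config.n_splits,
        seed=seed,
        replicate_ids=tuple(
            r.replicate_id or f"rep{i + 1}" for i, r in enumerate(replicates)
        ),
    )
    splits = build_splits(replicates, plan)
    aggregates = [
        pool_fragments(row, label=f"aggregate_{i + 1}") for i, row in enumerate(splits)
    ]

    igg_pool = pool_fragments(list(igg_replicates), label="igg_pool")
    downsample_to = config.igg_downsample
    if downsample_to is None:
        downsample_to = min(5_000_000, igg_pool.depth)
    igg_aggregate, igg_individual = aggregate_control(
        list(igg_replicates), downsample_to=downsample_to, seed=seed
    )

    agg_params = PeakCallParams(
        **{
            **_params_dict(config.caller_params),
            "threshold_mode": config.aggregate_mode,
            "threshold": config.aggregate_cutoff,
        }
    )
    logger.info("calling %d aggregates at %s<%g", len(aggregates),
                config.aggregate_mode, config.aggregate_cutoff)
    aggregate_calls = [
        call_peaks(agg, igg_aggregate, genome, agg_params) for agg in aggregates
    ]

    majority = majority_regions(
        [c.intervals(genome) for c in aggregate_calls], config.majority_min
    )

    rel_params = PeakCallParams(
        **{
            **_params_dict(config.caller_params),
            "threshold_mode": config.support_mode,
            "threshold": config.support_cutoff,
        }
    )
    logger.info("calling %d replicates at %s<%g (support filter)",
                len(replicates), config.support_mode, config.support_cutoff)
    replicate_calls = [
        call_peaks(rep, igg_individual, genome, rel_params) for rep in replicates
    ]

    final = support_filter(majority, [c.intervals(genome) for c in replicate_calls])

    n_agg = np.zeros(len(final), dtype=int)
    for call in aggregate_calls:
        n_agg += overlap_mask(final, call.intervals(genome)).astype(int)
    n_sup = np.zeros(len(final), dtype=int)
    for call in replicate_calls:
        n_sup += overlap_mask(final, call.intervals(genome)).astype(int)

    return IcebergResult(
        peaks=final,
        n_aggregates=n_agg,
        n_support=n_sup,
        config=config,
        plan=plan,
        aggregate_calls=aggregate_calls,
        replicate_calls=replicate_calls,
        majority=majority,
        seed=seed,
    )


def _params_dict(params: PeakCallParams) -> dict:
    return {
        "window": params.window,
        "step": params.step,
        "local_scales": params.local_scales,
        "merge_gap": params.merge_gap,
        "min_length": params.min_length,
        "pseudocount": params.pseudocount,
    }
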