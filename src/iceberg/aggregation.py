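"""Equal-depth downsampling, splits, aggregate pooling, and build curves.

The aggregation scheme: every replicate is downsampled to the common
depth *m* (the depth of the smallest replicate), independently *k*
times ("splits", default 3), and each split's downsamples are pooled
into one aggregate. Splits are independent random samples, not disjoint
partitions — the smallest replicate cannot be partitioned k ways at
depth m, so its content is shared across splits by construction.

Every random draw is seeded by a child seed derived deterministically
from the plan seed and the (replicate, split, purpose) coordinates, so
a run is reproducible fragment-for-fragment from its seed alone.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .calling import PeakCallParams, call_peaks
from .fragments import FragmentSet
from .genome import GenomeModel

__all__ = [
    "AggregationPlan",
    "BuildCurve",
    "AggregationError",
    "child_seed",
    "downsample_fragments",
    "build_splits",
    "pool_fragments",
    "pooled_depth",
    "aggregate_control",
    "build_curve",
]


class AggregationError(ValueError):
    pass


def child_seed(seed: int, *parts) -> int:
    """Stable, platform-independent child seed below 2**31.

    Hashes the parent seed together with arbitrary string/int
    coordinates (replicate id, split index, purpose tag) so that every
    consumer of randomness in a run draws from its own stream.
    """
    key = ":".join([str(seed), *[str(p) for p in parts]])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class AggregationPlan:
    """Downsampling plan: n replicates x k splits at common depth m."""

    n_replicates: int
    depth: int
    n_splits: int = 3
    seed: int = 0
    replicate_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_replicates < 1 or self.n_splits < 1 or self.depth < 1:
            raise AggregationError("n_replicates, n_splits and depth must be >= 1")
        if not self.replicate_ids:
            object.__setattr__(
                self,
                "replicate_ids",
                tuple(f"rep{i + 1}" for i in range(self.n_replicates)),
            )
        if len(self.replicate_ids) != self.n_replicates:
            raise AggregationError("replicate_ids length must equal n_replicates")

    @property
    def aggregate_depth(self) -> int:
        """Depth of each pooled aggregate: n x m fragments."""
        return self.n_replicates * self.depth


@dataclass
class BuildCurve:
    """Peak counts of a growing aggregate, one point per added replicate."""

    order_id: int
    split_id: int
    points: list[tuple[int, int]]  # (replicates added, peak count)

    def __post_init__(self) -> None:
        xs = [x for x, _ in self.points]
        if xs != sorted(set(xs)) or (xs and xs[0] != 1):
            raise AggregationError("points must have strictly increasing x from 1")
        if any(y < 0 for _, y in self.points):
            raise AggregationError("peak counts must be >= 0")


def downsample_fragments(frags: FragmentSet, m: int, seed: int) -> FragmentSet:
    """Uniform sample of exactly ``m`` fragments without replacement.

    Implemented as a seeded shuffle of fragment indices, taking the
    first ``m`` — the same fragments come back for the same seed on any
    platform. Metadata is preserved.
    """
    if m > frags.depth:
        raise AggregationError(
            f"cannot downsample replicate {frags.replicate_id!r} to {m}: "
            f"depth is only {frags.depth}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.permutation(frags.depth)[:m]
    return frags.take(np.sort(idx))


def build_splits(
    replicates: Sequence[FragmentSet], plan: AggregationPlan
) -> list[list[FragmentSet]]:
    """k independent equal-depth downsamples of every replicate.

    Returns ``splits[split_index][replicate_index]``. Each
    (replicate, split) pair draws from its own child seed; a replicate
    whose depth equals the plan depth contributes identical content to
    every split.
    """
    if len(replicates) != plan.n_replicates:
        raise AggregationError(
            f"plan expects {plan.n_replicates} replicates, got {len(replicates)}"
        )
    splits: list[list[FragmentSet]] = []
    for split_id in range(plan.n_splits):
        row = []
        for rep_id, frags in zip(plan.replicate_ids, replicates):
            seed = child_seed(plan.seed, rep_id, split_id, "downsample")
            row.append(downsample_fragments(frags, plan.depth, seed))
        splits.append(row)
    return splits


def pool_fragments(sets: Sequence[FragmentSet], label: str = "pool") -> FragmentSet:
    """Multiset union of fragment sets; depth is the sum of input depths."""
    if not sets:
        raise AggregationError("cannot pool an empty list of fragment sets")
    names: list[str] = []
    rank: dict[str, int] = {}
    remapped_codes = []
    for fs in sets:
        mapping = np.empty(len(fs.chrom_names), dtype=np.int32)
        for i, name in enumerate(fs.chrom_names):
            if name not in rank:
                rank[name] = len(names)
                names.append(name)
            mapping[i] = rank[name]
        remapped_codes.append(
            mapping[fs.chrom_codes] if fs.depth else np.empty(0, dtype=np.int32)
        )
    return FragmentSet(
        names,
        np.concatenate(remapped_codes),
        np.concatenate([fs.coords for fs in sets]),
        target=sets[0].target,
        replicate_id=label,
    )


def pooled_depth(depths: Sequence[int]) -> int:
    """Plan-level accounting of a pool's depth without materializing it."""
    return int(sum(int(d) for d in depths))


def aggregate_control(
    igg_replicates: Sequence[FragmentSet],
    downsample_to: int | None = 5_000_000,
    seed: int = 0,
) -> tuple[FragmentSet, FragmentSet]:
    """Pool the IgG controls; return (full aggregate, individual-call control).

    The full pooled IgG is the control for aggregate peak calls. For
    individual-replicate calls it is downsampled (default 5 million
    fragments) so single replicates are not tested against a control
    orders of magnitude deeper; ``downsample_to=None`` passes the full
    aggregate through.
    """
    if not igg_replicates:
        raise AggregationError("need at least one IgG control replicate")
    aggregate = pool_fragments(igg_replicates, label="igg_aggregate")
    if downsample_to is None or downsample_to >= aggregate.depth:
        if downsample_to is not None and downsample_to > aggregate.depth:
            raise AggregationError(
                f"cannot downsample pooled IgG ({aggregate.depth} fragments) "
                f"to {downsample_to}"
            )
        individual = aggregate
    else:
        individual = downsample_fragments(
            aggregate, downsample_to, child_seed(seed, "igg", "downsample")
        )
        individual.replicate_id = "igg_individual_control"
    return aggregate, individual


def build_curve(
    replicates: Sequence[FragmentSet],
    igg_aggregate: FragmentSet | None,
    genome: GenomeModel,
    plan: AggregationPlan,
    params: PeakCallParams | None = None,
    n_orders: int = 5,
    peak_counter: Callable[[FragmentSet], int] | None = None,
) -> list[BuildCurve]:
    """Peak-discovery curves: peak count after each replicate addition.

    For each of ``n_orders`` seeded random replicate orders and each of
    the plan's k splits, replicates' downsamples are pooled cumulatively
    and peaks are called after every addition (default: the built-in
    caller at q < 0.05 against the pooled IgG). Returns
    ``n_orders x k`` curves.
    """
    if params is None:
        params = PeakCallParams(threshold_mode="q", threshold=0.05)
    if peak_counter is None:
        def peak_counter(pool: FragmentSet) -> int:
            return len(call_peaks(pool, igg_aggregate, genome, params))

    splits = build_splits(replicates, plan)
    curves: list[BuildCurve] = []
    n = plan.n_replicates
    for order_id in range(1, n_orders + 1):
        rng = np.random.default_rng(child_seed(plan.seed, "order", order_id))
        order = rng.permutation(n)
        for split_id, row in enumerate(splits, start=1):
            points = []
            pool: FragmentSet | None = None
            for x, rep_idx in enumerate(order, start=1):
                nxt = row[rep_idx]
                pool = nxt if pool is None else pool_fragments([pool, nxt])
                points.append((x, peak_counter(pool)))
            curves.append(BuildCurve(order_id=order_id, split_id=split_id, points=points))
    return curves
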