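"""Replicate-level analytics: decay curves, concordance, detection
frequency, probability groups, the rarity ladder, and FrIP.

"Detection probability" here is empirical: the fraction of individual
replicates in which a final peak is independently called at standard
stringency (q < 0.05). Peaks are binned into probability groups by that
fraction; the USR group ("undetectable in single replicates") holds
final peaks never called in any individual replicate at q < 0.05 —
they exist in the final set only through the aggregates plus relaxed
support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fragments import FragmentSet
from .intervals import (
    IntervalError,
    IntervalSet,
    _merge_arrays,
    _overlap_mask_one_chrom,
    overlap_mask,
    overlap_matrix,
    regions_at_least,
)

__all__ = [
    "DecayCurve",
    "ProbabilityAnnotation",
    "RarityLadder",
    "decay_curve",
    "concordance",
    "detection_frequency",
    "assign_probability_groups",
    "group_labels",
    "peaks_by_group",
    "rarity_ladder",
    "frip",
]

logger = logging.getLogger("iceberg")

USR_LABEL = "USR"

# right-closed percentage bins for detection-probability groups
_PCT_BINS = [(0, 20), (20, 40), (40, 60), (60, 80), (80, 100)]


@dataclass
class DecayCurve:
    """Region counts called in at least / exactly x of n datasets.

    ``at_least[x-1]`` counts merged regions covered by >= x inputs;
    ``exactly`` is the successive difference of those counts (the
    count-subtraction definition), clipped at zero when merging fuses
    regions and makes a difference negative.
    """

    n_sets: int
    at_least: list[int]
    exactly: list[int]
    n_clipped: int = 0


@dataclass(frozen=True)
class ProbabilityAnnotation:
    strict_count: int
    group: str


@dataclass
class RarityLadder:
    """Nested tiers of ever-rarer final peaks.

    tier1: never called in a single replicate at q < 0.05 (USR);
    tier2: tier1 peaks also undetected at p < 0.001;
    tier3: tier2 peaks called fewer than 5 times at p < 0.01;
    tier4: tier3 peaks called exactly once at p < 0.01.
    """

    usr_q05: IntervalSet
    undetectable_p001: IntervalSet
    lt5_at_p01: IntervalSet
    exactly1_at_p01: IntervalSet

    @property
    def counts(self) -> tuple[int, int, int, int]:
        return (
            len(self.usr_q05),
            len(self.undetectable_p001),
            len(self.lt5_at_p01),
            len(self.exactly1_at_p01),
        )


def decay_curve(peak_sets: Sequence[IntervalSet]) -> DecayCurve:
    """Counts of merged regions called in at least / exactly x datasets."""
    n = len(peak_sets)
    if n < 1:
        raise IntervalError("decay_curve needs at least one peak set")
    matrix = overlap_matrix(list(peak_sets))
    at_least = [regions_at_least(matrix, x).count for x in range(1, n + 1)]
    exactly: list[int] = []
    n_clipped = 0
    for x in range(n):
        nxt = at_least[x + 1] if x + 1 < n else 0
        diff = at_least[x] - nxt
        if diff < 0:
            n_clipped += 1
            logger.warning(
                "exactly[%d] = %d clipped to 0 (region merging fused counts)",
                x + 1,
                diff,
            )
            diff = 0
        exactly.append(diff)
    return DecayCurve(n_sets=n, at_least=at_least, exactly=exactly, n_clipped=n_clipped)


def concordance(peak_sets: Sequence[IntervalSet]) -> tuple[IntervalSet, float | None]:
    """Regions called in every input, as a percentage of all called regions."""
    n = len(peak_sets)
    if n < 2:
        raise IntervalError("concordance needs at least two peak sets")
    matrix = overlap_matrix(list(peak_sets))
    concordant = regions_at_least(matrix, n)
    total = regions_at_least(matrix, 1).count
    percent = 100.0 * concordant.count / total if total > 0 else None
    return concordant, percent


def detection_frequency(
    iceberg_peaks: IntervalSet, strict_replicate_sets: Sequence[IntervalSet]
) -> np.ndarray:
    """Per-peak count of replicates whose strict set overlaps it (>= 1 bp)."""
    counts = np.zeros(len(iceberg_peaks), dtype=int)
    for rep_set in strict_replicate_sets:
        counts += overlap_mask(iceberg_peaks, rep_set).astype(int)
    return counts


def _group_label(count: int, n: int) -> str:
    if count == 0:
        return USR_LABEL
    pct = 100.0 * count / n
    for lo, hi in _PCT_BINS:
        if lo < pct <= hi:
            lo_count = int(np.floor(n * lo / 100)) + 1
            hi_count = int(np.floor(n * hi / 100))
            pct_label = "≤20%" if lo == 0 else f"{lo + 1}–{hi}%"
            return f"{lo_count}–{hi_count} ({pct_label})"
    raise IntervalError(f"count {count} outside [0, n={n}]")  # pragma: no cover


def group_labels(n: int) -> list[str]:
    """All group labels for n replicates, rarest first (USR, then bins)."""
    labels = [USR_LABEL]
    for lo, hi in _PCT_BINS:
        lo_count = int(np.floor(n * lo / 100)) + 1
        hi_count = int(np.floor(n * hi / 100))
        if hi_count >= lo_count:
            labels.append(_group_label(lo_count, n))
    return labels


def assign_probability_groups(
    counts: Sequence[int], n: int
) -> list[ProbabilityAnnotation]:
    """Bin per-peak strict detection counts into probability groups.

    Zero is the USR group; positive counts fall into right-closed
    percentage bins of count/n ((0,20], (20,40], ...), whose labels
    carry both the count range at this n and the percentage band.
    """
    out = []
    for count in counts:
        count = int(count)
        if not 0 <= count <= n:
            raise IntervalError(f"detection count {count} outside [0, n={n}]")
        out.append(ProbabilityAnnotation(strict_count=count, group=_group_label(count, n)))
    return out


def peaks_by_group(
    iceberg_peaks: IntervalSet, annotations: Sequence[ProbabilityAnnotation]
) -> dict[str, IntervalSet]:
    """Partition final peaks into their probability groups (disjoint)."""
    if len(annotations) != len(iceberg_peaks):
        raise IntervalError("one annotation per peak required")
    buckets: dict[str, list] = {}
    for iv, ann in zip(iceberg_peaks, annotations):
        buckets.setdefault(ann.group, []).append(iv)
    return {
        group: IntervalSet(ivs, genome=iceberg_peaks.genome)
        for group, ivs in buckets.items()
    }


def rarity_ladder(
    iceberg_peaks: IntervalSet,
    strict_sets: Sequence[IntervalSet],
    p001_sets: Sequence[IntervalSet],
    p01_sets: Sequence[IntervalSet],
) -> RarityLadder:
    """Progressively relax stringency to isolate the rarest final peaks."""
    q05 = detection_frequency(iceberg_peaks, strict_sets)
    p001 = detection_frequency(iceberg_peaks, p001_sets)
    p01 = detection_frequency(iceberg_peaks, p01_sets)
    genome = iceberg_peaks.genome

    tier1 = q05 == 0
    tier2 = tier1 & (p001 == 0)
    tier3 = tier2 & (p01 < 5)
    tier4 = tier3 & (p01 == 1)

    def subset(mask: np.ndarray) -> IntervalSet:
        return IntervalSet(
            [iv for iv, ok in zip(iceberg_peaks, mask) if ok], genome=genome
        )

    return RarityLadder(
        usr_q05=subset(tier1),
        undetectable_p001=subset(tier2),
        lt5_at_p01=subset(tier3),
        exactly1_at_p01=subset(tier4),
    )


def frip(frags: FragmentSet, peaks: IntervalSet) -> float:
    """Fraction of fragments overlapping (>= 1 bp) any peak, in [0, 1]."""
    if frags.depth == 0:
        raise IntervalError("FrIP undefined for a zero-depth fragment set")
    if len(peaks) == 0:
        return 0.0
    merged = {c: _merge_arrays(a, 0) for c, a in peaks.by_chrom().items()}
    n_in = 0
    for chrom, arr in frags.by_chrom().items():
        sub = merged.get(chrom)
        if sub is None:
            continue
        n_in += int(_overlap_mask_one_chrom(arr, sub).sum())
    return n_in / frags.depth
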