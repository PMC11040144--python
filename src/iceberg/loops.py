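"""Chromatin-loop (BEDPE) ingestion, filtering, and peak-anchored
statistics per detection-probability group.

A loop is a pair of same-chromosome anchor intervals with per-replicate
ligation counts. Loop size is the linear genomic span from the start of
the first anchor to the end of the second; loop strength is the mean of
the replicate counts. Loops are assigned to a probability group when at
least one anchor overlaps (>= 1 bp) a peak of that group — a loop whose
two anchors hit peaks of different groups counts in both.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .intervals import (
    GenomicInterval,
    IntervalError,
    IntervalSet,
    overlap_mask,
)

__all__ = ["Loop", "GroupLoopStats", "LoopStats", "read_bedpe", "filter_loops",
           "match_replicate_loops", "peak_anchored_stats"]

logger = logging.getLogger("iceberg")


@dataclass(frozen=True)
class Loop:
    anchor1: GenomicInterval
    anchor2: GenomicInterval
    counts: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.anchor1.chrom != self.anchor2.chrom:
            raise IntervalError("loop anchors must share a chromosome")
        if (self.anchor1.start, self.anchor1.end) > (
            self.anchor2.start,
            self.anchor2.end,
        ):
            # normalize anchor order along the chromosome
            first, second = self.anchor2, self.anchor1
            object.__setattr__(self, "anchor1", first)
            object.__setattr__(self, "anchor2", second)
        if self.size <= 0:
            raise IntervalError("loop has non-positive size")

    @property
    def size(self) -> int:
        """Linear genomic span: anchor2.end - anchor1.start."""
        return self.anchor2.end - self.anchor1.start

    @property
    def strength(self) -> float:
        """Mean of the per-replicate loop counts."""
        if not self.counts:
            raise IntervalError("loop carries no counts")
        return sum(self.counts) / len(self.counts)


@dataclass
class GroupLoopStats:
    group: str
    n_loops: int
    n_peaks: int
    loops_per_peak: float
    percent_peaks_in_loops: float
    log10_sizes: list[float]
    strengths: list[float]


@dataclass
class LoopStats:
    groups: dict[str, GroupLoopStats]


def read_bedpe(
    path: str | Path, count_cols: Sequence[int] | None = None
) -> list[Loop]:
    """Parse a BEDPE file into loops.

    The first six columns are chrom1,start1,end1,chrom2,start2,end2;
    ``count_cols`` gives the 0-based indices of per-replicate count
    columns. Anchors are normalized into chromosome order;
    inter-chromosomal rows are skipped (their number is logged).
    Malformed rows raise with the line number.
    """
    path = Path(path)
    loops: list[Loop] = []
    n_interchrom = 0
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise IntervalError(f"{path}:{lineno}: expected >= 6 columns")
            try:
                a1 = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                a2 = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
                a1.validate()
                a2.validate()
                counts = tuple(
                    float(fields[i]) for i in (count_cols or ())
                )
            except (ValueError, IndexError, IntervalError) as exc:
                raise IntervalError(f"{path}:{lineno}: {exc}") from None
            if a1.chrom != a2.chrom:
                n_interchrom += 1
                continue
            loops.append(Loop(anchor1=a1, anchor2=a2, counts=counts))
    if n_interchrom:
        logger.info("%s: skipped %d inter-chromosomal rows", path, n_interchrom)
    return loops


def filter_loops(
    loops: Sequence[Loop],
    require_both_replicates: bool = True,
    min_size: int = 5000,
    min_mean_count: float = 2.0,
) -> list[Loop]:
    """Apply the standard loop filters.

    Keeps loops (i) with a positive count in every replicate when
    ``require_both_replicates`` (presence operationalized as
    count > 0), (ii) strictly larger than ``min_size``, and (iii) with
    mean count >= ``min_mean_count``.
    """
    kept = []
    for loop in loops:
        if require_both_replicates:
            if not loop.counts or any(c <= 0 for c in loop.counts):
                continue
        if loop.size <= min_size:
            continue
        if loop.counts and loop.strength < min_mean_count:
            continue
        if not loop.counts and min_mean_count > 0:
            continue
        kept.append(loop)
    return kept


def match_replicate_loops(
    loops_a: Sequence[Loop], loops_b: Sequence[Loop]
) -> list[Loop]:
    """Match loops across two per-replicate files by anchor overlap.

    For loop callers that emit one file per biological replicate with
    no joint count columns, "present in both replicates" is decided by
    geometry: a loop of the first replicate is kept when some loop of
    the second overlaps it on *both* anchors (>= 1 bp each). The kept
    loop's counts are the concatenation of the two partners' counts, so
    the mean-count filter can run downstream.
    """
    matched: list[Loop] = []
    for loop in loops_a:
        partner = next(
            (
                other
                for other in loops_b
                if loop.anchor1.overlaps(other.anchor1)
                and loop.anchor2.overlaps(other.anchor2)
            ),
            None,
        )
        if partner is not None:
            matched.append(
                Loop(loop.anchor1, loop.anchor2, counts=loop.counts + partner.counts)
            )
    return matched


def peak_anchored_stats(
    loops: Sequence[Loop], peaks_by_group: dict[str, IntervalSet]
) -> LoopStats:
    """Per-group loop statistics for peak-anchored loops.

    For each probability group: the loops with >= 1 anchor overlapping
    a group peak, loops per peak, the percentage of group peaks
    involved in >= 1 loop, and the log10 size / strength vectors of the
    group's loops.
    """
    all_anchors = IntervalSet(
        [a for loop in loops for a in (loop.anchor1, loop.anchor2)]
    )
    stats: dict[str, GroupLoopStats] = {}
    for group, peaks in peaks_by_group.items():
        if len(peaks) == 0:
            stats[group] = GroupLoopStats(group, 0, 0, 0.0, 0.0, [], [])
            continue
        group_loops = [
            loop
            for loop in loops
            if overlap_mask(IntervalSet([loop.anchor1, loop.anchor2]), peaks).any()
        ]
        if len(all_anchors) > 0:
            in_loops = int(overlap_mask(peaks, all_anchors).sum())
        else:
            in_loops = 0
        stats[group] = GroupLoopStats(
            group=group,
            n_loops=len(group_loops),
            n_peaks=len(peaks),
            loops_per_peak=len(group_loops) / len(peaks),
            percent_peaks_in_loops=100.0 * in_loops / len(peaks),
            log10_sizes=[math.log10(loop.size) for loop in group_loops],
            strengths=[loop.strength for loop in group_loops if loop.counts],
        )
    return LoopStats(groups=stats)
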