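"""Genomic interval containers and the interval algebra the pipeline builds on.

All coordinates are 0-based half-open. The overlap predicate everywhere
is "at least one shared base": intervals ``[a, b)`` and ``[c, d)``
overlap iff ``a < d and c < b``. Merging with ``gap=0`` fuses book-ended
intervals (``end == start``), matching the convention of the standard
genome-arithmetic tools.

The central primitive is :func:`overlap_matrix`: an exact
union-breakpoint segmentation of *k* interval sets with per-segment
membership flags, from which "called in at least *x* datasets" region
sets (:func:`regions_at_least`) are extracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np

from .genome import GenomeModel

__all__ = [
    "GenomicInterval",
    "IntervalSet",
    "OverlapMatrix",
    "IntervalError",
    "read_intervals",
    "write_intervals",
    "merge_intervals",
    "intersect_count",
    "overlap_matrix",
    "regions_at_least",
]

_SKIP_PREFIXES = ("track", "browser", "#")


class IntervalError(ValueError):
    """Malformed interval, file, or out-of-range parameter."""


class GenomicInterval(NamedTuple):
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def validate(self, genome: GenomeModel | None = None) -> "GenomicInterval":
        if self.start < 0 or self.start >= self.end:
            raise IntervalError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if genome is not None:
            if self.chrom not in genome:
                raise IntervalError(f"chromosome {self.chrom!r} not in genome")
            if self.end > genome.length(self.chrom):
                raise IntervalError(
                    f"interval {self.chrom}:{self.start}-{self.end} exceeds "
                    f"chromosome length {genome.length(self.chrom)}"
                )
        return self

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


def _chrom_sort_key(genome: GenomeModel | None):
    if genome is None:
        return lambda iv: (iv.chrom, iv.start, iv.end)
    return lambda iv: (genome.rank(iv.chrom), iv.start, iv.end)


@dataclass
class IntervalSet:
    """A sorted list of genomic intervals.

    Sorting is by (chromosome order, start, end); chromosome order comes
    from the bound genome when present, lexicographic otherwise.
    Intervals may overlap unless the set is the output of a merge.
    """

    intervals: list[GenomicInterval]
    genome: GenomeModel | None = None
    _by_chrom: dict[str, np.ndarray] | None = field(
        default=None, init=False, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        ivs = [GenomicInterval(*iv).validate(self.genome) for iv in self.intervals]
        ivs.sort(key=_chrom_sort_key(self.genome))
        self.intervals = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.intervals == other.intervals

    @property
    def count(self) -> int:
        """Number of intervals (the "unique regions" count of the decay curves)."""
        return len(self.intervals)

    @property
    def total_bases(self) -> int:
        return sum(iv.length for iv in self.intervals)

    def chroms(self) -> list[str]:
        seen: dict[str, None] = {}
        for iv in self.intervals:
            seen.setdefault(iv.chrom, None)
        return list(seen)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Per-chromosome ``(n, 2)`` arrays of start/end, cached."""
        if self._by_chrom is None:
            out: dict[str, list[tuple[int, int]]] = {}
            for iv in self.intervals:
                out.setdefault(iv.chrom, []).append((iv.start, iv.end))
            self._by_chrom = {
                chrom: np.asarray(rows, dtype=np.int64).reshape(-1, 2)
                for chrom, rows in out.items()
            }
        return self._by_chrom

    @classmethod
    def from_by_chrom(
        cls,
        by_chrom: dict[str, np.ndarray],
        genome: GenomeModel | None = None,
    ) -> "IntervalSet":
        ivs = [
            GenomicInterval(chrom, int(s), int(e))
            for chrom, arr in by_chrom.items()
            for s, e in np.asarray(arr, dtype=np.int64).reshape(-1, 2)
        ]
        return cls(ivs, genome=genome)


@dataclass
class OverlapMatrix:
    """Union-breakpoint segmentation of *k* interval sets.

    ``segments`` are disjoint and sorted; every base covered by at least
    one input set lies in exactly one segment. ``membership[i, j]`` is
    True iff input set *j* covers the whole of segment *i* (coverage is
    all-or-none because segment boundaries include every input
    breakpoint).
    """

    segments: IntervalSet
    membership: np.ndarray  # bool, shape (n_segments, k)
    set_labels: list[str]

    def __post_init__(self) -> None:
        self.membership = np.asarray(self.membership, dtype=bool)
        if self.membership.shape != (len(self.segments), len(self.set_labels)):
            raise IntervalError("membership shape does not match segments/labels")

    @property
    def k(self) -> int:
        return len(self.set_labels)

    def coverage_counts(self) -> np.ndarray:
        """Number of input sets covering each segment."""
        return self.membership.sum(axis=1)


# ---------------------------------------------------------------------------
# File I/O


def _parse_bed_line(
    raw: str, lineno: int, path: Path, genome: GenomeModel | None
) -> GenomicInterval | None:
    line = raw.rstrip("\n")
    stripped = line.strip()
    if not stripped or stripped.startswith(_SKIP_PREFIXES):
        return None
    fields = line.split("\t")
    if len(fields) < 3:
        fields = stripped.split()
    if len(fields) < 3:
        raise IntervalError(f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}")
    chrom = fields[0]
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise IntervalError(
            f"{path}:{lineno}: coordinates {fields[1]!r}, {fields[2]!r} "
            "are not integers"
        ) from None
    try:
        return GenomicInterval(chrom, start, end).validate(genome)
    except IntervalError as exc:
        raise IntervalError(f"{path}:{lineno}: {exc}") from None


def read_intervals(path: str | Path, genome: GenomeModel | None = None) -> IntervalSet:
    """Read a BED file (>= 3 columns) into a sorted :class:`IntervalSet`.

    Extra columns are ignored; ``track``/``browser``/``#`` lines are
    skipped. Malformed lines raise :class:`IntervalError` naming the
    line number.
    """
    path = Path(path)
    intervals: list[GenomicInterval] = []
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            iv = _parse_bed_line(raw, lineno, path, genome)
            if iv is not None:
                intervals.append(iv)
    return IntervalSet(intervals, genome=genome)


def write_intervals(intervals, path: str | Path) -> None:
    """Write intervals as BED3, or scored peaks as 10-column narrowPeak.

    Dispatches on the object: anything with a ``peaks`` attribute of
    scored peaks gets narrowPeak output (name, score, strand ".",
    signal, -log10 p, -log10 q, summit offset); plain interval sets get
    BED3.
    """
    path = Path(path)
    try:
        handle = path.open("w")
    except OSError as exc:
        raise IntervalError(f"cannot write {path}: {exc}") from exc
    with handle:
        if hasattr(intervals, "peaks"):  # ScoredPeakSet duck type
            for i, peak in enumerate(intervals.peaks, start=1):
                iv = peak.interval
                handle.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t"
                    f"peak_{i}\t{peak.bed_score()}\t.\t"
                    f"{peak.signal:.5f}\t{peak.neg_log10_p():.5f}\t"
                    f"{peak.neg_log10_q():.5f}\t{peak.summit - iv.start}\n"
                )
        else:
            for iv in intervals:
                handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# Interval algebra


def _merge_arrays(arr: np.ndarray, gap: int) -> np.ndarray:
    """Merge a sorted-by-start (n, 2) array; returns disjoint sorted array."""
    if len(arr) == 0:
        return arr.reshape(0, 2)
    order = np.lexsort((arr[:, 1], arr[:, 0]))
    starts, ends = arr[order, 0], arr[order, 1]
    running_end = np.maximum.accumulate(ends)
    # new group where this start lies more than `gap` past everything before
    new_group = np.empty(len(arr), dtype=bool)
    new_group[0] = True
    new_group[1:] = starts[1:] > running_end[:-1] + gap
    group = np.cumsum(new_group) - 1
    n_groups = group[-1] + 1
    out = np.empty((n_groups, 2), dtype=np.int64)
    out[:, 0] = starts[new_group]
    last = np.flatnonzero(new_group)[1:] - 1
    out[:-1, 1] = running_end[last]
    out[-1, 1] = running_end[-1]
    return out


def merge_intervals(intervals: IntervalSet, gap: int = 0) -> IntervalSet:
    """Merge overlapping intervals and intervals separated by <= ``gap`` bases.

    With ``gap=0`` book-ended intervals are merged. Output is disjoint
    and sorted.
    """
    if gap < 0:
        raise IntervalError(f"gap must be >= 0, got {gap}")
    merged = {
        chrom: _merge_arrays(arr, gap) for chrom, arr in intervals.by_chrom().items()
    }
    return IntervalSet.from_by_chrom(merged, genome=intervals.genome)


def _overlap_mask_one_chrom(query: np.ndarray, merged_subject: np.ndarray) -> np.ndarray:
    """Boolean mask over query rows overlapping the disjoint sorted subject."""
    if len(merged_subject) == 0 or len(query) == 0:
        return np.zeros(len(query), dtype=bool)
    s_starts, s_ends = merged_subject[:, 0], merged_subject[:, 1]
    # candidate: rightmost subject starting strictly before query end
    idx = np.searchsorted(s_starts, query[:, 1], side="left") - 1
    mask = idx >= 0
    mask[mask] = s_ends[idx[mask]] > query[mask, 0]
    return mask


def overlap_mask(query: IntervalSet, subject: IntervalSet) -> np.ndarray:
    """Per-interval flag over ``query`` (in sorted order): overlaps any subject
    interval by >= 1 base."""
    # merging the subject (gap 0) leaves base coverage unchanged, so the
    # overlap predicate is unaffected and lookups become binary searches
    merged_subject = {
        chrom: _merge_arrays(arr, 0) for chrom, arr in subject.by_chrom().items()
    }
    flags = np.zeros(len(query), dtype=bool)
    by_chrom = query.by_chrom()
    # query.intervals is sorted, so each chromosome occupies one contiguous run
    offsets: dict[str, int] = {}
    running = 0
    for iv in query.intervals:
        if iv.chrom not in offsets:
            offsets[iv.chrom] = running
            running += len(by_chrom[iv.chrom])
    for chrom, arr in by_chrom.items():
        sub = merged_subject.get(chrom)
        if sub is None:
            continue
        flags[offsets[chrom] : offsets[chrom] + len(arr)] = _overlap_mask_one_chrom(
            arr, sub
        )
    return flags


def intersect_count(a: IntervalSet, b: IntervalSet) -> tuple[int, np.ndarray]:
    """Count of ``a`` intervals overlapping (>= 1 base) any ``b`` interval.

    Returns ``(count, mask)`` where ``mask`` is a boolean vector over
    ``a`` in sorted order; each ``a`` interval counts at most once.
    """
    mask = overlap_mask(a, b)
    return int(mask.sum()), mask


def overlap_matrix(
    sets: Sequence[IntervalSet], labels: Sequence[str] | None = None
) -> OverlapMatrix:
    """Segment the union of *k* interval sets at every breakpoint.

    Each input set is merged (gap 0) first. Segments are the maximal
    runs between consecutive breakpoints covered by at least one input;
    membership flags record which inputs cover each segment.
    """
    if len(sets) < 1:
        raise IntervalError("overlap_matrix requires at least one interval set")
    if labels is None:
        labels = [f"set_{i + 1}" for i in range(len(sets))]
    labels = [str(label) for label in labels]
    if len(labels) != len(sets):
        raise IntervalError("one label per input set required")
    if len(set(labels)) != len(labels):
        raise IntervalError(f"duplicate set labels: {labels}")

    genome = next((s.genome for s in sets if s.genome is not None), None)
    merged = [
        {chrom: _merge_arrays(arr, 0) for chrom, arr in s.by_chrom().items()}
        for s in sets
    ]
    all_chroms: dict[str, None] = {}
    for m in merged:
        for chrom in m:
            all_chroms.setdefault(chrom, None)
    chrom_names = list(all_chroms)
    if genome is not None:
        chrom_names.sort(key=genome.rank)
    else:
        chrom_names.sort()

    seg_by_chrom: dict[str, np.ndarray] = {}
    flags_parts: list[np.ndarray] = []
    for chrom in chrom_names:
        arrs = [m.get(chrom, np.empty((0, 2), dtype=np.int64)) for m in merged]
        breakpoints = np.unique(np.concatenate([a.ravel() for a in arrs]))
        if len(breakpoints) < 2:
            continue
        seg_starts = breakpoints[:-1]
        seg_ends = breakpoints[1:]
        member = np.zeros((len(seg_starts), len(sets)), dtype=bool)
        for j, a in enumerate(arrs):
            if len(a) == 0:
                continue
            idx = np.searchsorted(a[:, 0], seg_starts, side="right") - 1
            ok = idx >= 0
            ok[ok] = a[idx[ok], 1] >= seg_ends[ok]
            member[:, j] = ok
        covered = member.any(axis=1)
        seg_by_chrom[chrom] = np.column_stack([seg_starts[covered], seg_ends[covered]])
        flags_parts.append(member[covered])

    segments = IntervalSet.from_by_chrom(seg_by_chrom, genome=genome)
    membership = (
        np.concatenate(flags_parts, axis=0)
        if flags_parts
        else np.zeros((0, len(sets)), dtype=bool)
    )
    return OverlapMatrix(segments=segments, membership=membership, set_labels=labels)


def regions_at_least(matrix: OverlapMatrix, x: int) -> IntervalSet:
    """Regions covered by at least ``x`` of the input sets, merged gap 0.

    The count of the returned set is the "unique regions called in at
    least x datasets" statistic of the decay curves.
    """
    if not 1 <= x <= matrix.k:
        raise IntervalError(f"x must be in [1, {matrix.k}], got {x}")
    keep = matrix.coverage_counts() >= x
    kept = [iv for iv, flag in zip(matrix.segments, keep) if flag]
    return merge_intervals(
        IntervalSet(kept, genome=matrix.segments.genome), gap=0
    )
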