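"""Fragment containers: a replicate's deduplicated sequenced fragments.

Fragments are strandless genomic intervals kept as a multiset —
identical fragments are retained (duplicate handling happened upstream,
and calling keeps all remaining duplicates). The container is backed by
flat numpy arrays so that million-fragment pools stay cheap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .genome import GenomeModel
from .intervals import (
    GenomicInterval,
    IntervalError,
    IntervalSet,
    _merge_arrays,
    _overlap_mask_one_chrom,
    _parse_bed_line,
)

__all__ = ["Fragment", "FragmentSet", "read_fragments", "write_fragments",
           "subtract_fragments"]

Fragment = GenomicInterval  # a fragment IS its interval; strand is ignored


@dataclass
class FragmentSet:
    """A replicate's fragments plus metadata.

    ``chrom_names`` maps the integer codes in ``chrom_codes`` to
    chromosome names; ``coords`` is an ``(n, 2)`` start/end array in the
    original (file or generation) order. ``depth`` is the fragment
    count.
    """

    chrom_names: list[str]
    chrom_codes: np.ndarray  # int32, shape (n,)
    coords: np.ndarray  # int64, shape (n, 2)
    target: str = ""
    replicate_id: str = ""
    _by_chrom: dict[str, np.ndarray] | None = field(
        default=None, init=False, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.chrom_codes = np.asarray(self.chrom_codes, dtype=np.int32)
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        if len(self.chrom_codes) != len(self.coords):
            raise IntervalError("chrom_codes and coords length mismatch")

    @property
    def depth(self) -> int:
        return len(self.coords)

    def __len__(self) -> int:
        return self.depth

    def __iter__(self) -> Iterator[Fragment]:
        for code, (start, end) in zip(self.chrom_codes, self.coords):
            yield Fragment(self.chrom_names[code], int(start), int(end))

    @classmethod
    def from_fragments(
        cls,
        fragments,
        target: str = "",
        replicate_id: str = "",
        chrom_names: list[str] | None = None,
    ) -> "FragmentSet":
        fragments = list(fragments)
        names = list(chrom_names) if chrom_names is not None else []
        rank = {name: i for i, name in enumerate(names)}
        codes = np.empty(len(fragments), dtype=np.int32)
        coords = np.empty((len(fragments), 2), dtype=np.int64)
        for i, frag in enumerate(fragments):
            if frag.chrom not in rank:
                rank[frag.chrom] = len(names)
                names.append(frag.chrom)
            codes[i] = rank[frag.chrom]
            coords[i] = (frag.start, frag.end)
        return cls(names, codes, coords, target=target, replicate_id=replicate_id)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Per-chromosome ``(n, 2)`` coordinate arrays (cached, order stable)."""
        if self._by_chrom is None:
            self._by_chrom = {
                name: self.coords[self.chrom_codes == code]
                for code, name in enumerate(self.chrom_names)
                if np.any(self.chrom_codes == code)
            }
        return self._by_chrom

    def mean_fragment_length(self) -> float:
        if self.depth == 0:
            return 0.0
        return float(np.mean(self.coords[:, 1] - self.coords[:, 0]))

    def take(self, indices: np.ndarray, replicate_id: str | None = None) -> "FragmentSet":
        """Sub-multiset at the given row indices; metadata preserved."""
        return FragmentSet(
            list(self.chrom_names),
            self.chrom_codes[indices],
            self.coords[indices],
            target=self.target,
            replicate_id=self.replicate_id if replicate_id is None else replicate_id,
        )

    def as_multiset(self) -> dict[Fragment, int]:
        out: dict[Fragment, int] = {}
        for frag in self:
            out[frag] = out.get(frag, 0) + 1
        return out


def read_fragments(
    path: str | Path,
    target: str = "",
    replicate_id: str = "",
    genome: GenomeModel | None = None,
) -> FragmentSet:
    """Read a BED3 fragment file; depth equals the number of records.

    Duplicate lines are retained (multiset contract). Comment/track
    lines are skipped; malformed lines raise with the line number.
    """
    path = Path(path)
    if not replicate_id:
        replicate_id = path.stem
    fragments: list[Fragment] = []
    with path.open() as handle:
        for lineno, raw in enumerate(handle, start=1):
            iv = _parse_bed_line(raw, lineno, path, genome)
            if iv is not None:
                fragments.append(iv)
    names = genome.names if genome is not None else None
    return FragmentSet.from_fragments(
        fragments, target=target, replicate_id=replicate_id, chrom_names=names
    )


def write_fragments(frags: FragmentSet, path: str | Path) -> None:
    with Path(path).open("w") as handle:
        for frag in frags:
            handle.write(f"{frag.chrom}\t{frag.start}\t{frag.end}\n")


def subtract_fragments(frags: FragmentSet, suspect: IntervalSet) -> FragmentSet:
    """Drop every fragment overlapping (>= 1 base) any suspect interval.

    Whole-fragment removal, not clipping: a read touching an
    artifact-prone region is discarded entirely.
    """
    if len(suspect) == 0 or frags.depth == 0:
        return frags.take(np.arange(frags.depth))
    merged = {c: _merge_arrays(a, 0) for c, a in suspect.by_chrom().items()}
    drop = np.zeros(frags.depth, dtype=bool)
    for code, name in enumerate(frags.chrom_names):
        sub = merged.get(name)
        if sub is None:
            continue
        rows = np.flatnonzero(frags.chrom_codes == code)
        if len(rows) == 0:
            continue
        drop[rows] = _overlap_mask_one_chrom(frags.coords[rows], sub)
    return frags.take(np.flatnonzero(~drop))
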