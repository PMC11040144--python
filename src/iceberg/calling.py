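"""Poisson local-background peak caller for CUT&RUN fragment data.

Sliding windows are scored by the number of treatment fragments
overlapping them. The null rate for each window is the maximum of a
genome-wide uniform rate, the depth-scaled control count in the window
itself, and rates estimated from the control in wider windows centered
on the same position (default 1 kb and 10 kb). The window-matched term
matters for sharp artifact hotspots shared with the control: averaging
such a pile-up over 1 kb would understate its density and let it
through, while the same-window estimate suppresses it.
Window p-values are upper Poisson tails; Benjamini-Hochberg q-values
are computed across all tested windows; significant windows are merged
into peaks.

The caller is deliberately simple and deterministic. It is pluggable:
any externally produced BED/narrowPeak file can be substituted through
:func:`iceberg.intervals.read_intervals` wherever a peak set is
consumed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .fragments import FragmentSet
from .genome import GenomeModel
from .intervals import GenomicInterval, IntervalSet, _merge_arrays

__all__ = [
    "PeakCallParams",
    "ScoredPeak",
    "ScoredPeakSet",
    "PeakCallError",
    "call_peaks",
    "benjamini_hochberg",
    "threshold_peaks",
]

_P_FLOOR = 1e-300  # Poisson tails underflow for strong peaks; keep p in (0, 1]

_DEFAULT_THRESHOLDS = {"q": 0.05, "p": 0.01}


class PeakCallError(ValueError):
    """Invalid caller parameters or inputs."""


@dataclass(frozen=True)
class PeakCallParams:
    """Tuning parameters of the window caller.

    window/step are the sliding-window geometry in bp; ``local_scales``
    are the control-window widths for the local background estimate;
    windows passing the (mode, threshold) cut are merged within
    ``merge_gap`` and peaks shorter than ``min_length`` are dropped.
    ``pseudocount`` regularizes empty control windows.
    """

    window: int = 50
    step: int = 25
    local_scales: tuple[int, ...] = (1000, 10000)
    merge_gap: int = 100
    min_length: int = 50
    pseudocount: float = 0.5
    threshold_mode: str = "q"
    threshold: float | None = None

    def __post_init__(self) -> None:
        if not (self.window >= self.step > 0):
            raise PeakCallError(
                f"need window >= step > 0, got window={self.window} step={self.step}"
            )
        if self.threshold_mode not in ("q", "p"):
            raise PeakCallError(f"threshold_mode must be 'q' or 'p', got {self.threshold_mode!r}")
        if self.threshold is None:
            object.__setattr__(self, "threshold", _DEFAULT_THRESHOLDS[self.threshold_mode])
        if not 0 < self.threshold < 1:
            raise PeakCallError(f"threshold must be in (0,1), got {self.threshold}")
        if any(s < self.window for s in self.local_scales):
            raise PeakCallError("every local scale must be >= window")
        if self.pseudocount < 0 or self.merge_gap < 0 or self.min_length < 0:
            raise PeakCallError("pseudocount, merge_gap, min_length must be >= 0")


@dataclass(frozen=True)
class ScoredPeak:
    interval: GenomicInterval
    p_value: float
    q_value: float
    summit: int
    signal: float  # max window fold enrichment over local background

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise PeakCallError(f"p-value {self.p_value} outside (0, 1]")
        if not self.interval.start <= self.summit < self.interval.end:
            raise PeakCallError("summit outside peak interval")

    def neg_log10_p(self) -> float:
        return -math.log10(self.p_value)

    def neg_log10_q(self) -> float:
        return -math.log10(max(self.q_value, _P_FLOOR))

    def bed_score(self) -> int:
        """narrowPeak score column: int(min(1000, 10 * (-log10 q)))."""
        return int(min(1000.0, 10.0 * self.neg_log10_q()))


@dataclass
class ScoredPeakSet:
    peaks: list[ScoredPeak]
    params: PeakCallParams
    treatment_depth: int
    control_depth: int

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def intervals(self, genome: GenomeModel | None = None) -> IntervalSet:
        return IntervalSet([p.interval for p in self.peaks], genome=genome)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Step-up Benjamini-Hochberg q-values, input order preserved.

    q_i = min over ranks j >= rank(i) of m * p_(j) / j, the standard
    monotone adjustment.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise PeakCallError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def window_p_value(count, lam):
    """Upper Poisson tail P(X >= count | lam), floored away from zero.

    This is the per-window significance the caller assigns: the
    probability of seeing at least the observed fragment count under
    the local background rate.
    """
    p = stats.poisson.sf(np.asarray(count) - 1, lam)
    return np.clip(p, _P_FLOOR, 1.0)


def _window_grid(length: int, window: int, step: int) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(0, length, step, dtype=np.int64)
    ends = np.minimum(starts + window, length)
    keep = ends > starts
    return starts[keep], ends[keep]


def _count_overlapping(
    frag_starts_sorted: np.ndarray,
    frag_ends_sorted: np.ndarray,
    win_starts: np.ndarray,
    win_ends: np.ndarray,
) -> np.ndarray:
    """Fragments overlapping [s, e) by >= 1 bp, per window."""
    n_start_before_end = np.searchsorted(frag_starts_sorted, win_ends, side="left")
    n_end_at_or_before_start = np.searchsorted(frag_ends_sorted, win_starts, side="right")
    return n_start_before_end - n_end_at_or_before_start


def call_peaks(
    treatment: FragmentSet,
    control: FragmentSet | None,
    genome: GenomeModel,
    params: PeakCallParams | None = None,
) -> ScoredPeakSet:
    """Call enriched regions in ``treatment`` against ``control``.

    ``control=None`` selects pseudo-control mode: a uniform genome-wide
    rate derived from the treatment itself (local-scale estimates are
    unavailable without a control). A control with zero depth is an
    error directing the caller to pseudo-control mode explicitly.
    """
    if params is None:
        params = PeakCallParams()
    if len(genome) == 0:
        raise PeakCallError("empty genome")
    if treatment.depth == 0:
        raise PeakCallError("treatment has zero depth")
    if control is not None and control.depth == 0:
        raise PeakCallError(
            "control has zero depth; pass control=None to use pseudo-control "
            "(uniform genome-wide lambda) mode"
        )

    genome_len = genome.total_length
    frag_len = (control or treatment).mean_fragment_length()
    w_eff = params.window + frag_len  # expected footprint of a window on fragments
    if control is None:
        lambda_genome = treatment.depth * w_eff / genome_len
        ratio = 1.0
        control_by_chrom: dict[str, np.ndarray] = {}
    else:
        ratio = treatment.depth / control.depth
        lambda_genome = ratio * control.depth * w_eff / genome_len
        control_by_chrom = control.by_chrom()

    treat_by_chrom = treatment.by_chrom()

    per_chrom: list[tuple[str, np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = []
    all_p: list[np.ndarray] = []
    for name, length in genome.chromosomes:
        win_starts, win_ends = _window_grid(length, params.window, params.step)
        if len(win_starts) == 0:
            continue
        t_arr = treat_by_chrom.get(name)
        if t_arr is None or len(t_arr) == 0:
            counts = np.zeros(len(win_starts), dtype=np.int64)
        else:
            counts = _count_overlapping(
                np.sort(t_arr[:, 0]), np.sort(t_arr[:, 1]), win_starts, win_ends
            )
        lam = np.full(len(win_starts), lambda_genome, dtype=float)
        if control is not None:
            c_arr = control_by_chrom.get(name)
            c_starts = np.sort(c_arr[:, 0]) if c_arr is not None and len(c_arr) else None
            c_ends = np.sort(c_arr[:, 1]) if c_starts is not None else None
            centers = (win_starts + win_ends) // 2
            # window-matched scale always participates (see module docstring)
            scales = (params.window, *params.local_scales)
            for scale in scales:
                lo = np.maximum(centers - scale // 2, 0)
                hi = np.minimum(centers + scale // 2, length)
                if c_starts is None:
                    c_counts = np.zeros(len(win_starts), dtype=np.int64)
                else:
                    c_counts = _count_overlapping(c_starts, c_ends, lo, hi)
                scale_eff = (hi - lo) + frag_len
                lam_scale = ratio * (c_counts + params.pseudocount) * w_eff / scale_eff
                np.maximum(lam, lam_scale, out=lam)
        p = window_p_value(counts, lam)
        per_chrom.append((name, win_starts, win_ends, counts, lam))
        all_p.append(p)

    if not per_chrom:
        return ScoredPeakSet([], params, treatment.depth, control.depth if control else 0)

    p_flat = np.concatenate(all_p)
    q_flat = benjamini_hochberg(p_flat)

    if params.threshold_mode == "q":
        passing = q_flat < params.threshold
    else:
        passing = p_flat < params.threshold

    peaks: list[ScoredPeak] = []
    offset = 0
    for (name, win_starts, win_ends, counts, lam), p_chrom in zip(per_chrom, all_p):
        n = len(win_starts)
        q_chrom = q_flat[offset : offset + n]
        keep = passing[offset : offset + n]
        offset += n
        if not np.any(keep):
            continue
        hit = np.column_stack([win_starts[keep], win_ends[keep]])
        merged = _merge_arrays(hit, params.merge_gap)
        # member windows of each merged region, for summit/p/q summaries
        for start, end in merged:
            if end - start < params.min_length:
                continue
            members = np.flatnonzero(keep & (win_starts < end) & (win_ends > start))
            best = members[np.argmax(counts[members])]
            fold = (counts[members] + params.pseudocount) / (
                lam[members] + params.pseudocount
            )
            peaks.append(
                ScoredPeak(
                    interval=GenomicInterval(name, int(start), int(end)),
                    p_value=float(p_chrom[members].min()),
                    q_value=float(q_chrom[members].min()),
                    summit=int((win_starts[best] + win_ends[best]) // 2),
                    signal=float(fold.max()),
                )
            )
    return ScoredPeakSet(
        peaks, params, treatment.depth, control.depth if control is not None else 0
    )


def threshold_peaks(result: ScoredPeakSet, mode: str, cutoff: float) -> ScoredPeakSet:
    """Filter called peaks at a stricter stringency.

    Retains peaks with p (or q) below ``cutoff``. No re-merging: the
    call was made at the loosest stringency and stricter sets are
    obtained by filtering, so peak sets are nested by construction.
    """
    if mode not in ("q", "p"):
        raise PeakCallError(f"mode must be 'q' or 'p', got {mode!r}")
    if not 0 < cutoff <= 1:
        raise PeakCallError(f"cutoff must be in (0, 1], got {cutoff}")
    key = (lambda pk: pk.q_value) if mode == "q" else (lambda pk: pk.p_value)
    kept = [pk for pk in result.peaks if key(pk) < cutoff]
    return ScoredPeakSet(
        kept,
        replace(result.params, threshold_mode=mode, threshold=min(cutoff, 0.999999)),
        result.treatment_depth,
        result.control_depth,
    )
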