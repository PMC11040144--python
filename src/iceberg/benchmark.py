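"""Benchmarking peak sets and replicate-combination strategies against a
gold-standard peak set.

Precision is the fraction of called peaks overlapping the gold set;
recall is the fraction of gold peaks overlapping the called set. The
two ratios count different interval lists, so a called peak spanning
two gold peaks counts once toward precision while both gold peaks count
toward recall. F1 is the harmonic mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import IntervalError, IntervalSet, intersect_count, overlap_matrix, \
    regions_at_least

__all__ = [
    "BenchmarkResult",
    "precision_recall",
    "f1_score",
    "combine_replicates",
    "benchmark_table",
]

logger = logging.getLogger("iceberg")


@dataclass(frozen=True)
class BenchmarkResult:
    strategy: str
    caller: str
    combination: tuple[int, ...]
    precision: float | None  # None when the called set is empty
    recall: float
    f1: float | None
    n_called: int
    n_gold: int


def precision_recall(
    called: IntervalSet, gold: IntervalSet
) -> tuple[float | None, float]:
    """(precision, recall) of ``called`` against ``gold``.

    An empty called set has undefined precision (returned as None) and
    recall 0; an empty gold set is an error.
    """
    if len(gold) == 0:
        raise IntervalError("gold-standard peak set is empty")
    if len(called) == 0:
        return None, 0.0
    hits_called, _ = intersect_count(called, gold)
    hits_gold, _ = intersect_count(gold, called)
    return hits_called / len(called), hits_gold / len(gold)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    for name, value in (("precision", precision), ("recall", recall)):
        if not 0 <= value <= 1:
            raise IntervalError(f"{name} must be in [0, 1], got {value}")
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def combine_replicates(
    peak_sets: Sequence[IntervalSet],
    k: int,
    m: int,
    selection: str | int = "all",
    seed: int = 0,
) -> list[tuple[tuple[int, ...], IntervalSet]]:
    """Peak sets of k-of-m majority votes over replicate combinations.

    Enumerates distinct m-subsets of the n input sets (no replicate
    repeated within a combination) and applies the at-least-k coverage
    rule to each. ``selection="all"`` evaluates every C(n, m)
    combination; an integer draws that many distinct combinations with
    a seeded RNG (capped at the total, with a warning).
    """
    n = len(peak_sets)
    if not 1 <= k <= m <= n:
        raise IntervalError(f"need 1 <= k <= m <= n, got k={k} m={m} n={n}")
    all_combos = list(combinations(range(n), m))
    if selection == "all":
        chosen = all_combos
    else:
        count = int(selection)
        total = comb(n, m)
        if count > total:
            logger.warning(
                "requested %d combinations but only %d exist; using all", count, total
            )
            count = total
        rng = np.random.default_rng(seed)
        idx = rng.choice(total, size=count, replace=False)
        chosen = [all_combos[i] for i in sorted(idx)]
    out = []
    for combo in chosen:
        sets = [peak_sets[i] for i in combo]
        if m == 1:
            merged = regions_at_least(overlap_matrix(sets), 1)
        else:
            merged = regions_at_least(overlap_matrix(sets), k)
        out.append((combo, merged))
    return out


def benchmark_table(
    replicate_sets_by_mode: dict[str, Sequence[IntervalSet]],
    gold: IntervalSet,
    strategies: Sequence[tuple[int, int]] = ((1, 1), (2, 2), (2, 3), (3, 3)),
    triplicate_selection: str | int = 50,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate every (caller mode, strategy, combination) against ``gold``.

    ``replicate_sets_by_mode`` maps a caller/stringency label (e.g.
    "q<0.05") to that mode's per-replicate peak sets. Strategies are
    (k, m) majority votes; m = 1 is the single-replicate strategy,
    m = 2 exhausts all pairs, m >= 3 uses ``triplicate_selection``
    seeded random combinations. Returns (per-combination rows, summary
    with mean/sd F1 per mode and strategy; empty-called combinations
    are excluded from means and counted in n_excluded).
    """
    rows = []
    for mode, sets in replicate_sets_by_mode.items():
        sets = list(sets)
        for k, m in strategies:
            selection = "all" if m <= 2 else triplicate_selection
            label = "single" if m == 1 else f"{k}of{m}"
            for combo, called in combine_replicates(
                sets, k, m, selection=selection, seed=seed
            ):
                precision, recall = precision_recall(called, gold)
                f1 = None if precision is None else f1_score(precision, recall)
                rows.append(
                    BenchmarkResult(
                        strategy=label,
                        caller=mode,
                        combination=combo,
                        precision=precision,
                        recall=recall,
                        f1=f1,
                        n_called=len(called),
                        n_gold=len(gold),
                    )
                )
    table = pd.DataFrame([r.__dict__ for r in rows])
    summaries = []
    if not table.empty:
        for (mode, strategy), grp in table.groupby(["caller", "strategy"], sort=False):
            valid = grp["f1"].dropna()
            summaries.append(
                {
                    "caller": mode,
                    "strategy": strategy,
                    "n_combinations": len(grp),
                    "n_excluded": int(grp["f1"].isna().sum()),
                    "mean_f1": float(valid.mean()) if len(valid) else np.nan,
                    "sd_f1": float(valid.std(ddof=1)) if len(valid) > 1 else 0.0,
                    "mean_precision": float(grp["precision"].dropna().mean())
                    if grp["precision"].notna().any()
                    else np.nan,
                    "mean_recall": float(grp["recall"].mean()),
                }
            )
    summary = pd.DataFrame(summaries)
    return table, summary
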