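"""Shared fixtures: per-base boolean-coverage oracles for the interval
algebra, small deterministic fragment builders, and one session-scoped
full-scale simulation run reused by the analytics and acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from iceberg.calling import threshold_peaks
from iceberg.core import IcebergConfig, run_iceberg
from iceberg.fragments import FragmentSet
from iceberg.genome import GenomeModel
from iceberg.intervals import GenomicInterval, IntervalSet
from iceberg.simulate import SyntheticConfig, simulate_experiment

# ---------------------------------------------------------------------------
# per-base boolean oracle (single chromosome)


def coverage_array(intervals, genome_len: int) -> np.ndarray:
    cov = np.zeros(genome_len, dtype=bool)
    for iv in intervals:
        cov[iv.start : iv.end] = True
    return cov


def runs_of(cov: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean array as (start, end) half-open."""
    padded = np.concatenate([[False], cov, [False]])
    edges = np.flatnonzero(padded[1:] != padded[:-1])
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def oracle_merge(intervals, genome_len: int, gap: int = 0) -> list[tuple[int, int]]:
    runs = runs_of(coverage_array(intervals, genome_len))
    merged: list[list[int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] <= gap:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def oracle_regions_at_least(sets, genome_len: int, x: int) -> list[tuple[int, int]]:
    depth = np.zeros(genome_len, dtype=int)
    for ivs in sets:
        depth += coverage_array(ivs, genome_len).astype(int)
    return runs_of(depth >= x)


def oracle_overlaps(a: GenomicInterval, b_cov: np.ndarray) -> bool:
    return bool(b_cov[a.start : a.end].any())


# ---------------------------------------------------------------------------
# builders


def make_set(pairs, chrom: str = "chr1", genome: GenomeModel | None = None):
    return IntervalSet(
        [GenomicInterval(chrom, s, e) for s, e in pairs], genome=genome
    )


def uniform_fragments(
    n: int,
    genome_len: int,
    seed: int,
    chrom: str = "chr1",
    frag_len: int = 170,
    replicate_id: str = "frags",
) -> FragmentSet:
    rng = np.random.default_rng(seed)
    centers = rng.uniform(0, genome_len, size=n)
    starts = np.clip(np.round(centers - frag_len / 2).astype(np.int64), 0,
                     genome_len - 1)
    ends = np.minimum(starts + frag_len, genome_len)
    return FragmentSet.from_fragments(
        [GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends)],
        replicate_id=replicate_id,
        chrom_names=[chrom],
    )


@pytest.fixture
def toy_sets():
    """The three-set fixture used across the decay/majority examples."""
    a = make_set([(0, 10)], chrom="c")
    b = make_set([(5, 15)], chrom="c")
    c = make_set([(20, 30)], chrom="c")
    return a, b, c


@pytest.fixture(scope="session")
def sim_run():
    """Full-scale planted-spectrum simulation (default config) plus the
    aggregation pipeline run and per-replicate stringency tiers."""
    config = SyntheticConfig()  # 25 replicates, 200 sites, seed 1234
    truth, replicates, iggs = simulate_experiment(config)
    result = run_iceberg(replicates, iggs, config.genome, IcebergConfig(),
                         seed=config.seed)
    genome = config.genome
    strict = [threshold_peaks(c, "q", 0.05).intervals(genome)
              for c in result.replicate_calls]
    p001 = [threshold_peaks(c, "p", 0.001).intervals(genome)
            for c in result.replicate_calls]
    p01 = [c.intervals(genome) for c in result.replicate_calls]

    sites_sorted = sorted(
        truth.sites, key=lambda s: (s.interval.chrom, s.interval.start, s.interval.end)
    )
    return {
        "config": config,
        "truth": truth,
        "replicates": replicates,
        "iggs": iggs,
        "result": result,
        "strict_sets": strict,
        "p001_sets": p001,
        "p01_sets": p01,
        "site_set": IntervalSet([s.interval for s in sites_sorted], genome=genome),
        "site_probabilities": np.array([s.probability for s in sites_sorted]),
    }
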