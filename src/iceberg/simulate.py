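"""Seeded multi-replicate CUT&RUN fragment simulator with a planted truth.

The generative model mirrors what the aggregation pipeline observes in
real data, without modeling sequence or chemistry:

* a set of binding sites, each with an occupancy probability ``p_s``
  (the chance that a given replicate captures the event at all) and a
  strength ``lambda_s`` (expected fragments when captured). Site
  activity is Bernoulli per (site, replicate): at bulk level the
  "fraction of cells bound" and "residence time" interpretations
  collapse into a single detection probability, which is all the
  pipeline can see.
* uniform background fragments in every replicate,
* artifact hotspots that pile up fragments in treatment AND IgG
  control alike — the signature the control subtracts away,
* a multiplicative per-replicate depth jitter emulating the
  efficiency spread between real replicates.

Everything is drawn from child-seeded RNG streams keyed by
(seed, replicate index), so output is reproducible and platform
independent fragment-for-fragment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .aggregation import child_seed
from .fragments import FragmentSet, write_fragments
from .genome import GenomeModel
from .intervals import GenomicInterval, IntervalError

__all__ = [
    "SyntheticConfig",
    "SimSite",
    "TruthTable",
    "generate_truth",
    "simulate_replicate",
    "simulate_control",
    "simulate_experiment",
    "write_truth",
    "read_truth",
]

_DEFAULT_GENOME = GenomeModel([("chrSim", 2_000_000)])


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the planted-spectrum simulation.

    The probability mixture is a list of ``(weight, p_low, p_high)``
    components; each site draws its occupancy probability uniformly
    within one component. The default plants a bimodal spectrum: a
    quarter of sites near-constitutive (p in [0.8, 1.0]) and the rest
    rare-to-occasional (p in [0.02, 0.3]).
    """

    genome: GenomeModel = _DEFAULT_GENOME
    n_sites: int = 200
    probability_mixture: tuple[tuple[float, float, float], ...] = (
        (0.25, 0.8, 1.0),
        (0.75, 0.02, 0.3),
    )
    site_width: int = 300
    signal_fragments_mean: float = 40.0
    fragment_length_mean: float = 170.0
    fragment_length_sd: float = 30.0
    fragment_length_min: int = 50
    background_fragments: int = 50_000
    n_hotspots: int = 3
    hotspot_fragments_mean: float = 60.0
    n_replicates: int = 25
    n_igg: int = 10
    depth_jitter: tuple[float, float] = (0.8, 1.2)
    seed: int = 1234

    def __post_init__(self) -> None:
        weights = [w for w, _, _ in self.probability_mixture]
        if abs(sum(weights) - 1.0) > 1e-9:
            raise IntervalError("probability mixture weights must sum to 1")
        for _, lo, hi in self.probability_mixture:
            if not (0 <= lo <= hi <= 1):
                raise IntervalError(f"invalid mixture bounds ({lo}, {hi})")
        if min(self.n_sites, self.site_width, self.background_fragments,
               self.n_replicates, self.n_igg) < 1 or self.n_hotspots < 0:
            raise IntervalError("simulation counts must be positive")
        if not 0 < self.depth_jitter[0] <= self.depth_jitter[1]:
            raise IntervalError("depth_jitter range must satisfy 0 < low <= high")


@dataclass(frozen=True)
class SimSite:
    interval: GenomicInterval
    probability: float  # p_s: chance a replicate captures the event
    strength: float  # lambda_s: expected fragments when captured
    artifact: bool = False


@dataclass
class TruthTable:
    """Planted sites and artifact hotspots with their parameters."""

    sites: list[SimSite]
    hotspots: list[GenomicInterval]
    config: SyntheticConfig

    @property
    def site_intervals(self):
        from .intervals import IntervalSet

        return IntervalSet([s.interval for s in self.sites], genome=self.config.genome)

    @property
    def hotspot_intervals(self):
        from .intervals import IntervalSet

        return IntervalSet(list(self.hotspots), genome=self.config.genome)


def _place_disjoint(
    rng: np.random.Generator,
    genome: GenomeModel,
    n: int,
    width: int,
    occupied: list[tuple[int, int, int]],
    max_tries: int = 10_000,
) -> list[GenomicInterval]:
    """Rejection-sample n disjoint width-bp intervals avoiding `occupied`."""
    chrom_lengths = [length for _, length in genome.chromosomes]
    total = sum(max(length - width, 0) for length in chrom_lengths)
    if total <= 0:
        raise IntervalError("genome too small for the requested site width")
    placed: list[GenomicInterval] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise IntervalError(
                f"could not place {n} disjoint sites in {max_tries} tries; "
                "use a larger genome or fewer/narrower sites"
            )
        ci = int(rng.integers(0, len(chrom_lengths)))
        name, length = genome.chromosomes[ci]
        if length <= width:
            continue
        start = int(rng.integers(0, length - width))
        end = start + width
        clash = any(
            c == ci and start < oe and os_ < end for c, os_, oe in occupied
        )
        if clash:
            continue
        occupied.append((ci, start, end))
        placed.append(GenomicInterval(name, start, end))
    return placed


def generate_truth(config: SyntheticConfig) -> TruthTable:
    """Plant sites and hotspots; deterministic given the config seed.

    Site strengths are Gamma-distributed (shape 4) around the
    configured mean so the spectrum includes weak and strong events;
    occupancy probabilities come from the configured mixture.
    """
    rng = np.random.default_rng(child_seed(config.seed, "truth"))
    occupied: list[tuple[int, int, int]] = []
    site_ivs = _place_disjoint(rng, config.genome, config.n_sites,
                               config.site_width, occupied)
    hotspot_ivs = _place_disjoint(rng, config.genome, config.n_hotspots,
                                  config.site_width, occupied)
    weights = np.array([w for w, _, _ in config.probability_mixture])
    sites = []
    for iv in site_ivs:
        comp = int(rng.choice(len(weights), p=weights))
        _, lo, hi = config.probability_mixture[comp]
        p_s = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
        lam = float(rng.gamma(shape=4.0, scale=config.signal_fragments_mean / 4.0))
        sites.append(SimSite(interval=iv, probability=p_s, strength=lam))
    return TruthTable(sites=sites, hotspots=hotspot_ivs, config=config)


def _sample_fragments_at(
    rng: np.random.Generator,
    config: SyntheticConfig,
    chrom: str,
    center: float,
    n: int,
    positional_sd: float,
) -> list[GenomicInterval]:
    if n <= 0:
        return []
    length_limit = config.genome.length(chrom)
    centers = center + rng.normal(0.0, positional_sd, size=n)
    lengths = np.maximum(
        rng.normal(config.fragment_length_mean, config.fragment_length_sd, size=n),
        config.fragment_length_min,
    )
    starts = np.clip(np.round(centers - lengths / 2).astype(np.int64), 0,
                     length_limit - 1)
    ends = np.clip(np.round(centers + lengths / 2).astype(np.int64), 1, length_limit)
    ends = np.maximum(ends, starts + 1)
    return [GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends)]


def _background_fragments(
    rng: np.random.Generator, config: SyntheticConfig, n: int
) -> list[GenomicInterval]:
    if n <= 0:
        return []
    chroms = config.genome.chromosomes
    lengths = np.array([length for _, length in chroms], dtype=float)
    which = rng.choice(len(chroms), size=n, p=lengths / lengths.sum())
    out: list[GenomicInterval] = []
    for ci in range(len(chroms)):
        name, length = chroms[ci]
        k = int(np.sum(which == ci))
        if k == 0:
            continue
        centers = rng.uniform(0, length, size=k)
        frag_lengths = np.maximum(
            rng.normal(config.fragment_length_mean, config.fragment_length_sd, size=k),
            config.fragment_length_min,
        )
        starts = np.clip(np.round(centers - frag_lengths / 2).astype(np.int64), 0,
                         length - 1)
        ends = np.clip(np.round(centers + frag_lengths / 2).astype(np.int64), 1, length)
        ends = np.maximum(ends, starts + 1)
        out.extend(GenomicInterval(name, int(s), int(e)) for s, e in zip(starts, ends))
    return out


def _simulate(
    truth: TruthTable,
    config: SyntheticConfig,
    rng: np.random.Generator,
    with_signal: bool,
    replicate_id: str,
    target: str,
) -> FragmentSet:
    jitter = float(rng.uniform(*config.depth_jitter))
    frags: list[GenomicInterval] = []
    if with_signal:
        for site in truth.sites:
            if rng.random() >= site.probability:
                continue
            n = int(rng.poisson(site.strength * jitter))
            frags.extend(
                _sample_fragments_at(
                    rng,
                    config,
                    site.interval.chrom,
                    (site.interval.start + site.interval.end) / 2,
                    n,
                    positional_sd=config.site_width / 4,
                )
            )
    for hotspot in truth.hotspots:
        n = int(rng.poisson(config.hotspot_fragments_mean * jitter))
        frags.extend(
            _sample_fragments_at(
                rng,
                config,
                hotspot.chrom,
                (hotspot.start + hotspot.end) / 2,
                n,
                positional_sd=config.site_width / 4,
            )
        )
    n_bg = int(rng.poisson(config.background_fragments * jitter))
    frags.extend(_background_fragments(rng, config, n_bg))
    return FragmentSet.from_fragments(
        frags,
        target=target,
        replicate_id=replicate_id,
        chrom_names=config.genome.names,
    )


def simulate_replicate(
    truth: TruthTable, config: SyntheticConfig, replicate_index: int
) -> FragmentSet:
    """One treatment replicate: site signal + hotspots + background."""
    rng = np.random.default_rng(child_seed(config.seed, "rep", replicate_index))
    return _simulate(
        truth, config, rng, with_signal=True,
        replicate_id=f"rep{replicate_index + 1}", target="treatment",
    )


def simulate_control(
    truth: TruthTable, config: SyntheticConfig, igg_index: int
) -> FragmentSet:
    """One IgG control replicate: hotspots + background, no site signal."""
    rng = np.random.default_rng(child_seed(config.seed, "igg", igg_index))
    return _simulate(
        truth, config, rng, with_signal=False,
        replicate_id=f"igg{igg_index + 1}", target="igg",
    )


def simulate_experiment(
    config: SyntheticConfig,
) -> tuple[TruthTable, list[FragmentSet], list[FragmentSet]]:
    """Truth table plus all treatment replicates and IgG controls."""
    truth = generate_truth(config)
    reps = [simulate_replicate(truth, config, i) for i in range(config.n_replicates)]
    iggs = [simulate_control(truth, config, i) for i in range(config.n_igg)]
    return truth, reps, iggs


def write_truth(truth: TruthTable, path: str | Path) -> None:
    """Truth TSV: chrom, start, end, p_s, lambda_s, artifact flag."""
    with Path(path).open("w") as handle:
        handle.write("chrom\tstart\tend\tprobability\tstrength\tartifact\n")
        for site in truth.sites:
            iv = site.interval
            handle.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{site.probability:.6f}\t"
                f"{site.strength:.6f}\t0\n"
            )
        for iv in truth.hotspots:
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t0\t0\t1\n")


def read_truth(path: str | Path, config: SyntheticConfig) -> TruthTable:
    sites: list[SimSite] = []
    hotspots: list[GenomicInterval] = []
    with Path(path).open() as handle:
        header = handle.readline()
        if not header.startswith("chrom"):
            raise IntervalError(f"{path}: missing truth-table header")
        for line in handle:
            chrom, start, end, p_s, lam, artifact = line.rstrip("\n").split("\t")
            iv = GenomicInterval(chrom, int(start), int(end))
            if artifact == "1":
                hotspots.append(iv)
            else:
                sites.append(SimSite(iv, float(p_s), float(lam)))
    return TruthTable(sites=sites, hotspots=hotspots, config=config)


def write_simulation(
    truth: TruthTable,
    replicates: Sequence[FragmentSet],
    controls: Sequence[FragmentSet],
    outdir: str | Path,
) -> None:
    """Write per-replicate BED3 fragment files, IgG BED3s, and the truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "replicates").mkdir(exist_ok=True)
    (outdir / "igg").mkdir(exist_ok=True)
    for fs in replicates:
        write_fragments(fs, outdir / "replicates" / f"{fs.replicate_id}.bed")
    for fs in controls:
        write_fragments(fs, outdir / "igg" / f"{fs.replicate_id}.bed")
    write_truth(truth, outdir / "truth.tsv")
    truth.config.genome.to_chrom_sizes(outdir / "genome.chrom.sizes")
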