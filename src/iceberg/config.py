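"""Run configuration: one flat, fully-explicit key set for the pipeline.

A run is described by a YAML file of flat keys; command-line flags
override file values, which override package defaults. Unknown keys
are rejected with a nearest-key suggestion. The resolved configuration
(every default materialized) is serialized into each output directory,
so any run can be reproduced from its output alone.
"""

from __future__ import annotations

import dataclasses
import difflib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .calling import PeakCallParams
from .core import IcebergConfig
from .genome import GenomeModel
from .simulate import SyntheticConfig

__all__ = ["RunConfig", "ConfigError", "resolve_config"]


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All pipeline parameters, flat. Defaults are the standard study
    conditions (3 splits, 2-of-3 majority, q<0.05 aggregates, p<0.01
    support, 5 build-curve orders, polynomial order up to 5)."""

    seed: int = 1234
    outdir: str = "iceberg_out"
    # --- simulation ---
    genome_length: int = 2_000_000
    n_sites: int = 200
    site_width: int = 300
    signal_fragments_mean: float = 40.0
    background_fragments: int = 50_000
    n_hotspots: int = 3
    hotspot_fragments_mean: float = 60.0
    n_replicates: int = 25
    n_igg: int = 10
    fragment_length_mean: float = 170.0
    fragment_length_sd: float = 30.0
    fragment_length_min: int = 50
    depth_jitter_low: float = 0.8
    depth_jitter_high: float = 1.2
    probability_mixture: list = field(
        default_factory=lambda: [[0.25, 0.8, 1.0], [0.75, 0.02, 0.3]]
    )
    # --- caller ---
    window: int = 50
    step: int = 25
    local_scales: list = field(default_factory=lambda: [1000, 10000])
    merge_gap: int = 100
    min_length: int = 50
    pseudocount: float = 0.5
    # --- aggregation / decision rule ---
    n_splits: int = 3
    majority_min: int = 2
    aggregate_q: float = 0.05
    support_p: float = 0.01
    depth: int | None = None  # None -> min replicate depth
    igg_downsample: int | None = None  # None -> min(5e6, pooled IgG depth)
    # --- build curves / saturation ---
    n_orders: int = 5
    max_order: int = 5
    selection: str = "delta_r2"
    horizon: float | None = None
    # --- benchmarking ---
    n_triplicates: int = 50

    def caller_params(self) -> PeakCallParams:
        return PeakCallParams(
            window=self.window,
            step=self.step,
            local_scales=tuple(self.local_scales),
            merge_gap=self.merge_gap,
            min_length=self.min_length,
            pseudocount=self.pseudocount,
        )

    def iceberg_config(self) -> IcebergConfig:
        return IcebergConfig(
            aggregate_mode="q",
            aggregate_cutoff=self.aggregate_q,
            support_mode="p",
            support_cutoff=self.support_p,
            majority_min=self.majority_min,
            n_splits=self.n_splits,
            depth=self.depth,
            igg_downsample=self.igg_downsample,
            caller_params=self.caller_params(),
        )

    def synthetic_config(self) -> SyntheticConfig:
        return SyntheticConfig(
            genome=GenomeModel([("chrSim", self.genome_length)]),
            n_sites=self.n_sites,
            probability_mixture=tuple(
                tuple(component) for component in self.probability_mixture
            ),
            site_width=self.site_width,
            signal_fragments_mean=self.signal_fragments_mean,
            fragment_length_mean=self.fragment_length_mean,
            fragment_length_sd=self.fragment_length_sd,
            fragment_length_min=self.fragment_length_min,
            background_fragments=self.background_fragments,
            n_hotspots=self.n_hotspots,
            hotspot_fragments_mean=self.hotspot_fragments_mean,
            n_replicates=self.n_replicates,
            n_igg=self.n_igg,
            depth_jitter=(self.depth_jitter_low, self.depth_jitter_high),
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def dump(self, path: str | Path) -> None:
        with Path(path).open("w") as handle:
            yaml.safe_dump(self.to_dict(), handle, sort_keys=True)


_VALID_KEYS = {f.name for f in dataclasses.fields(RunConfig)}


def _check_keys(mapping: dict, source: str) -> None:
    for key in mapping:
        if key not in _VALID_KEYS:
            hint = difflib.get_close_matches(key, sorted(_VALID_KEYS), n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ConfigError(f"unknown config key {key!r} in {source}{suggestion}")


def resolve_config(
    path: str | Path | None = None, overrides: dict | None = None
) -> RunConfig:
    """Materialize a fully explicit RunConfig.

    Precedence: flag overrides > file values > defaults. ``overrides``
    entries that are None are ignored (unset flags).
    """
    values: dict = {}
    if path is not None:
        with Path(path).open() as handle:
            loaded = yaml.safe_load(handle) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a mapping of keys to values")
        _check_keys(loaded, str(path))
        values.update(loaded)
    if overrides:
        cleaned = {k: v for k, v in overrides.items() if v is not None}
        _check_keys(cleaned, "command-line overrides")
        values.update(cleaned)
    try:
        return RunConfig(**values)
    except TypeError as exc:
        raise ConfigError(str(exc)) from None
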