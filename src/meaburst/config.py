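"""Run configuration: schema-checked nested config for the CLI pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .bursts import BurstDetectionConfig
from .connectivity import ConnectivityConfig
from .core import ElectrodeGrid
from .errors import ConfigError
from .protocol import ResponseWindow, StimulationProtocol
from .synthetic import SimulationConfig

__all__ = ["RunConfig", "load_config"]


@dataclass(frozen=True)
class LocalizationConfig:
    min_defined_trials: int = 8
    significance_alpha: float | None = 0.05
    isi_bin_width: float = 10.0
    isi_max: float = 1000.0


@dataclass(frozen=True)
class AssociationConfig:
    link_radius: float = 115.0
    percentile_keep: float = 0.9
    cluster_radius: float = 81.0


@dataclass(frozen=True)
class PipelineConfig:
    pre_duration_ms: float = 120_000.0
    post_duration_ms: float = 120_000.0
    learning_center: tuple = (8, 8)
    learning_radius: float = 4.5  # in pitch units
    n_hub_sites: int = 2
    max_graph_nodes: int = 120
    graph_n_nulls: int = 20


# Defaults here favour a quick end-to-end run on a reduced grid; pass a config
# file to scale any block up to the full 64x64 geometry.
@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    grid: ElectrodeGrid = field(default_factory=lambda: ElectrodeGrid(n_rows=24, n_cols=24))
    protocol: StimulationProtocol = field(default_factory=StimulationProtocol)
    window: ResponseWindow = field(default_factory=ResponseWindow)
    simulation: SimulationConfig = field(default_factory=lambda: SimulationConfig(burst_sites=((6, 6),)))
    burst_detection: BurstDetectionConfig = field(default_factory=BurstDetectionConfig)
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)
    localization: LocalizationConfig = field(default_factory=LocalizationConfig)
    association: AssociationConfig = field(default_factory=AssociationConfig)
    pipeline: PipelineConfig = field(default_factory=PipelineConfig)

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, (list, tuple)):
                return [enc(x) for x in obj]
            if isinstance(obj, frozenset):
                return sorted(obj)
            return obj

        return enc(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_BLOCKS = {
    "grid": ElectrodeGrid,
    "protocol": StimulationProtocol,
    "window": ResponseWindow,
    "simulation": SimulationConfig,
    "burst_detection": BurstDetectionConfig,
    "connectivity": ConnectivityConfig,
    "localization": LocalizationConfig,
    "association": AssociationConfig,
    "pipeline": PipelineConfig,
}

_TUPLE_FIELDS = {"burst_sites", "learning_set", "stim_electrode_pair", "burst_len_range", "learning_center"}


def _build_block(cls, mapping: dict, block: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ConfigError(f"unknown key(s) in '{block}': {', '.join(sorted(unknown))}")
    kwargs = {}
    for k, v in mapping.items():
        if k in _TUPLE_FIELDS and isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[k] = v
    return cls(**kwargs)


def config_from_mapping(data: dict) -> RunConfig:
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(data) - set(_BLOCKS) - {"seed"}
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {', '.join(sorted(unknown))}")
    kwargs: dict = {}
    if "seed" in data:
        kwargs["seed"] = int(data["seed"])
    for block, cls in _BLOCKS.items():
        if block in data:
            kwargs[block] = _build_block(cls, dict(data[block]), block)
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration; unknown keys are rejected."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) or {}
    return config_from_mapping(data)
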