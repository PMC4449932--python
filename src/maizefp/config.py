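"""YAML scenario configuration for end-to-end runs.

A scenario bundles the generator, caller, QC and selection settings plus
the global seed. Unknown keys are rejected so typos fail loudly, and a
config round-trips through serialization unchanged.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .locusqc import QcThresholds
from .panelselect import SelectionConfig
from .signalmodel import ClusterBuildConfig
from .simdata import DEFAULT_DEFECT_FRACTIONS

__all__ = ["SimdataConfig", "ScenarioConfig", "load_scenario", "save_scenario"]


def _from_mapping(cls, data: dict, context: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"{context}: unknown keys {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class SimdataConfig:
    """Generator settings for one scenario."""

    n_loci: int = 2000
    n_chromosomes: int = 10
    defect_fractions: dict = field(default_factory=lambda: dict(DEFAULT_DEFECT_FRACTIONS))
    n_inbreds_per_group: int = 8
    n_hybrids: int = 40
    n_triplets: int = 22
    n_duplicates: int = 2
    purity: float = 1.0
    theta_sd: float = 0.02


@dataclass(frozen=True)
class ScenarioConfig:
    seed: int = 0
    output_dir: str = "maizefp_out"
    log_level: str = "INFO"
    simdata: SimdataConfig = field(default_factory=SimdataConfig)
    signalmodel: ClusterBuildConfig = field(default_factory=ClusterBuildConfig)
    locusqc: QcThresholds = field(default_factory=QcThresholds)
    panelselect: SelectionConfig = field(default_factory=SelectionConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        data = dict(data)
        allowed = {f.name for f in fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"scenario: unknown keys {sorted(unknown)}")
        for key, sub_cls in (("simdata", SimdataConfig),
                             ("signalmodel", ClusterBuildConfig),
                             ("locusqc", QcThresholds),
                             ("panelselect", SelectionConfig)):
            if key in data and isinstance(data[key], dict):
                data[key] = _from_mapping(sub_cls, data[key], key)
        return cls(**data)


def load_scenario(path) -> ScenarioConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: scenario config must be a mapping")
    return ScenarioConfig.from_dict(data)


def save_scenario(config: ScenarioConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True),
                          encoding="utf-8")
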