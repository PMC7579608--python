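"""Pipeline configuration: defaults, YAML round-trip, config hashing.

Defaults encode the analysis protocol: 125 Hz analysis rate, 2--20 Hz
band-pass with 60 Hz notch, 2 s epochs, the first 10 artifact-free epochs
per condition, four microstate classes, post hoc α = 0.0125.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class ResampleConfig:
    fs: float = 125.0


@dataclass
class FilterConfig:
    lo: float = 2.0
    hi: float = 20.0
    notch: float = 60.0


@dataclass
class EpochConfig:
    s: float = 2.0


@dataclass
class ArtifactConfig:
    amp_uv: float = 200.0
    flat_uv: float = 0.5
    max_bad_frac: float = 0.1


@dataclass
class MicrostateConfig:
    n_states: int = 4
    min_peak_sep: int = 1
    #: backfit with one shared template set instead of per-cell group maps
    shared_maps: bool = False


@dataclass
class ParamsConfig:
    include_truncated: bool = False


@dataclass
class StatsConfig:
    alpha: float = 0.05
    posthoc_alpha: float = 0.0125
    equal_var: bool = True


@dataclass
class SimulateConfig:
    n_per_group: int = 13
    n_epochs: int = 10
    n_channels: int = 32
    snr: float = 2.0


@dataclass
class PipelineConfig:
    """All settings of the end-to-end analysis, serializable to YAML."""

    resample: ResampleConfig = field(default_factory=ResampleConfig)
    filter: FilterConfig = field(default_factory=FilterConfig)
    epoch: EpochConfig = field(default_factory=EpochConfig)
    artifact: ArtifactConfig = field(default_factory=ArtifactConfig)
    microstates: MicrostateConfig = field(default_factory=MicrostateConfig)
    params: ParamsConfig = field(default_factory=ParamsConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    n_epochs: int = 10
    seed: int = 0

    _SECTIONS = {
        "resample": ResampleConfig,
        "filter": FilterConfig,
        "epoch": EpochConfig,
        "artifact": ArtifactConfig,
        "microstates": MicrostateConfig,
        "params": ParamsConfig,
        "stats": StatsConfig,
        "simulate": SimulateConfig,
    }

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        payload = dict(payload or {})
        known = set(cls._SECTIONS) | {"n_epochs", "seed"}
        unknown = set(payload) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = {}
        for name, section_cls in cls._SECTIONS.items():
            if name in payload:
                section = payload[name]
                if not isinstance(section, dict):
                    raise ConfigError(f"config section {name!r} must be a mapping")
                sec_fields = {f.name for f in dataclasses.fields(section_cls)}
                bad = set(section) - sec_fields
                if bad:
                    raise ConfigError(
                        f"unknown config key(s) in {name!r}: {sorted(bad)}"
                    )
                kwargs[name] = section_cls(**section)
        for name in ("n_epochs", "seed"):
            if name in payload:
                kwargs[name] = payload[name]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(payload)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def hash(self) -> str:
        """Stable short hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
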