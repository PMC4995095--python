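"""Pipeline configuration: TOML parsing, strict validation, config hashing.

One TOML file configures all stages.  Sections map onto the stage configs
(``[session]``, ``[scoring]``, ``[spindles]``, ``[jitter]``, ``[infusion]``)
plus global fields ``seed``, ``alpha`` (0.05) and ``band_alpha`` (0.01).
Unknown keys are rejected so typos fail loudly instead of silently using a
default.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError
from .infusion import InfusionDesign
from .scoring import ScoringConfig
from .spindles import SpindleCriteria
from .synth import SessionConfig
from .perievent import JitterSpec

__all__ = ["PipelineConfig", "load_config", "config_hash"]


def _build(cls, section: dict, name: str):
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in [{name}]: {sorted(unknown)}")
    coerced = {}
    for k, v in section.items():
        coerced[k] = tuple(v) if isinstance(v, list) and k.endswith(("_hz", "_s")) and len(v) == 2 else v
    try:
        return cls(**coerced)
    except TypeError as e:  # pragma: no cover - defensive
        raise ConfigError(f"invalid [{name}] section: {e}") from e


@dataclass
class PipelineConfig:
    session: SessionConfig = field(default_factory=SessionConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    spindles: SpindleCriteria = field(default_factory=SpindleCriteria)
    jitter: JitterSpec = field(default_factory=JitterSpec)
    infusion: InfusionDesign = field(default_factory=InfusionDesign)
    seed: int = 0
    alpha: float = 0.05
    band_alpha: float = 0.01

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1) or not (0 < self.band_alpha < 1):
            raise ConfigError("alpha and band_alpha must lie in (0, 1)")
        self.session.seed = int(self.seed) if self.seed else self.session.seed
        self.jitter.alpha = self.band_alpha

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sections = {
            "session": SessionConfig,
            "scoring": ScoringConfig,
            "spindles": SpindleCriteria,
            "jitter": JitterSpec,
            "infusion": InfusionDesign,
        }
        kwargs = {}
        for name, klass in sections.items():
            if name in raw:
                kwargs[name] = _build(klass, raw.pop(name), name)
        globals_allowed = {"seed", "alpha", "band_alpha"}
        unknown = set(raw) - globals_allowed
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        kwargs.update(raw)
        return cls(**kwargs)


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    with open(path, "rb") as f:
        raw = tomllib.load(f)
    return PipelineConfig.from_dict(raw)


def config_hash(cfg: PipelineConfig) -> str:
    """Short stable hash of the full configuration, embedded in every output."""
    blob = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]
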