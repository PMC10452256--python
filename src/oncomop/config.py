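"""Pipeline configuration: one declarative YAML file, CLI overrides.

All randomness in a run flows from the single ``seed``; every artifact
is reproducible from (inputs, config, seed) alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


@dataclass
class PipelineConfig:
    vocab_dir: Path | None = None
    source_dir: Path | None = None
    out_dir: Path = Path("omop_out")
    manual_mapping_file: Path | None = None
    regimen_reference: Path | None = None
    substance_rules: Path | None = None
    window_days: int = 30
    gap_days: int = 30
    unmapped_rate_threshold: float = 0.5
    delimiter: str = ","
    overall_disease_episodes: bool = False
    seed: int = 0
    n_patients: int = 300

    def __post_init__(self) -> None:
        for name in ("vocab_dir", "source_dir", "out_dir", "manual_mapping_file",
                     "regimen_reference", "substance_rules"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))
        if self.window_days < 0 or self.gap_days < 0:
            raise ConfigError("window_days and gap_days must be non-negative")
        if not 0.0 <= self.unmapped_rate_threshold <= 1.0:
            raise ConfigError("unmapped_rate_threshold must lie in [0, 1]")
        if self.n_patients < 0:
            raise ConfigError("n_patients must be non-negative")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    def require(self, *names: str) -> None:
        """Check that the named paths are configured and exist."""
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise ConfigError(f"config is missing required path {name!r}")
            if not Path(value).exists():
                raise ConfigError(f"configured {name} does not exist: {value}")
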