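"""Pipeline configuration: YAML-backed nested sections with validation."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["ConfigError", "PipelineConfig", "load_config", "stage_seed"]

REQUIRED_SECTIONS = (
    "landscape",
    "rsf",
    "telemetry",
    "ranges",
    "design",
    "forest",
    "interpret",
    "validation",
)


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


@dataclass
class PipelineConfig:
    base_seed: int
    output_dir: str
    landscape: dict = field(default_factory=dict)
    rsf: dict = field(default_factory=dict)
    telemetry: dict = field(default_factory=dict)
    ranges: dict = field(default_factory=dict)
    design: dict = field(default_factory=dict)
    forest: dict = field(default_factory=dict)
    interpret: dict = field(default_factory=dict)
    validation: dict = field(default_factory=dict)

    def section(self, name: str) -> dict:
        return getattr(self, name)


def load_config(path) -> PipelineConfig:
    """Parse and validate a YAML pipeline config file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    if "base_seed" not in raw:
        raise ConfigError("config is missing required key 'base_seed'")
    missing = [s for s in REQUIRED_SECTIONS if s not in raw]
    if missing:
        raise ConfigError(
            f"config is missing required section(s): {', '.join(missing)}"
        )
    return PipelineConfig(
        base_seed=int(raw["base_seed"]),
        output_dir=str(raw.get("output_dir", "habsel_out")),
        **{s: dict(raw[s] or {}) for s in REQUIRED_SECTIONS},
    )


def stage_seed(base_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SHA-256 of ``"{base_seed}:{stage}"``."""
    digest = hashlib.sha256(f"{base_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big")
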