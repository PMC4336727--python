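"""Pipeline configuration: one flat key-value file, flags win over file.

The config carries every tunable of the pipeline; ``seed`` is mandatory so
each run is reproducible, and the effective configuration's hash is embedded
in every output file for auditability.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .image_io import DEFAULT_TIMESTAMP_PATTERN

__all__ = ["PipelineConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PipelineConfig:
    seed: int
    grid_spacing: int = 15
    radii: tuple[int, ...] = (4, 6, 8, 10)
    k: int = 600
    kmeans_restarts: int = 8
    svm_C: float = 1.0
    map_order: int = 2
    map_period: float = 0.5
    window_px: int = 140
    connectivity: int = 8
    normalize_histograms: bool = True
    timestamp_pattern: str = DEFAULT_TIMESTAMP_PATTERN

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ConfigError(f"connectivity must be 4 or 8, got {self.connectivity}")
        if self.seed is None:
            raise ConfigError("seed is required")
        object.__setattr__(self, "radii", tuple(int(r) for r in self.radii))

    def grid(self):
        from .features import GridSpec

        return GridSpec(spacing=self.grid_spacing, radii=self.radii)

    @property
    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def stamp(self) -> str:
        """Audit line embedded as a comment in every output file."""
        return f"config_hash={self.hash} seed={self.seed}"


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Read the flat YAML key-value file, apply overrides, reject unknown keys."""
    values: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must be a flat key-value mapping")
        values.update(raw)
    values.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(values) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in values:
        raise ConfigError("config must provide a seed")
    if isinstance(values.get("radii"), str):
        values["radii"] = tuple(int(t) for t in values["radii"].split(","))
    return PipelineConfig(**values)
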