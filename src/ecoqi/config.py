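"""Pipeline configuration: validated, serializable, reproducible.

A :class:`PipelineConfig` fully determines a composite-index run: input
manifest, normalization shift/scale, PCA fitting scope and seed, composite
period and output directory.  Unknown keys are rejected at load time so a
typo never silently changes a run, and the full config is serialized into
every run's provenance sidecar.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigurationError

__all__ = ["PipelineConfig", "load_config"]


class SensorOverrides(BaseModel):
    """Optional overrides of the per-sensor physical constants."""

    model_config = ConfigDict(extra="forbid")

    thermal_wavelength_um: float | None = None


class PipelineConfig(BaseModel):
    """Everything a composite-index run needs, in one validated object."""

    model_config = ConfigDict(extra="forbid")

    manifest: str
    out_dir: str = "ecoqi-run"
    # normalization shift c and scale d of the min-max transform
    c: float = 0.0
    d: float = Field(default=1.0, gt=0)
    pca_scope: Literal["per_date", "global"] = "per_date"
    seed: int = 0
    sample_limit: int = Field(default=2_000_000, gt=1)
    period: Literal["year", "season", "month", "all"] = "all"
    min_obs: int = Field(default=1, ge=1)
    celsius: bool = False
    tm_overrides: SensorOverrides = Field(default_factory=SensorOverrides)
    oli_overrides: SensorOverrides = Field(default_factory=SensorOverrides)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML config file; unknown keys are errors."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    try:
        return PipelineConfig(**raw)
    except ValidationError as exc:
        raise ConfigurationError(f"invalid pipeline config {path}: {exc}") from exc
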