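"""Run configuration: a validated schema for simulation/reconstruction runs.

Every CLI run resolves to a :class:`RunConfig`, which is validated before
any computation and logged (YAML) next to the outputs so runs are
reproducible from the recorded config plus the seed.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator

from .errors import ConfigError

__all__ = ["GeometryConfig", "SweepConfig", "GridConfig", "RunConfig", "load_config"]


class GeometryConfig(BaseModel):
    n_antennas: int = Field(16, ge=2)
    diameter_mm: float = Field(340.0, gt=0)
    eps_r: float = Field(1.0, ge=1.0)


class SweepConfig(BaseModel):
    f_start_hz: float = Field(1.2e9, gt=0)
    f_stop_hz: float = Field(5.0e9, gt=0)
    n_points: int = Field(191, ge=2)

    @model_validator(mode="after")
    def _ordered(self):
        if self.f_stop_hz <= self.f_start_hz:
            raise ValueError("f_stop_hz must exceed f_start_hz")
        return self


class GridConfig(BaseModel):
    width_mm: float = Field(250.0, gt=0)
    height_mm: float = Field(250.0, gt=0)
    pitch_mm: float = Field(1.0, gt=0)


class RunConfig(BaseModel):
    geometry: GeometryConfig = GeometryConfig()
    sweep: SweepConfig = SweepConfig()
    grid: GridConfig = GridConfig()
    algorithm: Literal["DAS", "DMAS", "both"] = "both"
    window: str = "hann"
    zero_pad_factor: int = Field(4, ge=1)
    t_win_percent: float = Field(100.0, gt=0)
    threshold: float = Field(0.8, ge=0.0, le=1.0)
    noise_sd: float = Field(0.0, ge=0.0)
    seed: int | None = None

    def dump_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML run config (or defaults) with keyword overrides."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    try:
        return RunConfig(**data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc
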