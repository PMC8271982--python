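"""Application configuration: YAML file validated against a strict schema.

Unknown keys are rejected so typos fail loudly.  The JSON schema exported
by ``AppConfig.model_json_schema()`` is kept in ``docs/config.schema.json``;
``docs/config.example.yaml`` is a commented example.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

__all__ = ["AppConfig", "load_config"]


class PathsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    data: str = "data"
    models: str = "models"
    reports: str = "reports"


class TrainingOverrides(BaseModel):
    model_config = ConfigDict(extra="forbid")
    epochs: int | None = Field(None, ge=1)
    batch_size: int | None = Field(None, ge=1)
    learning_rate: float | None = Field(None, gt=0)
    momentum: float | None = Field(None, ge=0, lt=1)
    weight_decay: float | None = Field(None, ge=0)
    runs: int | None = Field(None, ge=1)


class ProtocolOverrides(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_subjects: int | None = Field(None, ge=1)
    n_frames: int | None = Field(None, ge=32)
    sigma: float | None = Field(None, ge=0, le=0.02)


class AppConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    paths: PathsConfig = PathsConfig()
    ordering: str = "B1"
    window_length: int = Field(32, ge=1)
    window_stride: int = Field(1, ge=1)
    training: TrainingOverrides = TrainingOverrides()
    protocol: ProtocolOverrides = ProtocolOverrides()
    log_level: str = "INFO"

    def training_config(self, **extra):
        from .nn.model import TrainingConfig

        overrides = {
            k: v for k, v in self.training.model_dump().items() if v is not None
        }
        overrides.update(extra)
        return TrainingConfig(**overrides)


def load_config(path: str | Path | None) -> AppConfig:
    if path is None:
        return AppConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return AppConfig.model_validate(raw)
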