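"""Pipeline configuration: a schema-validated YAML config with named presets."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class VolumeConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    droplet_volume_nl: float = 0.85
    reaction_template_volume_ul: float = 2.0
    elution_volume_ul: float = 20.0
    plasma_volume_ml: float = 0.9


class PathsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    workdir: str = "cfmethyl_run"
    beta_tsv: str | None = None
    sample_sheet_csv: str | None = None
    roster_csv: str | None = None
    droplet_csv: str | None = None
    feature_csv: str | None = None
    model_state_json: str | None = None


class PipelineConfig(BaseModel):
    """Schema-validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    preset: str = "toy"
    seed: int = 0
    epsilon: float | None = None
    c_param: float = 1.0
    amplitude_grid: int = 64
    search_variables: list[str] | None = None
    volumes: VolumeConfig = Field(default_factory=VolumeConfig)
    paths: PathsConfig = Field(default_factory=PathsConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    def config_hash(self) -> str:
        canon = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


PRESETS = ("table1_cohort", "toy")


def preset_config(name: str, seed: int = 0) -> PipelineConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {PRESETS}")
    return PipelineConfig(preset=name, seed=seed)
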