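"""Pipeline configuration: nested, validated, YAML round-trippable.

Defaults throughout are the study values (bSQI 0.8, 10 s / 25% missing
rules, 75% noise rule, the published architecture hyperparameters, the
4% patient decision threshold).  Unknown keys are rejected.
"""
from __future__ import annotations

import hashlib
from typing import List, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class PreprocessConfig(_Strict):
    agreement_ms: float = Field(50.0, gt=0)


class WindowConfig(_Strict):
    bsqi_min: float = Field(0.8, ge=0.0, le=1.0)
    missing_max_s: float = Field(10.0, ge=0.0)
    patient_missing_max: float = Field(0.25, ge=0.0, le=1.0)
    noise_max: float = Field(0.75, ge=0.0, le=1.0)


class ModelSection(_Strict):
    n_b: int = Field(5, ge=1)
    n_f: int = Field(64, ge=1)
    f_l: int = Field(10, ge=1)
    d_r1: float = Field(0.2, ge=0.0, lt=1.0)
    d_r2: float = Field(0.5, ge=0.0, lt=1.0)
    n_d: int = Field(512, ge=1)
    n_dense: int = Field(3, ge=1)
    h: int = Field(6, ge=0)
    lr: float = Field(1e-2, gt=0)
    pos_weight: Optional[float] = Field(None, gt=0)
    early_stop_min_delta: float = Field(0.001, ge=0)
    early_stop_patience: int = Field(5, ge=1)
    gru_units: int = Field(64, ge=1)
    stage2_dense: int = Field(64, ge=1)
    max_grad_norm: Optional[float] = Field(1.0, gt=0)
    max_epochs: int = Field(30, ge=1)
    batch_size: int = Field(128, ge=1)
    train_fraction: float = Field(0.6, gt=0, lt=1)
    val_fraction: float = Field(0.2, gt=0, lt=1)


class MetricsConfig(_Strict):
    strata: List[str] = Field(default_factory=lambda: ["sex", "age_bin"])


class SimulateConfig(_Strict):
    n_patients: int = Field(40, ge=1)
    duration_h: float = Field(2.0, gt=0)
    episode_rhythm: str = "AF"
    min_episode_s: float = Field(60.0, gt=0)
    max_episode_s: float = Field(900.0, gt=0)
    at_fraction_of_patients: float = Field(0.5, ge=0.0, le=1.0)
    at_burden: float = Field(0.05, ge=0.0, le=1.0)
    unknown_fraction: float = Field(0.0, ge=0.0, le=1.0)

    @field_validator("episode_rhythm")
    @classmethod
    def _known_rhythm(cls, v):
        if v not in ("AF", "AFL", "AT"):
            raise ValueError(f"unknown episode rhythm {v!r}")
        return v


class PipelineConfig(_Strict):
    seed: int = 0
    log_level: str = "INFO"
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    window: WindowConfig = Field(default_factory=WindowConfig)
    model: ModelSection = Field(default_factory=ModelSection)
    metrics: MetricsConfig = Field(default_factory=MetricsConfig)
    simulate: SimulateConfig = Field(default_factory=SimulateConfig)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text) or {}
        return cls.model_validate(data)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path) as f:
            return cls.from_yaml(f.read())

    def config_hash(self) -> str:
        """Stable digest stamped onto every artifact for provenance."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
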