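"""Validated pipeline configuration.

All stage constants live in one auditable place: filter band and order,
alignment search window, QC retention bounds, model hyperparameters and
split ratios.  Unknown keys are rejected (typo safety) and every
out-of-range value is reported in one validation error.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator
import yaml


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class SynthSection(_Section):
    n_subjects: int = Field(default=100, ge=1)
    segments_per_subject: int = Field(default=20, ge=1)
    segment_len: int = Field(default=300, ge=8)
    heart_rate_bpm: float = Field(default=75.0, gt=30, lt=200)
    hr_jitter: float = Field(default=0.02, ge=0, lt=0.2)
    noise_sd: float = Field(default=0.01, ge=0)
    baseline_wander_amp: float = Field(default=0.05, ge=0)
    corrupt_frac: float = Field(default=0.0, ge=0, le=1)


class PreprocessSection(_Section):
    low_hz: float = Field(default=0.5, gt=0)
    high_hz: float = Field(default=8.0, gt=0)
    order: int = Field(default=3, ge=1)
    max_lag: int = Field(default=72, ge=1)

    @model_validator(mode="after")
    def _band_ordered(self):
        if self.low_hz >= self.high_hz:
            raise ValueError("low_hz must be below high_hz")
        return self


class QCSection(_Section):
    sbp_max: float = 180.0
    sbp_min: float = 80.0
    dbp_max: float = 130.0
    dbp_min: float = 60.0
    min_r: float = Field(default=0.8, le=1.01)


class ModelSection(_Section):
    encoder_layers: int = Field(default=2, ge=1)
    decoder_layers: int = Field(default=2, ge=1)
    hidden_units: int = Field(default=128, ge=1)
    dropout_rate: float = Field(default=0.2, ge=0, lt=1)
    learning_rate: float = Field(default=0.0025, gt=0)
    max_epochs: int = Field(default=50, ge=0)
    batch_size: int = Field(default=128, ge=1)
    patience: int = Field(default=5, ge=0)


class SplitSection(_Section):
    train: float = Field(default=0.7, gt=0, lt=1)
    val: float = Field(default=0.1, ge=0, lt=1)
    test: float = Field(default=0.2, gt=0, lt=1)

    @model_validator(mode="after")
    def _sums_to_one(self):
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("train + val + test fractions must sum to 1")
        return self


class PipelineConfig(_Section):
    """Full pipeline configuration; defaults reproduce the reference
    constants (0.5–8 Hz order-3 band, 80/180 and 60/130 mmHg bounds,
    r >= 0.8, 128 hidden units, dropout 0.2, lr 0.0025, 50 epochs,
    70/10/20 split)."""

    seed: int = 0
    synth: SynthSection = Field(default_factory=SynthSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    qc: QCSection = Field(default_factory=QCSection)
    model: ModelSection = Field(default_factory=ModelSection)
    split: SplitSection = Field(default_factory=SplitSection)


class ConfigError(ValueError):
    pass


def validate_config(raw: str | dict | None) -> PipelineConfig:
    """Parse and validate a YAML/dict config; missing keys take defaults."""
    if raw is None:
        data = {}
    elif isinstance(raw, str):
        data = yaml.safe_load(raw) or {}
    else:
        data = raw
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping of sections")
    try:
        return PipelineConfig(**data)
    except ValidationError as err:
        issues = "; ".join(
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()
        )
        raise ConfigError(f"invalid configuration: {issues}") from err
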