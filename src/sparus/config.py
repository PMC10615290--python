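"""Run configuration: validated, YAML round-trippable, with deterministic
per-stage seed derivation from one global seed."""

from __future__ import annotations

import zlib

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, ValidationError as PydanticValidationError

from .acquisition import ValidationError

__all__ = [
    "ArrayConfig",
    "SequenceConfig",
    "GridConfig",
    "RUNetTrainConfig",
    "DatasetConfig",
    "MetricsConfig",
    "RunConfig",
    "validate_config",
    "stage_seed",
]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class ArrayConfig(_Strict):
    n_elements: int = Field(default=128, ge=2)
    pitch: float = Field(default=70e-6, gt=0)
    center_freq: float = Field(default=28e6, gt=0)
    frac_bandwidth: float = Field(default=0.6, gt=0, lt=2)


class SequenceConfig(_Strict):
    n_angles: int = Field(default=7, ge=1)
    angle_min: float = -15.0
    angle_max: float = 15.0
    sound_speed: float = Field(default=1480.0, gt=0)
    sampling_rate: float = Field(default=62.5e6, gt=0)
    prf: float = Field(default=5e3, gt=0)

    def angles(self) -> list[float]:
        if self.n_angles == 1:
            return [0.5 * (self.angle_min + self.angle_max)]
        return list(np.linspace(self.angle_min, self.angle_max, self.n_angles))


class GridConfig(_Strict):
    n_rows: int = Field(default=512, ge=2)
    n_cols: int = Field(default=512, ge=2)
    lateral_min: float = -4.48e-3
    lateral_max: float = 4.48e-3
    depth_min: float = Field(default=0.5e-3, gt=0)
    depth_max: float = 15e-3


class RUNetTrainConfig(_Strict):
    depth: int = Field(default=4, ge=1)
    base_channels: int = Field(default=32, ge=1)
    epochs: int = Field(default=50, ge=0)
    batch_size: int = Field(default=8, ge=1)
    learning_rate: float = Field(default=1e-4, gt=0)
    pixel_weight: float = Field(default=1.0, ge=0)
    perceptual_weight: float = Field(default=0.1, ge=0)
    global_residual: bool = True


class DatasetConfig(_Strict):
    n_pairs: int = Field(default=60, ge=1)
    n_test: int = Field(default=0, ge=0)
    factors: list[int] = Field(default_factory=lambda: [8])
    image_size: int = Field(default=128, ge=16)
    val_fraction: float = Field(default=0.2, gt=0, lt=1)
    dynamic_range_db: float = Field(default=50.0, gt=0)
    scatterer_density: float = Field(default=20.0, gt=0)


class MetricsConfig(_Strict):
    i_max: float = Field(default=255.0, gt=0)


class RunConfig(_Strict):
    seed: int = 0
    out_dir: str = "runs/out"
    log_level: str = "INFO"
    array: ArrayConfig = Field(default_factory=ArrayConfig)
    sequence: SequenceConfig = Field(default_factory=SequenceConfig)
    grid: GridConfig = Field(default_factory=GridConfig)
    runet: RUNetTrainConfig = Field(default_factory=RUNetTrainConfig)
    dataset: DatasetConfig = Field(default_factory=DatasetConfig)
    metrics: MetricsConfig = Field(default_factory=MetricsConfig)

    def to_dict(self) -> dict:
        return self.model_dump()


def validate_config(raw: dict | None) -> RunConfig:
    """Parse a raw mapping into a RunConfig, injecting defaults.

    Unknown keys and type/range violations are rejected with an aggregated
    report naming each offending location (e.g. ``array.pitch``).
    """
    try:
        return RunConfig.model_validate(raw or {})
    except PydanticValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<root>"
            lines.append(f"{loc}: {err['msg']}")
        raise ValidationError("invalid configuration:\n  " + "\n  ".join(lines)) from exc


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: adding stages never perturbs earlier streams."""
    ss = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1, dtype=np.uint32)[0])
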