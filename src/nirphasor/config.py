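"""Schema-validated run configuration for the command-line pipelines."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .camera import CameraModel
from .optics import RetarderModel, SpectralWindow

__all__ = ["WindowConfig", "CameraConfig", "RetarderConfig", "RunConfig",
           "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class WindowConfig(_Strict):
    lambda_min: float = 900.0
    lambda_max: float = 1600.0

    def build(self) -> SpectralWindow:
        return SpectralWindow(self.lambda_min, self.lambda_max)


class CameraConfig(_Strict):
    gain: float = 1.1e-3
    read_noise_var: float = 1000.0
    quantization_var: float = 1.0 / 12.0
    quantum_efficiency: float = 0.56
    pixel_area: float = 9e-6
    exposure: float = 3.0
    bit_depth: int = 12
    dark_offset: float = 0.0

    def build(self) -> CameraModel:
        return CameraModel(**self.model_dump())


class RetarderConfig(_Strict):
    max_retardance: float | None = 10400.0

    def build(self) -> RetarderModel:
        return RetarderModel(max_retardance=self.max_retardance)


class SceneConfig(_Strict):
    shape: tuple[int, int] = (64, 64)
    species: list[str] = Field(default_factory=lambda: ["(6,5)", "(7,5)"])
    flux: float = 1e11
    profile: str = "uniform"


class TimeSeriesConfig(_Strict):
    frame_period: float = 5.0           # s per hyperspectral cube (0.2 s^-1)
    regression_window: float = 600.0    # s of trailing OLS history
    reference_period: float = 300.0     # s of dry-state reference
    normalization_percentile: float = 99.0


class PipelineConfig(_Strict):
    median_window: tuple[int, int] = (3, 3)
    min_total: float | None = None
    histogram_bins: int = 64


class RunConfig(_Strict):
    """Everything a reproducible run needs; unknown keys are rejected and
    a seed is mandatory for any stochastic step."""

    seed: int
    window: WindowConfig = Field(default_factory=WindowConfig)
    camera: CameraConfig = Field(default_factory=CameraConfig)
    retarder: RetarderConfig = Field(default_factory=RetarderConfig)
    scene: SceneConfig = Field(default_factory=SceneConfig)
    timeseries: TimeSeriesConfig = Field(default_factory=TimeSeriesConfig)
    pipeline: PipelineConfig = Field(default_factory=PipelineConfig)

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(raw)
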