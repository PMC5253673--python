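"""Validated pipeline configuration.

A single YAML document drives the whole pipeline; every field name carries
its unit (``ambient_c``, ``slope_c_per_mw``, ``pixel_size_um``) so that a
config file is unambiguous without external documentation.  The seed is
mandatory: every stochastic step derives its generator from it.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, model_validator

from .constants import (
    CALIBRATION_RANGE_C,
    HALF_DISTANCE_UM,
    HEAT_SHOCK_BAND_C,
    DEFAULT_LETHAL_TEMP_C,
    DEFAULT_TAU_MS,
    MCHERRY_SENSITIVITY_PER_C,
    REF_TEMP_C,
    SLOPE_TEXT_C_PER_MW,
)


class SceneConfig(BaseModel):
    image_shape: tuple[int, int] = (160, 160)
    pixel_size_um: float = Field(0.25, gt=0)
    cell_radius_um: float = Field(6.0, gt=0)
    base_fluorescence: float = Field(2000.0, gt=0)
    background_level: float = Field(100.0, ge=0)
    read_noise_sd: float = Field(3.0, ge=0)
    shot_noise: bool = True

    @model_validator(mode="after")
    def _check_contrast(self):
        if self.base_fluorescence <= self.background_level:
            raise ValueError("base_fluorescence must exceed background_level")
        return self


class GeneratorConfig(BaseModel):
    sensitivity_per_c: float = Field(MCHERRY_SENSITIVITY_PER_C, gt=0, lt=0.1)
    calibration_temps_c: list[float] = Field(
        default_factory=lambda: [15.0 + 2.5 * i for i in range(11)]
    )
    map_power_mw: float = Field(3.5, ge=0)
    measurement_powers_mw: list[float] = Field(default_factory=lambda: [2.0, 3.0, 4.0])
    n_cells_per_power: int = Field(40, ge=1)
    max_distance_um: float = Field(35.0, gt=0)
    measurement_noise_sd_c: float = Field(0.3, ge=0)
    scene: SceneConfig = SceneConfig()


class HeatModelConfig(BaseModel):
    slope_c_per_mw: float = Field(SLOPE_TEXT_C_PER_MW, gt=0)
    half_distance_um: float = Field(HALF_DISTANCE_UM, gt=0)
    ambient_c: float = REF_TEMP_C
    tau_ms: float = Field(DEFAULT_TAU_MS, gt=0)


class CalibrationConfig(BaseModel):
    ref_temp_c: float = REF_TEMP_C
    valid_range_c: tuple[float, float] = CALIBRATION_RANGE_C
    downsample_factor: int = Field(3, ge=1)


class PlannerConfig(BaseModel):
    threshold_band_c: tuple[float, float] = HEAT_SHOCK_BAND_C
    lethal_temp_c: float = DEFAULT_LETHAL_TEMP_C
    neighbor_distance_um: float = Field(11.0, gt=0)

    @model_validator(mode="after")
    def _check_band(self):
        if not self.threshold_band_c[0] < self.threshold_band_c[1]:
            raise ValueError("threshold band lower bound must be below upper")
        return self


class PipelineConfig(BaseModel):
    seed: int
    output_dir: Path = Path("irheat_out")
    generator: GeneratorConfig = GeneratorConfig()
    heat_model: HeatModelConfig = HeatModelConfig()
    calibration: CalibrationConfig = CalibrationConfig()
    planner: PlannerConfig = PlannerConfig()

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)
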