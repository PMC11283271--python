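"""Run configuration: validated YAML schema for the CLI workflows.

Every command validates its configuration against these models before
any computation and writes the fully resolved configuration next to its
results, so a run is reproducible from its output directory alone.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, field_validator

__all__ = ["RunConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised when a configuration fails schema validation."""


class GeometryConfig(BaseModel):
    pitch_x_um: float = Field(10.0, gt=0)
    pitch_y_um: float = Field(10.0, gt=0)
    pitch_z_um: float = Field(3.0, gt=0)


class OpticsConfig(BaseModel):
    lambda0_nm: float = Field(1050.0, gt=0)
    n_tissue: float = Field(1.38, ge=1.0)
    dt_s: float = Field(7.0 / 3000.0, gt=0)


class LandmarksConfig(BaseModel):
    roi: Optional[list[list[int]]] = None  # [[y0,y1],[z0,z1],[x0,x1]]
    schwalbe_point_um: Optional[list[float]] = None
    tm_plane_angle_deg: float = Field(60.0, ge=0.0, lt=180.0)
    tm_center: Optional[list[int]] = None  # [z, x]
    location_label: Optional[str] = None
    day_label: Optional[str] = None

    @field_validator("roi")
    @classmethod
    def _roi_shape(cls, v):
        if v is not None:
            if len(v) != 3 or any(len(b) != 2 for b in v):
                raise ValueError("roi must be three [lo, hi) index pairs")
            if any(b[1] <= b[0] or b[0] < 0 for b in v):
                raise ValueError("roi bounds must satisfy 0 <= lo < hi")
        return v

    @field_validator("schwalbe_point_um")
    @classmethod
    def _point_shape(cls, v):
        if v is not None and len(v) != 3:
            raise ValueError("schwalbe_point_um must have 3 components (y, z, x)")
        return v


class SegmentationConfig(BaseModel):
    threshold_method: Literal["otsu", "fixed"] = "otsu"
    fixed_threshold: Optional[float] = None
    cap_value: float = Field(50.0, gt=0)
    noise_floor: Optional[float] = None
    shadow_exclusion: bool = False
    shadow_keep_depth: int = Field(8, ge=0)
    min_component_voxels: int = Field(50, ge=1)
    closing_radius_vox: list[int] = [1, 1, 1]
    average_group_size: int = Field(1, ge=1)


class MotionConfig(BaseModel):
    filter_order: int = Field(20, ge=1)
    cutoff_hz: float = Field(6.0, gt=0)
    ellipse_semi_x_um: float = Field(25.0, gt=0)
    ellipse_semi_z_um: float = Field(7.5, gt=0)
    upsample_factor: int = Field(100, ge=1)
    detrend: bool = True
    registration: bool = True
    compensate: bool = True
    per_pixel_filter: bool = False


class StatsConfig(BaseModel):
    equal_var: bool = False
    scheme: Literal["by_day", "by_location"] = "by_location"
    holm: bool = False
    plots: bool = False


class RunConfig(BaseModel):
    """Top-level configuration shared by all subcommands."""

    input: Optional[str] = None
    input_imag: Optional[str] = None
    out_dir: str = "stentoct_out"
    seed: int = 0
    strict: bool = False
    geometry: GeometryConfig = GeometryConfig()
    optics: OpticsConfig = OpticsConfig()
    landmarks: LandmarksConfig = LandmarksConfig()
    segmentation: SegmentationConfig = SegmentationConfig()
    motion: MotionConfig = MotionConfig()
    stats: StatsConfig = StatsConfig()

    def resolved_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)


def load_config(path: str | Path | None, **overrides) -> RunConfig:
    """Load and validate a YAML config; keyword overrides win."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    for key, value in overrides.items():
        if value is not None:
            data[key] = value
    try:
        return RunConfig.model_validate(data)
    except Exception as exc:  # pydantic ValidationError
        raise ConfigError(str(exc)) from exc
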