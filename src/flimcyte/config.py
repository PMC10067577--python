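"""Pipeline configuration: one validated, versioned, JSON-serialisable object.

Unknown keys are rejected (a typo'd option should fail loudly, not be
ignored), every default is visible in one place, and a config echo plus the
seed is written next to every CLI output so any run can be regenerated.
"""

from __future__ import annotations

import json
from pathlib import Path

from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .exceptions import ConfigError
from .fitting import FitConfig
from .features import FeaturesConfig
from .segmentation import SegmentationConfig, default_threshold_specs

__all__ = ["PipelineConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class FitSection(_Strict):
    min_photons: float = 100.0
    binning: int = Field(default=3, description="odd moving-window photon pooling size")
    irf_center_ps: float | None = None
    irf_fwhm_ps: float = 250.0

    def to_fit_config(self) -> FitConfig:
        return FitConfig(min_photons=self.min_photons)


class SegmentationSection(_Strict):
    gate_low: float = 800.0
    gate_high: float = 1500.0
    threshold_methods: list[str] = Field(default_factory=lambda: list(default_threshold_specs()))
    local_block_size: int = 35
    canny_sigma: float = 1.0
    expansion_modes: list[str] = ["dilate", "close"]
    struct_radius_1: int = 2
    struct_radius_2: int = 1
    min_area: int = 20
    connectivity: int = 8
    voting_mode: str = "per_image_argmax"

    def to_segmentation_config(self) -> SegmentationConfig:
        return SegmentationConfig(
            gate_low=self.gate_low,
            gate_high=self.gate_high,
            threshold_methods=tuple(self.threshold_methods),
            local_block_size=self.local_block_size,
            canny_sigma=self.canny_sigma,
            expansion_modes=tuple(self.expansion_modes),
            struct_radius_1=self.struct_radius_1,
            struct_radius_2=self.struct_radius_2,
            min_area=self.min_area,
            connectivity=self.connectivity,
            voting_mode=self.voting_mode,
        )


class FeaturesSection(_Strict):
    weighted: bool = True

    def to_features_config(self) -> FeaturesConfig:
        return FeaturesConfig(weighted=self.weighted)


class StatsSection(_Strict):
    split_key: str = "tissue"
    control_label: str = "spleen"
    include_redox: bool = True


class SyntheticSection(_Strict):
    shape: list[int] = [256, 256]
    n_cells: int = 10
    n_distractors: int = 5
    photons_per_cell: float = 5000.0
    autofl_photons_per_cell: float = 10_000.0
    seed: int = 0


class PipelineConfig(_Strict):
    """Top-level nested configuration with an embedded version string."""

    version: str = __version__
    seed: int = 0
    fit: FitSection = Field(default_factory=FitSection)
    segmentation: SegmentationSection = Field(default_factory=SegmentationSection)
    features: FeaturesSection = Field(default_factory=FeaturesSection)
    stats: StatsSection = Field(default_factory=StatsSection)
    synthetic: SyntheticSection = Field(default_factory=SyntheticSection)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.model_dump(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as exc:
            raise ConfigError(f"invalid JSON config {path}: {exc}") from exc
        try:
            return cls.model_validate(payload)
        except Exception as exc:
            raise ConfigError(f"invalid config {path}: {exc}") from exc
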