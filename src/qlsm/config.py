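"""Pipeline configuration: schema-validated, YAML round-trippable."""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["ClassifierConfig", "ThresholdConfig", "PipelineConfig"]

REQUIRED_CHANNELS = ("nerve", "cd31", "emcn")


class ClassifierConfig(BaseModel):
    """Random-forest pixel classifier settings for the nerve channel."""

    model_config = ConfigDict(extra="forbid")

    scales: tuple[float, ...] = (0.7, 1.0, 1.6, 3.5)
    n_estimators: int = 100
    n_labels_per_class: int = 300
    probability_threshold: float = 0.5
    labels_csv: Optional[str] = None  # voxel z,y,x,class rows for real data


class ThresholdConfig(BaseModel):
    """Absolute intensity thresholds per stain (optimized per stain, held
    consistent across samples)."""

    model_config = ConfigDict(extra="forbid")

    cd31_tau: float = 110.0
    emcn_tau: float = 110.0
    nerve_tau: Optional[float] = None  # set to bypass the classifier


class PipelineConfig(BaseModel):
    """Everything needed for one end-to-end run.

    Exactly one input source must be given: ``phantom`` (a
    :class:`~qlsm.phantom.PhantomSpec` field mapping) or ``input_paths``
    (TIFF path per channel: nerve, cd31, emcn).  The config is validated
    before any stage runs and persisted verbatim into the output directory.
    """

    model_config = ConfigDict(extra="forbid")

    phantom: Optional[dict] = None
    input_paths: Optional[dict[str, str]] = None
    fallback_spacing_um: Optional[tuple[float, float, float]] = None

    vois: list[dict] = Field(default_factory=list)
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)
    classifier: ClassifierConfig = Field(default_factory=ClassifierConfig)
    background_radius_um: float = 10.0
    min_volume_um3: float = 1e4
    downsample_factor: int = 2
    seed_diameter_um: float = 10.0
    association_d_um: float = 10.0
    overlap_min_voxels: int = 1

    out_dir: Optional[str] = None
    write_intermediates: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _check_inputs(self) -> "PipelineConfig":
        if (self.phantom is None) == (self.input_paths is None):
            raise ValueError("exactly one of 'phantom' or 'input_paths' must be set")
        if self.input_paths is not None:
            missing = [c for c in REQUIRED_CHANNELS if c not in self.input_paths]
            if missing:
                raise ValueError(f"input_paths is missing channel mappings: {missing}")
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        return self

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(mode="json"), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(Path(path)) as fh:
            return cls.model_validate(yaml.safe_load(fh))

    def config_hash(self) -> str:
        import hashlib

        blob = yaml.safe_dump(self.model_dump(mode="json"), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
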