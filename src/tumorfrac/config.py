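"""Pipeline configuration: one YAML-serializable object holding every
constant the stages share (scan resolution, detector gates, annotation
budget, adequacy thresholds, CNV gate, agreement settings)."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .detect import DetectParams

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration with a versioned schema.

    Defaults are the constants used throughout: 0.4416 microns per pixel,
    a 5-per-class annotation budget (10 maximum), adequacy at 100 tumor
    cells and 20% TCF, the 6-criterion CNV gate at 5 criteria with the
    x >= 4 primary-call predicate, and integer-percent agreement binning.
    """

    schema_version: int = 1
    mpp: float = 0.4416
    # synthetic cohort
    n_cases: int = 6
    tile_px: int = 512
    cells_per_case: int = 100
    artifact_per_case: int = 8
    observer_bias: float = 18.0
    observer_noise_sd: float = 10.0
    n_observers: int = 3
    # detection
    od_threshold: float = 0.35
    min_area_um2: float = 8.0
    max_area_um2: float = 400.0
    split_min_distance_px: int = 9
    # classification
    annotations_per_class: int = 5
    # adequacy
    min_cells: int = 100
    min_tcf: float = 0.20
    # CNV gate
    min_criteria: int = 5
    call_threshold: float = 4.0
    # agreement
    bin_width: int = 5
    n_perm: int = 2000

    def detect_params(self) -> DetectParams:
        return DetectParams(
            od_threshold=self.od_threshold,
            min_area_um2=self.min_area_um2,
            max_area_um2=self.max_area_um2,
            split_min_distance_px=self.split_min_distance_px,
            mpp=self.mpp,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        """Stable hash of the configuration for the run manifest."""
        canon = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
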