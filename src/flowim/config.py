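"""Run configuration: one serializable object driving the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .optics import OpticalConfig
from .quantify import LOQ_CV_DEFAULT, MERGE_OCCUPANCY_FLOOR, Z_DEFAULT


@dataclass
class RunConfig:
    """Everything a sample-processing run needs, YAML round-trippable."""

    optical: OpticalConfig = field(default_factory=OpticalConfig)
    detector: str = "fast"  # "fast" or "segmenter"
    detector_params: dict = field(default_factory=dict)
    classifier_path: Optional[str] = None
    z: float = Z_DEFAULT
    loq_cv_criterion: float = LOQ_CV_DEFAULT
    merge_occupancy_floor: int = MERGE_OCCUPANCY_FLOOR
    dilution_factor: float = 1.0
    seed: int = 0
    output_dir: str = "flowim-output"

    def __post_init__(self) -> None:
        if self.detector not in ("fast", "segmenter"):
            raise ValueError(f"unknown detector {self.detector!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["optical"] = self.optical.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if isinstance(d.get("optical"), dict):
            d["optical"] = OpticalConfig.from_dict(d["optical"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
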