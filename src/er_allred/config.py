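"""Pipeline configuration and report serialization.

Every numeric constant of the method is surfaced here in one place — the
0.2 score-map threshold, the 240 px^2 area rule, the 40/50 hue/value
thresholds, the 64/32 patch sizes, and the Allred treatment cutoff of 3 —
so a run is fully described by one validated config object. Reports carry
the slide summary, the Allred result, and provenance (config hash, model
hashes, package version, timestamp) and round-trip losslessly through JSON.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .allred import AllredResult, SlideSummary
from .detection import DetectionParams
from .stain import PNThresholds

__all__ = ["PipelineConfig", "Report", "load_config", "dump_config",
           "write_report", "read_report"]


class PipelineConfig(BaseModel):
    """Validated configuration of the whole pipeline; unknown keys rejected."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    cell_radius: float = Field(32.0, gt=0)
    score_threshold: float = Field(0.2, gt=0, lt=1)
    min_region_area: float = Field(240.0, gt=0)
    area_is_minimum: bool = True
    smooth_sigma: float = Field(2.0, ge=0)
    detection_patch_size: int = Field(64, gt=0)
    class_patch_size: int = Field(32, gt=0)
    hue_threshold: float = Field(40.0, ge=0, le=255)
    value_threshold: float = Field(50.0, ge=0, le=255)
    field_size: int = Field(512, gt=0)
    merge_radius: float = Field(8.0, ge=0)
    match_tolerance: float = Field(16.0, gt=0)
    treatment_cutoff: int = Field(3, ge=2, le=8)
    seed: int = 0

    def detection_params(self) -> DetectionParams:
        return DetectionParams(cell_radius=self.cell_radius,
                               score_threshold=self.score_threshold,
                               min_region_area=self.min_region_area,
                               area_is_minimum=self.area_is_minimum,
                               patch_size=self.detection_patch_size,
                               smooth_sigma=self.smooth_sigma)

    def pn_thresholds(self) -> PNThresholds:
        return PNThresholds(hue_threshold=self.hue_threshold,
                            value_threshold=self.value_threshold)

    def hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Load a YAML/JSON config; an empty file yields the all-defaults config."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return PipelineConfig(**data)


def dump_config(cfg: PipelineConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.model_dump(), sort_keys=True),
                          encoding="utf-8")


def file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


class Report(BaseModel):
    """Per-slide scoring report with provenance."""

    model_config = ConfigDict(extra="forbid")

    slide: str = ""
    n_negative: float
    n_weak: float
    n_moderate: float
    n_strong: float
    er_pct: float
    proportion_score: int
    intensity_score: int
    allred_score: int
    actionable: bool
    low_positivity: bool = False
    config_hash: str = ""
    model_hashes: dict = Field(default_factory=dict)
    version: str = __version__
    timestamp: str = ""

    @model_validator(mode="after")
    def _check_scores(self):
        if self.allred_score == 1:
            raise ValueError("an Allred score of 1 is not a possible outcome")
        if self.allred_score != self.proportion_score + self.intensity_score:
            raise ValueError("Allred score must equal the sum of its components")
        return self

    @classmethod
    def from_result(cls, summary: SlideSummary, result: AllredResult,
                    slide: str = "", config_hash: str = "",
                    model_hashes: dict | None = None) -> "Report":
        return cls(slide=slide,
                   n_negative=round(summary.n_negative, 4),
                   n_weak=round(summary.n_weak, 4),
                   n_moderate=round(summary.n_moderate, 4),
                   n_strong=round(summary.n_strong, 4),
                   er_pct=round(summary.positive_pct, 4),
                   proportion_score=result.proportion_score,
                   intensity_score=result.intensity_score,
                   allred_score=result.total,
                   actionable=result.actionable,
                   low_positivity=result.low_positivity,
                   config_hash=config_hash,
                   model_hashes=model_hashes or {},
                   timestamp=datetime.now(timezone.utc).isoformat(timespec="seconds"))


def write_report(report: Report, path) -> None:
    Path(path).write_text(report.model_dump_json(indent=2) + "\n", encoding="utf-8")


def read_report(path) -> Report:
    return Report(**json.loads(Path(path).read_text(encoding="utf-8")))
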