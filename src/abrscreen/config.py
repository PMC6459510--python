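"""Pipeline configuration: every analysis switch with its default.

Defaults encode the conventions of the calling pipeline (strict percentile
bounds, per-stimulus 60% rule, pooled Fisher table, face-value ceilings,
corrected LowFrequency gate); each is an explicit switch so the alternative
readings remain testable.  Configs round-trip losslessly through YAML.
"""
from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, Field, field_validator

from .stimuli import BATTERY_LABELS


class DetectorConfig(BaseModel):
    corr_threshold: float = 0.35
    rms_ratio_threshold: float = 1.15
    max_lag_ms: float = 0.5


class PipelineConfig(BaseModel):
    seed: int = 0
    n_lines: int = 50
    n_per_line: int = Field(default=4, ge=4)
    n_controls: int = 200
    class_mixture: dict[str, float] = {"Normal": 1.0}
    inter_mouse_sd_db: float = 5.0
    outlier_prob: float = 0.0
    simulate_waveforms: bool = False
    detector: DetectorConfig = DetectorConfig()

    percentile_convention: Literal["linear", "hazen"] = "linear"
    rule60_denominator: Literal["per_stimulus", "any_stimulus"] = "per_stimulus"
    fisher_pooling: Literal["pooled", "per_stimulus"] = "pooled"
    ceiling_mode: Literal["face_value", "censored"] = "face_value"
    low_frequency_as_printed: bool = False

    alpha: float = 0.05
    genome_size: int = 20_000
    flank_bp: int = 100_000
    n_assoc_genes: int = 37
    n_assoc_traits: int = 2

    outdir: str = "abrscreen-out"

    @field_validator("class_mixture")
    @classmethod
    def _mixture_sums_to_one(cls, v: dict[str, float]) -> dict[str, float]:
        if abs(sum(v.values()) - 1.0) > 1e-9:
            raise ValueError("class mixture must sum to 1")
        return v

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text(encoding="utf-8")))
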