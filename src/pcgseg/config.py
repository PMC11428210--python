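"""Validated run configuration for the end-to-end experiments.

One YAML document collects every tunable of the pipeline; unknown keys are
rejected so typos fail loudly, and each experiment writes its resolved
configuration (plus a content hash) beside its outputs for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field


class FilterConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    low_hz: float = 25.0
    high_hz: float = 400.0
    order: int = 2
    target_rate: float = 2000.0


class SegmenterConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    dilations: list[int] = Field(default=[2, 4, 8, 16, 16])
    kernel_size: int = 3
    channels: int = 32
    lstm_hidden: int = 64
    bidirectional: bool = True
    dropout_rate: float = 0.25
    lr: float = 0.001
    batch_size: int = 32
    epochs: int = 90
    frame_rate: float = 50.0
    fusion: str = "concat"


class EvalConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    tol_s1_ms: float = 100.0
    tol_s2_ms: float = 80.0
    precision_mode: str = "conventional"


class MfccConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    f_low_hz: float = 30.0
    f_high_hz: float = 500.0
    n_filters: int = 26
    n_coeffs: int = 13
    n_fft: int = 256
    drop_c0: bool = False


class ClassifierConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_trees: int = 100
    retained_variance: float = 0.95
    folds: int = 6
    cycle_min: int = 1
    cycle_max: int = 9
    use_ground_truth_labels: bool = True


class DataConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_per_class: int = 20
    duration_s: float = 5.0  # segmentation records (short auscultation samples)
    classification_duration_s: float = 10.0  # must hold >= cycle_max + 1 heartbeats
    noise_snr_db: float | None = 15.0


class RunConfig(BaseModel):
    """Top-level experiment configuration (schema-validated, extra keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    filter: FilterConfig = Field(default_factory=FilterConfig)
    segmenter: SegmenterConfig = Field(default_factory=SegmenterConfig)
    evaluation: EvalConfig = Field(default_factory=EvalConfig)
    mfcc: MfccConfig = Field(default_factory=MfccConfig)
    classifier: ClassifierConfig = Field(default_factory=ClassifierConfig)
    data: DataConfig = Field(default_factory=DataConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(Path(path)) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.model_validate(payload)

    def to_yaml(self, path) -> None:
        with open(Path(path), "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    def content_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
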