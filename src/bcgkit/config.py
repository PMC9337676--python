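"""Central pipeline configuration with hardware-default constants."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .errors import ParameterError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunables of every pipeline stage.

    Defaults follow the reference hardware and protocol: 200 Hz sampling,
    1-s / 50 % segmentation, 35/85 mV QC band, 1-9 Hz band-pass, 3-s model
    windows, [0.5, 1.1] s RR plausibility band, 0.1 s match tolerance.
    """

    # acquisition
    fs: float = 200.0
    # band-pass
    band_low: float = 1.0
    band_high: float = 9.0
    filter_order: int = 4
    # segmentation + QC
    window_s: float = 1.0
    overlap: float = 0.5
    qc_low: float = 35.0
    qc_high: float = 85.0
    # candidate extraction
    min_spacing: float = 0.3
    prominence_factor: float = 0.1
    # constant-latency regularization of predicted offsets: maximum snap
    # adjustment for the dominant-prominence candidate class (0 disables)
    offset_correction: float = 0.5
    # CNN
    model_window_s: float = 3.0
    learning_rate: float = 0.01
    momentum: float = 0.9
    clip_norm: float = 2.0
    batch_size: int = 32
    max_epochs: int = 500
    error_tol: float = 1e-4
    margin_tol: float = 1e-4
    max_training_windows: int = 2000
    # RR plausibility band
    min_rri: float = 0.5
    max_rri: float = 1.1
    # validation
    tolerance: float = 0.1
    epoch_len: float = 1.0
    hr_window_s: float = 10.0
    # baseline picker
    baseline_k: float = 1.0
    baseline_window_s: float = 2.0
    baseline_time_offset: float = 0.25
    # reproducibility
    seed: int = 0

    def validate(self) -> None:
        if self.fs <= 0:
            raise ParameterError("fs must be > 0")
        if not (0 < self.band_low < self.band_high < self.fs / 2):
            raise ParameterError(
                f"need 0 < band_low < band_high < fs/2, got "
                f"{self.band_low}, {self.band_high}, fs={self.fs}"
            )
        if not (0 <= self.overlap < 1):
            raise ParameterError("overlap must be in [0, 1)")
        if not (self.qc_high > self.qc_low > 0):
            raise ParameterError("need qc_high > qc_low > 0")
        if not (0 < self.min_rri < self.max_rri):
            raise ParameterError("need 0 < min_rri < max_rri")
        if self.tolerance <= 0:
            raise ParameterError("tolerance must be > 0")
        if self.epoch_len <= 0:
            raise ParameterError("epoch_len must be > 0")
        if self.max_epochs < 1 or self.batch_size < 1:
            raise ParameterError("max_epochs and batch_size must be >= 1")

    def as_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.as_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.as_dict(), sort_keys=True))
        return path
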