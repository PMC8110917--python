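"""Run configuration: one object holding every pipeline tunable.

Loaded from a YAML file with CLI-flag overrides; the canonical-JSON SHA-256
hash of a config is recorded in outputs for provenance.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ValidationError
from .imaging import MODALITIES


@dataclass
class RunConfig:
    scale_um_per_px: float = 1.0
    modality: str = "fluorescent"
    equalize: bool = True
    box_size: int = 32
    stride: float = 16.0
    radius_factor: float = 1.25
    min_confidence: float = 0.0
    support_quantile: float = 0.8
    min_support: float = 0.7
    threshold_quantile: float = 0.9
    min_object_px: int = 50
    max_object_px: int = 50000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.scale_um_per_px > 0):
            raise ValidationError("scale_um_per_px must be > 0")
        if self.modality not in MODALITIES:
            raise ValidationError(f"modality must be one of {MODALITIES}")
        if self.box_size < 2:
            raise ValidationError("box_size must be >= 2")
        if not (0 < self.stride < self.box_size):
            raise ValidationError("stride must be in (0, box_size)")
        if not (self.radius_factor > 0):
            raise ValidationError("radius_factor must be > 0")
        if not (0.0 <= self.min_confidence <= 1.0):
            raise ValidationError("min_confidence must be in [0, 1]")
        for name in ("support_quantile", "threshold_quantile"):
            if not (0.0 < getattr(self, name) < 1.0):
                raise ValidationError(f"{name} must be in (0, 1)")
        if not (0.0 < self.min_support <= 1.0):
            raise ValidationError("min_support must be in (0, 1]")
        if not (0 <= self.min_object_px <= self.max_object_px):
            raise ValidationError("need 0 <= min_object_px <= max_object_px")

    @classmethod
    def load(cls, path: str | Path | None = None, **overrides) -> "RunConfig":
        data: dict = {}
        if path is not None:
            doc = yaml.safe_load(Path(path).read_text()) or {}
            known = {f.name for f in fields(cls)}
            unknown = set(doc) - known
            if unknown:
                raise ValidationError(f"unknown config fields: {sorted(unknown)}")
            data.update(doc)
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
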