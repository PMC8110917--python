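"""Vessel length density and method-comparison accuracy.

Length density is total vessel centerline length per image area, reported in
µm/mm². Per-sample density is the mean over that sample's images
(conventionally 4), and per-group density the mean over samples. Method
agreement is quantified per group as

    percent_error   = |reference − measured| / reference × 100
    percent_accuracy = 100 − percent_error        (N/A when error > 100)

where the reference is the manually annotated measurement. Unit conversion
happens here and only here: all geometry upstream stays in pixels.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Polyline, polyline_length
from .errors import ValidationError
from .imaging import Image2D

logger = logging.getLogger(__name__)

METHODS = ("annotated", "biosegment", "pixel_based")

#: Sentinel for an undefined accuracy (percent error above 100).
NA = float("nan")


def is_na(x: float) -> bool:
    return isinstance(x, float) and math.isnan(x)


@dataclass
class LengthDensityResult:
    image_id: str
    total_length_um: float
    area_mm2: float
    method: str = "biosegment"
    density_um_per_mm2: float = field(init=False)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValidationError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.total_length_um < 0:
            raise ValidationError("total_length_um must be >= 0")
        if not (self.area_mm2 > 0):
            raise ValidationError("area_mm2 must be > 0")
        self.density_um_per_mm2 = self.total_length_um / self.area_mm2


@dataclass
class GroupResult:
    """Per-group density: mean and sample SD (n−1) over per-sample means."""

    group_id: str
    sample_means: list[float]
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        if not self.sample_means:
            raise ValidationError("group needs at least one sample mean")
        arr = np.asarray(self.sample_means, dtype=float)
        self.mean = float(arr.mean())
        self.sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0


@dataclass
class AccuracyReport:
    group_id: str
    percent_error: float
    percent_accuracy: float = field(init=False)

    def __post_init__(self) -> None:
        if self.percent_error < 0:
            raise ValidationError("percent_error must be >= 0")
        self.percent_accuracy = percent_accuracy(self.percent_error)


def total_vessel_length(polylines: list[Polyline], scale_um_per_px: float) -> float:
    """Summed length of vessel-labelled polylines, converted to µm.

    Out-of-plane and debris polylines are excluded: they are annotated
    precisely so they do not count toward vessel length.
    """
    if not (scale_um_per_px > 0):
        raise ValidationError("scale_um_per_px must be > 0")
    return sum(polyline_length(p) for p in polylines if p.label == "vessel") * scale_um_per_px


def length_density(total_length_um: float, image: Image2D, method: str = "biosegment") -> LengthDensityResult:
    """Length density of one image: total length (µm) over field area (mm²)."""
    area = image.area_mm2
    if not (area > 0):
        raise ValidationError("image area must be > 0")
    return LengthDensityResult(image.id, float(total_length_um), area, method)


def sample_density(image_results: list[LengthDensityResult]) -> float:
    """Mean density over one sample's images (the convention is 4 images/sample)."""
    if not image_results:
        raise ValidationError("sample_density needs at least one image result")
    methods = {r.method for r in image_results}
    if len(methods) > 1:
        raise ValidationError(f"cannot average across methods {sorted(methods)}")
    if len(image_results) != 4:
        logger.warning(
            "sample_density: %d images (convention is 4 per sample)", len(image_results)
        )
    return float(np.mean([r.density_um_per_mm2 for r in image_results]))


def percent_error(reference_length: float, measured_length: float) -> float:
    """|reference − measured| / reference × 100 (reference must be positive)."""
    if not (reference_length > 0):
        raise ValidationError("reference length must be > 0 (percent error undefined)")
    if measured_length < 0:
        raise ValidationError("measured length must be >= 0")
    return abs(reference_length - measured_length) / reference_length * 100.0


def percent_accuracy(pe: float) -> float:
    """100 − percent_error, or NA (NaN sentinel) when the error exceeds 100."""
    if pe < 0:
        raise ValidationError("percent_error must be >= 0")
    return 100.0 - pe if pe <= 100.0 else NA


def aggregate_accuracy(reports: list[AccuracyReport]) -> tuple[float, int]:
    """Mean accuracy over groups; NA propagates.

    Returns ``(mean_accuracy, excluded_count)``: if any group's accuracy is
    NA the aggregate is NA and ``excluded_count`` says how many groups were NA.
    """
    if not reports:
        raise ValidationError("aggregate_accuracy needs at least one report")
    excluded = sum(1 for r in reports if is_na(r.percent_accuracy))
    if excluded:
        return NA, excluded
    return float(np.mean([r.percent_accuracy for r in reports])), 0


def results_table(rows: list[dict]) -> pd.DataFrame:
    """Tidy results: one row per (experiment, group, sample, image, method)."""
    cols = ["experiment", "group", "sample", "image_id", "method",
            "total_length_um", "area_mm2", "density_um_per_mm2"]
    df = pd.DataFrame(rows)
    return df[[c for c in cols if c in df.columns] + [c for c in df.columns if c not in cols]]


def comparison_table(reports: list[AccuracyReport]) -> pd.DataFrame:
    """Group-level comparison: percent error and accuracy ('NA' when undefined)."""
    return pd.DataFrame(
        {
            "group": [r.group_id for r in reports],
            "percent_error": [r.percent_error for r in reports],
            "percent_accuracy": [
                "NA" if is_na(r.percent_accuracy) else r.percent_accuracy for r in reports
            ],
        }
    )


def write_csv(df: pd.DataFrame, path: str | Path) -> Path:
    p = Path(path)
    df.to_csv(p, index=False)
    return p
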