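"""Detection boxes, training-region construction, and desk-scale detector backends.

The detector contract is ``image -> DetectionSet``: a set of axis-aligned boxes
with confidence and class, the interface between any object detector and the
polyline reconstruction. Training regions for a detector are built by sampling
overlapping squares along annotation polylines (:func:`boxes_from_polyline`).

Two backends ship with the package:

* :func:`oracle_detect` — a ground-truth-driven stand-in for a trained model,
  with controllable center jitter, box drop-out and false positives; used to
  study reconstruction behaviour under known detector error.
* :func:`classical_detect` — threshold / size-filter / skeleton sampling on the
  image itself, requiring no training.

:func:`pixel_based_length` implements the classical skeleton-based length
protocol (contrast enhancement, quantile threshold, component size filtering,
topological skeletonization, diagonal-corrected pixel count) used as the
comparison method against polyline-based measurement.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from skimage import measure as _measure
from skimage import morphology as _morphology

from .annotation import LABELS, AnnotationSet, Polyline, point_at_arc, polyline_length
from .errors import BackendContractError, ValidationError
from .imaging import Image2D, equalize_histogram

logger = logging.getLogger(__name__)

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class DetectionBox:
    """Axis-aligned box given by center, extents, confidence, class label."""

    cx: float
    cy: float
    w: float
    h: float
    confidence: float = 1.0
    label: str = "vessel"

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValidationError(f"box extents must be positive, got w={self.w}, h={self.h}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(f"confidence must be in [0, 1], got {self.confidence}")
        if self.label not in LABELS:
            raise ValidationError(f"unknown label {self.label!r}; allowed labels: {list(LABELS)}")

    @property
    def diagonal(self) -> float:
        return math.hypot(self.w, self.h)


@dataclass
class DetectionSet:
    """All boxes detected (or constructed) on one image."""

    image_id: str
    boxes: list[DetectionBox] = field(default_factory=list)


def boxes_from_polyline(
    p: Polyline, box_size: int = 32, stride: float | None = None, image_id: str = ""
) -> DetectionSet:
    """Overlapping square regions sampled along a polyline's arc length.

    Square boxes of side ``box_size`` are centered at arc positions
    0, stride, 2·stride, …, always including the final endpoint, so consecutive
    centers are at most one stride apart and the union of boxes covers the
    whole chain. Each box inherits the polyline's label. ``stride`` defaults
    to ``box_size / 2`` (50% overlap) and must stay below ``box_size`` so that
    consecutive regions overlap.
    """
    if box_size < 2:
        raise ValidationError(f"box_size must be >= 2 px, got {box_size}")
    if stride is None:
        stride = box_size / 2.0
    if not (0 < stride < box_size):
        raise ValidationError(
            f"stride ({stride}) must be in (0, box_size={box_size}): regions would not overlap"
        )
    L = polyline_length(p)
    n = int(math.floor(L / stride + 1e-9))
    positions = [i * stride for i in range(n + 1)]
    if L - positions[-1] > 1e-9:
        positions.append(L)
    boxes = []
    for s in positions:
        cx, cy = point_at_arc(p, s)
        boxes.append(DetectionBox(cx, cy, float(box_size), float(box_size), 1.0, p.label))
    return DetectionSet(image_id, boxes)


def boxes_for_annotations(
    truth: AnnotationSet, box_size: int = 32, stride: float | None = None
) -> DetectionSet:
    """Training regions for every polyline of an annotation set (all classes)."""
    boxes: list[DetectionBox] = []
    for p in truth.polylines:
        boxes.extend(boxes_from_polyline(p, box_size, stride, truth.image_id).boxes)
    return DetectionSet(truth.image_id, boxes)


def oracle_detect(
    truth: AnnotationSet,
    box_size: int = 32,
    stride: float | None = None,
    jitter_sd: float = 0.0,
    miss_rate: float = 0.0,
    false_positive_count: int = 0,
    seed: int = 0,
    field_px: tuple[int, int] | None = None,
) -> DetectionSet:
    """Ground-truth-driven detector with controlled error injection.

    Starts from :func:`boxes_for_annotations`, perturbs every box center by
    isotropic Gaussian noise of standard deviation ``jitter_sd``, drops each
    box independently with probability ``miss_rate``, and adds
    ``false_positive_count`` vessel-labelled boxes placed uniformly at random
    (inside ``field_px`` when given, else inside the padded bounding box of the
    annotations). Deterministic for a fixed seed.
    """
    if jitter_sd < 0:
        raise ValidationError(f"jitter_sd must be >= 0, got {jitter_sd}")
    if not (0.0 <= miss_rate < 1.0):
        raise ValidationError(f"miss_rate must be in [0, 1), got {miss_rate}")
    if false_positive_count < 0:
        raise ValidationError("false_positive_count must be >= 0")
    rng = np.random.default_rng(seed)
    base = boxes_for_annotations(truth, box_size, stride)
    boxes: list[DetectionBox] = []
    for b in base.boxes:
        dx, dy = rng.normal(0.0, jitter_sd, size=2) if jitter_sd > 0 else (0.0, 0.0)
        keep = rng.random() >= miss_rate
        if keep:
            boxes.append(
                DetectionBox(b.cx + float(dx), b.cy + float(dy), b.w, b.h, b.confidence, b.label)
            )
    if false_positive_count > 0:
        if field_px is not None:
            x0, y0, x1, y1 = 0.0, 0.0, float(field_px[0]), float(field_px[1])
        else:
            pts = np.concatenate([p.as_array() for p in truth.polylines]) if truth.polylines else np.zeros((1, 2))
            x0, y0 = pts.min(axis=0) - box_size
            x1, y1 = pts.max(axis=0) + box_size
        for _ in range(false_positive_count):
            cx = rng.uniform(x0, x1)
            cy = rng.uniform(y0, y1)
            conf = rng.uniform(0.0, 1.0)
            boxes.append(DetectionBox(float(cx), float(cy), float(box_size), float(box_size), float(conf), "vessel"))
    return DetectionSet(truth.image_id, boxes)


def _size_filtered_foreground(
    image: Image2D, threshold_quantile: float, min_px: int, max_px: int
) -> np.ndarray:
    """Equalize, threshold at an intensity quantile, drop components outside [min_px, max_px]."""
    if not (0.0 < threshold_quantile < 1.0):
        raise ValidationError(f"threshold_quantile must be in (0, 1), got {threshold_quantile}")
    eq = equalize_histogram(image)
    thr = np.quantile(eq.pixels, threshold_quantile)
    fg = eq.pixels > thr
    if not fg.any():
        return fg
    labels = _measure.label(fg, connectivity=2)
    keep = np.zeros_like(fg)
    for region in _measure.regionprops(labels):
        if min_px <= region.area <= max_px:
            keep[labels == region.label] = True
    return keep


def skeleton_length_px(skeleton: np.ndarray) -> float:
    """Length of a binary skeleton with diagonal-step correction.

    Adjacent skeleton pixel pairs are counted once each: orthogonal steps
    contribute 1 px, diagonal steps √2 px. A diagonal pair that shares an
    orthogonal skeleton neighbour (a staircase corner triangle) is skipped to
    avoid double-counting the same advance.
    """
    skel = np.asarray(skeleton, dtype=bool)
    coords = set(zip(*np.nonzero(skel)))
    length = 0.0
    for r, c in coords:
        if (r, c + 1) in coords:
            length += 1.0
        if (r + 1, c) in coords:
            length += 1.0
        if (r + 1, c + 1) in coords and (r, c + 1) not in coords and (r + 1, c) not in coords:
            length += _SQRT2
        if (r + 1, c - 1) in coords and (r, c - 1) not in coords and (r + 1, c) not in coords:
            length += _SQRT2
    return length


def pixel_based_length(
    image: Image2D,
    threshold_quantile: float = 0.9,
    min_object_px: int = 50,
    max_object_px: int = 50000,
) -> float:
    """Skeleton-based total vessel length, in pixels.

    The classical measurement chain: histogram equalization → quantile
    threshold → removal of small cells and large clumps by component area →
    topological skeletonization → diagonal-corrected skeleton length. Blank
    images yield 0. Anything elongated and bright enough survives the filter,
    vessel or not — which is exactly the method's known failure mode.
    """
    keep = _size_filtered_foreground(image, threshold_quantile, min_object_px, max_object_px)
    if not keep.any():
        return 0.0
    skel = _morphology.skeletonize(keep)
    return skeleton_length_px(skel)


def classical_detect(
    image: Image2D,
    threshold_quantile: float = 0.9,
    min_component_px: int = 50,
    max_component_px: int = 50000,
    box_size: int = 32,
    stride: float | None = None,
) -> DetectionSet:
    """Training-free detector: threshold, size-filter, sample boxes along skeletons.

    Surviving connected components are skeletonized and square boxes are placed
    along the skeleton at roughly ``stride`` spacing; each box's confidence is
    the mean equalized intensity inside it. An image with empty foreground
    yields an empty DetectionSet.
    """
    if stride is None:
        stride = box_size / 2.0
    if not (0 < stride < box_size):
        raise ValidationError(
            f"stride ({stride}) must be in (0, box_size={box_size}): regions would not overlap"
        )
    keep = _size_filtered_foreground(image, threshold_quantile, min_component_px, max_component_px)
    if not keep.any():
        logger.info("classical_detect: empty foreground on %r", image.id)
        return DetectionSet(image.id, [])
    eq = equalize_histogram(image)
    labels = _measure.label(keep, connectivity=2)
    boxes: list[DetectionBox] = []
    half = box_size / 2.0
    for region_label in range(1, labels.max() + 1):
        comp = labels == region_label
        skel = _morphology.skeletonize(comp)
        rr, cc = np.nonzero(skel)
        kept: list[tuple[float, float]] = []
        for r, c in zip(rr, cc):
            if all((r - y) ** 2 + (c - x) ** 2 >= stride**2 for x, y in kept):
                kept.append((float(c), float(r)))
        for cx, cy in kept:
            r0 = max(0, int(cy - half))
            r1 = min(image.height, int(cy + half) + 1)
            c0 = max(0, int(cx - half))
            c1 = min(image.width, int(cx + half) + 1)
            conf = float(np.clip(eq.pixels[r0:r1, c0:c1].mean(), 0.0, 1.0))
            boxes.append(DetectionBox(cx, cy, float(box_size), float(box_size), conf, "vessel"))
    return DetectionSet(image.id, boxes)


BACKENDS: dict[str, Callable[..., DetectionSet]] = {"classical": classical_detect}


def detect(image: Image2D, backend: str | Callable[..., DetectionSet], **params) -> DetectionSet:
    """Dispatch to a detector backend and validate its output against the contract."""
    fn = BACKENDS[backend] if isinstance(backend, str) else backend
    result = fn(image, **params)
    if not isinstance(result, DetectionSet):
        raise BackendContractError(f"backend returned {type(result).__name__}, not DetectionSet")
    checked = []
    for i, b in enumerate(result.boxes):
        w = getattr(b, "w", None)
        h = getattr(b, "h", None)
        conf = getattr(b, "confidence", None)
        label = getattr(b, "label", None)
        if w is None or h is None or not (w > 0 and h > 0):
            raise BackendContractError(f"box {i} has non-positive extents (w={w}, h={h})")
        if conf is None or not (0.0 <= conf <= 1.0):
            raise BackendContractError(f"box {i} has confidence {conf} outside [0, 1]")
        if label not in LABELS:
            raise BackendContractError(f"box {i} has unknown label {label!r}")
        checked.append(DetectionBox(float(b.cx), float(b.cy), float(w), float(h), float(conf), label))
    return DetectionSet(result.image_id, checked)


def write_detections(dset: DetectionSet, path: str | Path) -> Path:
    doc = {
        "image_id": dset.image_id,
        "boxes": [
            {"cx": b.cx, "cy": b.cy, "w": b.w, "h": b.h, "confidence": b.confidence, "label": b.label}
            for b in dset.boxes
        ],
    }
    p = Path(path)
    p.write_text(json.dumps(doc, indent=1))
    return p


def read_detections(path: str | Path) -> DetectionSet:
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"cannot read detections file: {p}")
    doc = json.loads(p.read_text())
    boxes = [
        DetectionBox(b["cx"], b["cy"], b["w"], b["h"], b.get("confidence", 1.0), b.get("label", "vessel"))
        for b in doc.get("boxes", [])
    ]
    return DetectionSet(doc["image_id"], boxes)
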