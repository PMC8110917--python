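"""Polyline annotations: the ground-truth vessel tracings and their JSON format.

A vessel trace is an ordered chain of 2-D points ("polyline") with a class
label: a real vessel, an out-of-plane object too blurry to call, or debris
(non-vessel tissue clumps). Total vessel length — the field's primary
measurement — is the sum of segment lengths over vessel-labelled polylines.

The interchange JSON schema, shared by manual annotations, synthetic ground
truth, and reconstruction output::

    {"image_id": str,
     "scale_um_per_px": float,
     "polylines": [{"label": "vessel"|"out_of_plane"|"debris",
                    "points": [[x, y], ...]}]}
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError

LABELS = ("vessel", "out_of_plane", "debris")


@dataclass(frozen=True)
class Polyline:
    """Ordered chain of ≥ 2 pixel-coordinate points with a class label."""

    points: tuple[tuple[float, float], ...]
    label: str = "vessel"

    def __post_init__(self) -> None:
        pts = tuple((float(x), float(y)) for x, y in self.points)
        if len(pts) < 2:
            raise ValidationError(f"polyline needs at least 2 points, got {len(pts)}")
        for a, b in zip(pts, pts[1:]):
            if a == b:
                raise ValidationError(f"consecutive identical points {a} in polyline")
        if self.label not in LABELS:
            raise ValidationError(f"unknown label {self.label!r}; allowed labels: {list(LABELS)}")
        object.__setattr__(self, "points", pts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.points, dtype=float)


def polyline_length(p: Polyline) -> float:
    """Sum of Euclidean segment lengths, in pixels."""
    xy = p.as_array()
    return float(np.hypot(*np.diff(xy, axis=0).T).sum())


def point_at_arc(p: Polyline, s: float) -> tuple[float, float]:
    """Point at arc-length position ``s`` along the polyline (clamped to [0, L])."""
    xy = p.as_array()
    seg = np.hypot(*np.diff(xy, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    s = float(np.clip(s, 0.0, cum[-1]))
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(seg) - 1)
    t = (s - cum[i]) / seg[i]
    pt = xy[i] + t * (xy[i + 1] - xy[i])
    return float(pt[0]), float(pt[1])


@dataclass
class AnnotationSet:
    """All polylines traced on one image, with provenance fields."""

    image_id: str
    polylines: list[Polyline] = field(default_factory=list)
    scale_um_per_px: float = 1.0
    author: str = ""
    created: str = ""

    def __post_init__(self) -> None:
        if not self.image_id:
            raise ValidationError("image_id must be non-empty")
        if not (self.scale_um_per_px > 0):
            raise ValidationError("scale_um_per_px must be > 0")

    def by_label(self, label: str) -> list[Polyline]:
        return [p for p in self.polylines if p.label == label]


def write_annotations(aset: AnnotationSet, path: str | Path) -> Path:
    doc = {
        "image_id": aset.image_id,
        "scale_um_per_px": aset.scale_um_per_px,
        "author": aset.author,
        "created": aset.created,
        "polylines": [
            {"label": p.label, "points": [[x, y] for x, y in p.points]} for p in aset.polylines
        ],
    }
    p = Path(path)
    p.write_text(json.dumps(doc, indent=1))
    return p


def read_annotations(path: str | Path) -> AnnotationSet:
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"cannot read annotation file: {p}")
    doc = json.loads(p.read_text())
    polylines = []
    for entry in doc.get("polylines", []):
        label = entry.get("label", "vessel")
        if label not in LABELS:
            raise ValidationError(
                f"unknown label {label!r} in {p}; allowed labels: {list(LABELS)}"
            )
        polylines.append(Polyline(tuple((x, y) for x, y in entry["points"]), label))
    return AnnotationSet(
        image_id=doc["image_id"],
        polylines=polylines,
        scale_um_per_px=float(doc.get("scale_um_per_px", 1.0)),
        author=doc.get("author", ""),
        created=doc.get("created", ""),
    )
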