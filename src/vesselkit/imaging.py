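"""Calibrated 2-D grayscale images: loading, z-projection, histogram equalization.

Images are held as float arrays in whatever range the source file used
(0–255 for 8-bit PNG, observed range for 16-bit TIFF); :func:`equalize_histogram`
maps to [0, 1]. All geometry elsewhere in the package is in pixel units with the
origin at the top-left corner, x increasing rightward (columns) and y downward
(rows); the µm-per-pixel calibration is only applied when densities are computed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image as _PILImage

from .errors import ValidationError

logger = logging.getLogger(__name__)

MODALITIES = ("fluorescent", "phase")


@dataclass
class Image2D:
    """A single calibrated grayscale raster.

    Parameters
    ----------
    pixels : ndarray
        2-D array of finite, non-negative intensities (any float range).
    scale_um_per_px : float
        Physical calibration, micrometres per pixel; must be positive.
    modality : {"fluorescent", "phase"}
        Imaging modality tag (bright-on-dark vessels vs. inverted-contrast).
    id : str
        Free-form image identifier used to match detections and annotations.
    """

    pixels: np.ndarray
    scale_um_per_px: float = 1.0
    modality: str = "fluorescent"
    id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError(f"image must be a non-empty 2-D raster, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValidationError("image intensities must all be finite")
        if px.min() < 0:
            raise ValidationError("image intensities must be non-negative")
        if not (self.scale_um_per_px > 0):
            raise ValidationError(f"scale_um_per_px must be > 0, got {self.scale_um_per_px}")
        if self.modality not in MODALITIES:
            raise ValidationError(f"modality must be one of {MODALITIES}, got {self.modality!r}")
        self.pixels = px

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def area_mm2(self) -> float:
        """Field area in mm² from the pixel count and µm/px calibration."""
        return self.width * self.height * self.scale_um_per_px**2 / 1e6


@dataclass
class ImageStack:
    """An ordered z-stack of same-shape 2-D slices sharing one calibration."""

    slices: list[np.ndarray] = field(default_factory=list)
    scale_um_per_px: float = 1.0

    def __post_init__(self) -> None:
        if len(self.slices) < 1:
            raise ValidationError("stack must contain at least one slice")
        arrs = [np.asarray(s, dtype=float) for s in self.slices]
        shape = arrs[0].shape
        for i, a in enumerate(arrs):
            if a.ndim != 2 or a.shape != shape:
                raise ValidationError(
                    f"all slices must share one 2-D shape; slice {i} has {a.shape}, expected {shape}"
                )
        if not (self.scale_um_per_px > 0):
            raise ValidationError("scale_um_per_px must be > 0")
        self.slices = arrs


def _collapse_channels(arr: np.ndarray) -> np.ndarray:
    """Collapse a channel-last colour image to one channel by plain channel mean.

    Alpha channels (4th channel of RGBA) are dropped before averaging.
    """
    if arr.ndim == 3:
        if arr.shape[-1] == 4:
            arr = arr[..., :3]
        arr = arr.mean(axis=-1)
    return arr


def load_image(
    path: str | Path,
    scale_um_per_px: float,
    modality: str = "fluorescent",
    image_id: str | None = None,
) -> Image2D:
    """Read a PNG or TIFF raster into an :class:`Image2D`.

    Multi-channel input is collapsed to a single channel by averaging the
    colour channels. The pixel scale is always supplied by the caller, never
    inferred from file metadata.
    """
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"cannot read image file: {p}")
    if p.suffix.lower() in (".tif", ".tiff"):
        arr = np.asarray(tifffile.imread(p))
        if arr.ndim == 3 and arr.shape[0] > 1 and arr.shape[-1] not in (3, 4):
            raise ValidationError(
                f"{p} is a multi-page TIFF; use load_stack() and max_projection()"
            )
    else:
        with _PILImage.open(p) as im:
            arr = np.asarray(im, dtype=float)
    arr = _collapse_channels(np.asarray(arr, dtype=float))
    if arr.size == 0:
        raise ValidationError(f"zero-size raster in {p}")
    return Image2D(arr, scale_um_per_px, modality, image_id if image_id is not None else p.stem)


def load_stack(path: str | Path, scale_um_per_px: float) -> ImageStack:
    """Read a multi-page TIFF (or single page) as an :class:`ImageStack`."""
    p = Path(path)
    if not p.is_file():
        raise FileNotFoundError(f"cannot read image file: {p}")
    arr = np.asarray(tifffile.imread(p), dtype=float)
    if arr.ndim == 2:
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValidationError(f"expected a stack of 2-D slices in {p}, got shape {arr.shape}")
    return ImageStack(list(arr), scale_um_per_px)


def max_projection(stack: ImageStack, modality: str = "fluorescent", image_id: str = "") -> Image2D:
    """Maximum-intensity z-projection: per-pixel max across slices."""
    proj = np.max(np.stack(stack.slices, axis=0), axis=0)
    return Image2D(proj, stack.scale_um_per_px, modality, image_id)


def equalize_histogram(image: Image2D) -> Image2D:
    """Global histogram equalization over the observed intensity range.

    Each distinct input value v is mapped to the empirical CDF at v, so the
    output is a monotone non-decreasing transform of input ranks spanning
    (0, 1]. A constant image has no contrast to equalize and is returned
    unchanged with a warning.
    """
    px = image.pixels
    if px.max() == px.min():
        logger.warning("equalize_histogram: constant image %r returned unchanged", image.id)
        return Image2D(px.copy(), image.scale_um_per_px, image.modality, image.id)
    values, inverse, counts = np.unique(px.ravel(), return_inverse=True, return_counts=True)
    cdf = np.cumsum(counts) / px.size
    out = cdf[inverse].reshape(px.shape)
    return Image2D(out, image.scale_um_per_px, image.modality, image.id)


def save_png(image: Image2D, path: str | Path) -> Path:
    """Write an image as 8-bit PNG, rescaling floats to the 0–255 range.

    Values in [0, 1] map linearly onto 0–255; wider ranges are normalized by
    their observed maximum first.
    """
    px = image.pixels
    top = px.max()
    if top > 1.0:
        px = px / top
    arr = np.clip(np.round(px * 255.0), 0, 255).astype(np.uint8)
    p = Path(path)
    _PILImage.fromarray(arr, mode="L").save(p)
    return p
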