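"""Synthetic microvessel scenes: ground-truth networks plus rendered images.

The generator emulates the qualitative features of angiogenesis-assay imagery
that drive measurement difficulty, without any biophysical simulation:

* vessels as branching correlated random walks (irregular, tortuous
  centerlines with side branches, as angiogenic sprouts are);
* per-vessel brightness drawn from a lognormal, emulating the intrinsic
  variation in fluorescence intensity between vessels;
* debris as short, thick, bright dashes — elongated non-vessel objects
  (endothelial cells, undigested tissue clumps) that confound pixel-based
  measurement because they pass a size filter and skeletonize to a length;
* out-of-plane objects: vessel-like walks rendered heavily blurred and dim,
  excluded from ground-truth vessel length;
* Gaussian read noise; fluorescent (bright-on-dark) or phase-contrast
  (dark-on-gray with halo) rendering.

Ground truth is an :class:`~vesselkit.annotation.AnnotationSet`, so the true
total vessel length is known exactly and independently of rendering. All
randomness is derived from the scene seed through separate substreams for
vessels, out-of-plane objects, debris, and rendering, so e.g. changing
``n_debris`` leaves the vessel network untouched.
"""
from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field, replace
from typing import Iterable

import numpy as np
from scipy.ndimage import gaussian_filter

from .annotation import AnnotationSet, Polyline, polyline_length
from .errors import ValidationError
from .imaging import MODALITIES, Image2D

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class SceneParams:
    """Knobs of one synthetic scene (lengths in pixels, angles in radians)."""

    field_px: tuple[int, int] = (512, 512)
    scale_um_per_px: float = 0.65
    n_seeds: int = 4
    branch_prob: float = 0.015
    step_px: float = 4.0
    n_steps: int = 50
    tortuosity_sd: float = 0.1
    vessel_width_px: float = 4.0
    intensity_cv: float = 0.3
    n_debris: int = 6
    debris_size_px: tuple[float, float] = (8.0, 16.0)
    n_out_of_plane: int = 2
    blur_sigma_px: float = 6.0
    noise_sd: float = 0.02
    modality: str = "fluorescent"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_px[0] < 8 or self.field_px[1] < 8:
            raise ValidationError("field_px must be at least 8x8")
        if not (self.scale_um_per_px > 0):
            raise ValidationError("scale_um_per_px must be > 0")
        for name in ("n_seeds", "n_debris", "n_out_of_plane", "n_steps"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0.0 <= self.branch_prob <= 1.0):
            raise ValidationError("branch_prob must be in [0, 1]")
        if not (self.step_px > 0 and self.vessel_width_px > 0 and self.blur_sigma_px > 0):
            raise ValidationError("step_px, vessel_width_px and blur_sigma_px must be > 0")
        if self.tortuosity_sd < 0 or self.intensity_cv < 0 or self.noise_sd < 0:
            raise ValidationError("tortuosity_sd, intensity_cv and noise_sd must be >= 0")
        if self.debris_size_px[0] > self.debris_size_px[1] or self.debris_size_px[0] <= 0:
            raise ValidationError("debris_size_px must be a positive (low, high) range")
        if self.modality not in MODALITIES:
            raise ValidationError(f"modality must be one of {MODALITIES}")

    @property
    def image_id(self) -> str:
        return f"scene-{self.seed}"


@dataclass
class SyntheticScene:
    image: Image2D
    truth: AnnotationSet
    params: SceneParams

    def __post_init__(self) -> None:
        if self.truth.image_id != self.image.id:
            raise ValidationError("scene truth and image must share one image_id")

    @property
    def truth_vessel_length_px(self) -> float:
        return sum(polyline_length(p) for p in self.truth.by_label("vessel"))

    @property
    def truth_vessel_length_um(self) -> float:
        return self.truth_vessel_length_px * self.params.scale_um_per_px


def _walk(
    rng: np.random.Generator,
    start: np.ndarray,
    heading: float,
    n_steps: int,
    params: SceneParams,
) -> tuple[list[tuple[float, float]], list[tuple[int, np.ndarray, float]]]:
    """One correlated random walk; returns points and (step, pos, heading) branch events."""
    W, H = params.field_px
    pts = [(float(start[0]), float(start[1]))]
    pos = start.astype(float).copy()
    branches: list[tuple[int, np.ndarray, float]] = []
    for t in range(n_steps):
        if params.tortuosity_sd > 0:
            heading += rng.normal(0.0, params.tortuosity_sd)
        nxt = pos + params.step_px * np.array([math.cos(heading), math.sin(heading)])
        inside = 0.0 <= nxt[0] <= W - 1 and 0.0 <= nxt[1] <= H - 1
        if not inside:
            nxt = np.clip(nxt, [0.0, 0.0], [W - 1.0, H - 1.0])
            if tuple(nxt) != pts[-1]:
                pts.append((float(nxt[0]), float(nxt[1])))
            break
        pos = nxt
        pts.append((float(pos[0]), float(pos[1])))
        if params.branch_prob > 0 and rng.random() < params.branch_prob:
            branches.append((t, pos.copy(), heading))
    return pts, branches


def grow_network(params: SceneParams) -> AnnotationSet:
    """Grow the ground-truth annotation set for one scene.

    Each of ``n_seeds`` vessel fragments is a correlated random walk of up to
    ``n_steps`` steps of ``step_px`` whose heading is perturbed by
    Normal(0, tortuosity_sd) at every step; with probability ``branch_prob``
    per step a side branch sprouts at ±~45° and walks out the remaining steps
    (branches do not branch again, so branch counts per walk are binomial).
    Growth is clipped at the field border. Out-of-plane objects are shorter
    walks of their own label; debris are 3-point dashes whose chain length is
    drawn from ``debris_size_px``.
    """
    W, H = params.field_px
    rng_vessel = np.random.default_rng([params.seed, 0])
    rng_oop = np.random.default_rng([params.seed, 1])
    rng_debris = np.random.default_rng([params.seed, 2])
    polylines: list[Polyline] = []

    def _start(rng: np.random.Generator) -> np.ndarray:
        return np.array(
            [rng.uniform(0.1 * W, 0.9 * W), rng.uniform(0.1 * H, 0.9 * H)]
        )

    for _ in range(params.n_seeds):
        pts, branches = _walk(
            rng_vessel, _start(rng_vessel), rng_vessel.uniform(0, 2 * math.pi),
            params.n_steps, params,
        )
        if len(pts) >= 2:
            polylines.append(Polyline(tuple(pts), "vessel"))
        for t, pos, heading in branches:
            side = rng_vessel.choice([-1.0, 1.0])
            b_heading = heading + side * (math.pi / 4 + rng_vessel.normal(0.0, 0.2))
            b_params = replace(params, branch_prob=0.0)
            b_pts, _ = _walk(rng_vessel, pos, b_heading, params.n_steps - t, b_params)
            if len(b_pts) >= 2:
                polylines.append(Polyline(tuple(b_pts), "vessel"))

    for _ in range(params.n_out_of_plane):
        o_params = replace(params, branch_prob=0.0)
        pts, _ = _walk(
            rng_oop, _start(rng_oop), rng_oop.uniform(0, 2 * math.pi),
            max(2, params.n_steps // 2), o_params,
        )
        if len(pts) >= 2:
            polylines.append(Polyline(tuple(pts), "out_of_plane"))

    lo, hi = params.debris_size_px
    for _ in range(params.n_debris):
        center = _start(rng_debris)
        size = rng_debris.uniform(lo, hi)
        heading = rng_debris.uniform(0, 2 * math.pi)
        bend = rng_debris.normal(0.0, 0.4)
        u = np.array([math.cos(heading), math.sin(heading)])
        v = np.array([math.cos(heading + bend), math.sin(heading + bend)])
        a = center - u * size / 2
        b = center
        c = center + v * size / 2
        pts = [tuple(np.clip(p, [0, 0], [W - 1, H - 1])) for p in (a, b, c)]
        deduped = [pts[0]] + [p for prev, p in zip(pts, pts[1:]) if p != prev]
        if len(deduped) >= 2:
            polylines.append(Polyline(tuple((float(x), float(y)) for x, y in deduped), "debris"))

    return AnnotationSet(params.image_id, polylines, params.scale_um_per_px)


def _stamp(layer: np.ndarray, p: Polyline, amplitude: float) -> None:
    """Burn a polyline into a layer as a 1-px centerline at the given amplitude."""
    h, w = layer.shape
    xy = p.as_array()
    for a, b in zip(xy, xy[1:]):
        n = max(2, int(math.ceil(np.hypot(*(b - a)) / 0.4)) + 1)
        xs = np.clip(np.rint(np.linspace(a[0], b[0], n)).astype(int), 0, w - 1)
        ys = np.clip(np.rint(np.linspace(a[1], b[1], n)).astype(int), 0, h - 1)
        np.maximum.at(layer, (ys, xs), amplitude)


def _ridge(layer: np.ndarray, sigma: float) -> np.ndarray:
    """Blur a stamped centerline layer into ridges of peak ≈ stamped amplitude."""
    return gaussian_filter(layer, sigma) * sigma * _SQRT_2PI


def render(truth: AnnotationSet, params: SceneParams) -> Image2D:
    """Render a scene's image from its ground truth. Deterministic given the seed."""
    W, H = params.field_px
    rng = np.random.default_rng([params.seed, 3])
    sigma_v = params.vessel_width_px / 2.0

    vessel_layer = np.zeros((H, W))
    lg_sd = math.sqrt(math.log(1.0 + params.intensity_cv**2))
    for p in truth.by_label("vessel"):
        amp = 1.0 if lg_sd == 0 else float(rng.lognormal(-lg_sd**2 / 2.0, lg_sd))
        _stamp(vessel_layer, p, max(0.2, min(amp, 2.5)))
    vessels = _ridge(vessel_layer, sigma_v)

    oop_layer = np.zeros((H, W))
    for p in truth.by_label("out_of_plane"):
        _stamp(oop_layer, p, 1.0)
    oop = _ridge(oop_layer, params.blur_sigma_px) * 0.5

    debris = np.zeros((H, W))
    for p in truth.by_label("debris"):
        width = max(2.0, polyline_length(p) / 3.0)
        single = np.zeros((H, W))
        amp = float(np.clip(rng.lognormal(-lg_sd**2 / 2.0, lg_sd), 0.4, 2.0)) if lg_sd else 1.0
        _stamp(single, p, amp)
        debris = np.maximum(debris, _ridge(single, width / 2.0))

    if params.modality == "fluorescent":
        img = 0.05 + vessels + 0.9 * debris + oop
    else:
        halo = gaussian_filter(vessel_layer, 3.0 * sigma_v) * 3.0 * sigma_v * _SQRT_2PI
        img = (
            0.6
            - 0.35 * np.clip(vessels, 0, 1)
            - 0.3 * np.clip(debris, 0, 1)
            - 0.15 * np.clip(oop, 0, 1)
            + 0.08 * np.clip(halo, 0, 1)
        )
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)
    return Image2D(img, params.scale_um_per_px, params.modality, params.image_id)


def make_scene(params: SceneParams) -> SyntheticScene:
    truth = grow_network(params)
    image = render(truth, params)
    return SyntheticScene(image, truth, params)


def density_grid(
    n_seeds_levels: Iterable[int] = (2, 4, 8),
    modalities: Iterable[str] = ("fluorescent",),
) -> list[dict]:
    """Low/medium/high vessel-density parameter grid, per modality.

    The default levels bracket the default seed count (half to double),
    emulating treatment groups with differing levels of angiogenesis.
    """
    return [
        {"n_seeds": n, "modality": m} for n in n_seeds_levels for m in modalities
    ]


def generate_benchmark(
    params_grid: list[dict], n_scenes: int, seed: int = 0
) -> list[SyntheticScene]:
    """A reproducible scene collection: ``len(params_grid) × n_scenes`` scenes.

    Each grid entry is a dict of :class:`SceneParams` overrides; every scene
    gets its own RNG stream derived from the master seed and scene index, so
    collections are reproducible under any generation order.
    """
    if not params_grid:
        raise ValidationError("params_grid must be non-empty")
    if n_scenes < 1:
        raise ValidationError("n_scenes must be >= 1")
    base = asdict(SceneParams())
    scenes: list[SyntheticScene] = []
    idx = 0
    for overrides in params_grid:
        for _ in range(n_scenes):
            scene_seed = (seed * 1_000_003 + idx * 7_919 + 17) % (2**31)
            merged = {**base, **overrides, "seed": scene_seed}
            merged["field_px"] = tuple(merged["field_px"])
            merged["debris_size_px"] = tuple(merged["debris_size_px"])
            scenes.append(make_scene(SceneParams(**merged)))
            idx += 1
    return scenes


def benchmark_manifest(scenes: list[SyntheticScene]) -> "pd.DataFrame":  # noqa: F821
    import pandas as pd

    rows = []
    for s in scenes:
        rows.append(
            {
                "scene_id": s.image.id,
                "modality": s.params.modality,
                "truth_length_um": s.truth_vessel_length_um,
                "n_seeds": s.params.n_seeds,
                "seed": s.params.seed,
            }
        )
    return pd.DataFrame(rows)
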