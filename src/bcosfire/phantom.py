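"""Synthetic fundus-like phantoms with known vessel ground truth.

A phantom is a bright field-of-view disc on a dark surround, carrying dark
curvilinear vessels and, optionally, small dark background blobs (the
"artifacts" that the postprocessing stage is meant to delete) plus additive
Gaussian noise and a mild illumination gradient.  Vessels follow smooth
random-walk centerlines and darken the background with a Gaussian cross
profile — the standard model of a retinal vessel's intensity cross section —
whose full width at half maximum is the vessel width; the ground-truth mask
is the region where the darkening exceeds half its peak, so the mask width
equals the nominal vessel width.

Artifacts are stamped as the exact number of pixels requested (the nearest
pixels to a random center), strictly disjoint from the vessel mask and from
each other, so component-area assertions and artifact-size recovery have
well-defined answers.  Everything is a deterministic function of the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .raster_io import DatasetItem

#: FWHM of a Gaussian = _FWHM * sigma
_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))


class PhantomGenerationError(RuntimeError):
    """Raised when artifacts cannot be packed into the disc."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generation parameters; the defaults define the standard test conditions.

    The default artifact areas (4-18 px) stay strictly below any vessel
    component's area, so the optimal background-artifact size is well defined.
    """

    height: int = 256
    width: int = 256
    n_vessels: int = 4
    width_range: tuple[float, float] = (3.0, 6.0)
    contrast: float = 0.5
    curvature: float = 0.08
    n_artifacts: int = 6
    artifact_area_range: tuple[int, int] = (4, 18)
    noise_sd: float = 0.02
    illumination_gradient: float = 0.1
    vessel_reflex: bool = False
    background: float = 0.78
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.height, self.width) < 32:
            raise ValueError("phantom dimensions must be at least 32 pixels")
        if not 0.0 <= self.contrast <= 1.0:
            raise ValueError("contrast must lie in [0, 1]")
        if self.artifact_area_range[0] < 1:
            raise ValueError("artifact areas must be at least 1 pixel")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class PhantomSample:
    image: np.ndarray
    gt: np.ndarray
    fov: np.ndarray
    artifact_mask: np.ndarray


def _fov_disc(h: int, w: int) -> np.ndarray:
    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = 0.46 * min(h, w)
    return ((ys - cy) ** 2 + (xs - cx) ** 2 <= radius**2).astype(np.uint8)


def _walk_centerline(
    rng: np.random.Generator, h: int, w: int, curvature: float
) -> np.ndarray:
    """Smooth random-walk centerline crossing the disc; (N, 2) of (y, x)."""
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = 0.46 * min(h, w)
    start_angle = rng.uniform(0.0, 2.0 * math.pi)
    y = cy + 0.92 * radius * math.sin(start_angle)
    x = cx + 0.92 * radius * math.cos(start_angle)
    heading = start_angle + math.pi + rng.uniform(-0.5, 0.5)
    points = []
    for _ in range(int(4 * radius)):
        points.append((y, x))
        heading += rng.normal(0.0, curvature)
        y += math.sin(heading)
        x += math.cos(heading)
        if (y - cy) ** 2 + (x - cx) ** 2 > (1.02 * radius) ** 2:
            break
    return np.asarray(points)


def _vessel_field(
    rng: np.random.Generator, spec: PhantomSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Darkening field (max over vessels) and ground-truth mask."""
    h, w = spec.height, spec.width
    darkening = np.zeros((h, w), dtype=np.float64)
    gt = np.zeros((h, w), dtype=bool)
    if spec.contrast == 0.0 or spec.n_vessels == 0:
        return darkening, gt.astype(np.uint8)
    for _ in range(spec.n_vessels):
        width = rng.uniform(*spec.width_range)
        sigma_v = width / _FWHM
        pts = _walk_centerline(rng, h, w, spec.curvature)
        canvas = np.zeros((h, w), dtype=bool)
        ys = np.clip(np.round(pts[:, 0]).astype(int), 0, h - 1)
        xs = np.clip(np.round(pts[:, 1]).astype(int), 0, w - 1)
        canvas[ys, xs] = True
        dist = ndimage.distance_transform_edt(~canvas)
        profile = spec.contrast * np.exp(-(dist**2) / (2.0 * sigma_v**2))
        if spec.vessel_reflex:
            profile -= 0.3 * spec.contrast * np.exp(-(dist**2) / (2.0 * (0.3 * sigma_v) ** 2))
        np.maximum(darkening, profile, out=darkening)
        gt |= dist <= sigma_v * math.sqrt(2.0 * math.log(2.0))
    return darkening, gt.astype(np.uint8)


def _stamp_blob(center: tuple[int, int], area: int, h: int, w: int) -> np.ndarray:
    """Boolean mask of exactly ``area`` pixels nearest to ``center``."""
    cy, cx = center
    r = int(math.ceil(math.sqrt(area / math.pi))) + 2
    ys, xs = np.mgrid[max(cy - r, 0) : min(cy + r + 1, h), max(cx - r, 0) : min(cx + r + 1, w)]
    d2 = (ys - cy) ** 2 + (xs - cx) ** 2
    flat = np.argsort(d2.ravel(), kind="stable")[:area]
    mask = np.zeros((h, w), dtype=bool)
    mask[ys.ravel()[flat], xs.ravel()[flat]] = True
    return mask


_EIGHT = ndimage.generate_binary_structure(2, 2)


def _artifact_field(
    rng: np.random.Generator, spec: PhantomSpec, gt: np.ndarray, fov: np.ndarray
) -> np.ndarray:
    h, w = spec.height, spec.width
    forbidden = ndimage.binary_dilation(gt > 0, structure=_EIGHT, iterations=3)
    eroded_fov = ndimage.binary_erosion(fov > 0, structure=_EIGHT, iterations=8)
    artifact = np.zeros((h, w), dtype=bool)
    lo, hi = spec.artifact_area_range
    for i in range(spec.n_artifacts):
        placed = False
        for _ in range(300):
            area = int(rng.integers(lo, hi + 1))
            cy = int(rng.integers(0, h))
            cx = int(rng.integers(0, w))
            if not eroded_fov[cy, cx]:
                continue
            blob = _stamp_blob((cy, cx), area, h, w)
            # keep a 1-px gap to other artifacts so components stay separate
            grown = ndimage.binary_dilation(blob, structure=_EIGHT)
            if (blob & forbidden).any() or (grown & artifact).any():
                continue
            if not (blob <= eroded_fov).all():
                continue
            artifact |= blob
            placed = True
            break
        if not placed:
            raise PhantomGenerationError(
                f"could not place artifact {i + 1}/{spec.n_artifacts} after 300 tries"
            )
    return artifact.astype(np.uint8)


def generate(spec: PhantomSpec) -> PhantomSample:
    """Generate one phantom; fully determined by ``spec`` (including its seed)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    fov = _fov_disc(h, w)

    ys, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    background = spec.background + spec.illumination_gradient * (
        (xs + ys) / (h + w) - 0.5
    )

    darkening, gt = _vessel_field(rng, spec)
    gt = (gt & (fov > 0)).astype(np.uint8)

    if spec.n_artifacts > 0 and spec.contrast > 0.0:
        artifact_mask = _artifact_field(rng, spec, gt, fov)
    else:
        artifact_mask = np.zeros((h, w), dtype=np.uint8)

    image = background - darkening - spec.contrast * artifact_mask
    image = np.where(fov > 0, image, 0.03)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, size=(h, w))
    return PhantomSample(
        image=np.clip(image, 0.0, 1.0),
        gt=gt,
        fov=fov,
        artifact_mask=artifact_mask,
    )


def make_suite(
    n_images: int, template: PhantomSpec | None = None, seed: int = 0
) -> list[DatasetItem]:
    """Generate ``n_images`` phantoms with per-image seeds derived from ``seed``."""
    if n_images < 1:
        raise ValueError("n_images must be at least 1")
    template = template if template is not None else PhantomSpec()
    child_seeds = np.random.default_rng(seed).integers(0, 2**31 - 1, size=n_images)
    items = []
    for i, child in enumerate(child_seeds):
        sample = generate(replace(template, seed=int(child)))
        items.append(
            DatasetItem(
                image=sample.image,
                identifier=f"phantom{i:03d}",
                fov_mask=sample.fov,
                gt_mask=sample.gt,
            )
        )
    return items
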