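"""Raster input/output and dataset discovery.

Images are exposed as ``numpy`` arrays with a fixed coordinate convention:
row-major, 0-based, ``(row, col) == (y, x)``, origin at the top-left corner.
Intensities are rescaled to ``[0, 1]`` on read so that thresholds expressed
as fractions are independent of the source bit depth.  Binary masks (field
of view, ground truth) hold ``{0, 1}`` in ``uint8``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np

log = logging.getLogger(__name__)

#: recognised raster suffixes (read side)
RASTER_SUFFIXES = (".png", ".tif", ".tiff", ".ppm", ".pgm", ".gif", ".jpg", ".jpeg")


class RasterFormatError(ValueError):
    """Raised when a file cannot be decoded as a supported raster."""


class PairingError(ValueError):
    """Raised when dataset roles cannot be paired consistently."""


@dataclass
class DatasetItem:
    """One dataset entry: an image plus optional FOV and ground-truth masks."""

    image: np.ndarray
    identifier: str
    fov_mask: np.ndarray | None = None
    gt_mask: np.ndarray | None = None
    path: Path | None = None

    def __post_init__(self) -> None:
        shape = self.image.shape[:2]
        for name, mask in (("fov_mask", self.fov_mask), ("gt_mask", self.gt_mask)):
            if mask is not None and mask.shape != shape:
                raise PairingError(
                    f"{name} shape {mask.shape} does not match image shape "
                    f"{shape} for item '{self.identifier}'"
                )


def _rescale(pixels: np.ndarray) -> np.ndarray:
    """Map an integer/bool/float raster to float64 in [0, 1]."""
    if pixels.dtype == np.bool_:
        return pixels.astype(np.float64)
    if np.issubdtype(pixels.dtype, np.integer):
        info = np.iinfo(pixels.dtype)
        return pixels.astype(np.float64) / float(info.max)
    out = pixels.astype(np.float64)
    if out.size and out.max() > 1.0:  # float image stored on a 0..255 scale
        out = out / 255.0
    return np.clip(out, 0.0, 1.0)


def read_image(path: str | Path) -> np.ndarray:
    """Read a raster file as float64 in [0, 1].

    Returns a 2-D array for single-channel files and an (H, W, 3) array for
    color files; an alpha channel, if present, is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise RasterFormatError(f"no such raster file: {path}")
    try:
        pixels = np.asarray(iio.imread(path))
    except Exception as exc:  # pragma: no cover - backend specific
        raise RasterFormatError(f"cannot decode raster file {path}: {exc}") from exc
    if pixels.ndim == 3 and pixels.shape[2] == 4:
        pixels = pixels[:, :, :3]
    if pixels.ndim == 3 and pixels.shape[2] == 1:
        pixels = pixels[:, :, 0]
    if pixels.ndim not in (2, 3) or min(pixels.shape[:2]) < 1:
        raise RasterFormatError(f"unsupported raster geometry {pixels.shape} in {path}")
    bit_depth = pixels.dtype.itemsize * 8 if np.issubdtype(pixels.dtype, np.integer) else None
    log.debug("read %s: shape=%s bit_depth=%s", path, pixels.shape, bit_depth)
    return _rescale(pixels)


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    """Write an array as an 8-bit PNG; floats are assumed to live in [0, 1]."""
    path = Path(path)
    arr = np.asarray(pixels)
    if np.issubdtype(arr.dtype, np.floating):
        arr = np.round(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)
    elif arr.dtype == np.bool_ or (np.issubdtype(arr.dtype, np.integer) and arr.max(initial=0) <= 1):
        arr = (arr > 0).astype(np.uint8) * 255
    else:
        arr = arr.astype(np.uint8)
    iio.imwrite(path, arr)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a raster as a {0, 1} binary mask (threshold 0.5 after rescale)."""
    pixels = read_image(path)
    if pixels.ndim == 3:
        pixels = pixels[:, :, 0]
    if min(pixels.shape) < 1:
        raise RasterFormatError(f"degenerate mask shape {pixels.shape} in {path}")
    return (pixels > 0.5).astype(np.uint8)


# --- dataset discovery -------------------------------------------------------

#: built-in directory layouts: role -> glob, plus the pairing-key rule.
#: "stem" pairs files by full stem, "prefix" by the text before the first
#: underscore (the DRIVE convention, where 21_training / 21_manual1 /
#: 21_training_mask describe one eye).
BUILTIN_LAYOUTS: dict[str, dict[str, str]] = {
    "flat": {"image": "images/*", "gt": "gt/*", "fov": "fov/*", "key": "stem"},
    "drive": {
        "image": "images/*",
        "gt": "1st_manual/*",
        "fov": "mask/*",
        "key": "prefix",
    },
    "stare": {"image": "stare-images/*", "gt": "labels-ah/*", "key": "prefix"},
    "chase_db1": {"image": "images/*", "gt": "gt/*", "key": "prefix"},
}


def _pair_key(path: Path, rule: str) -> str:
    stem = path.stem
    if rule == "prefix":
        return re.split(r"[_.]", stem, maxsplit=1)[0]
    return stem


def load_layout(source: str | Path | Mapping[str, str]) -> dict[str, str]:
    """Resolve a layout name, ``key=value`` file, or mapping to a role->glob dict."""
    if isinstance(source, Mapping):
        return dict(source)
    name = str(source)
    if name in BUILTIN_LAYOUTS:
        return dict(BUILTIN_LAYOUTS[name])
    path = Path(source)
    if path.is_file():
        layout: dict[str, str] = {}
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            layout[key.strip()] = value.strip()
        return layout
    raise ValueError(f"unknown dataset layout: {source!r}")


def discover_dataset(
    root: str | Path, layout: str | Path | Mapping[str, str] = "flat"
) -> list[DatasetItem]:
    """Scan a directory tree and pair image / FOV / ground-truth files.

    Items are paired by filename key (full stem, or the pre-underscore prefix
    for DRIVE-style naming).  Missing FOV or GT files are recorded as absent,
    never fabricated.  An image/GT shape mismatch raises :class:`PairingError`.
    """
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(f"dataset root does not exist: {root}")
    spec = load_layout(layout)
    key_rule = spec.pop("key", "stem")
    if "image" not in spec:
        raise ValueError("layout must define an 'image' glob")

    files: dict[str, dict[str, Path]] = {}
    for role, pattern in spec.items():
        for path in sorted(root.glob(pattern)):
            if path.suffix.lower() not in RASTER_SUFFIXES or not path.is_file():
                continue
            files.setdefault(role, {})[_pair_key(path, key_rule)] = path

    items: list[DatasetItem] = []
    for key, img_path in sorted(files.get("image", {}).items()):
        image = read_image(img_path)
        gt_path = files.get("gt", {}).get(key)
        fov_path = files.get("fov", {}).get(key)
        gt = read_mask(gt_path) if gt_path else None
        fov = read_mask(fov_path) if fov_path else None
        items.append(
            DatasetItem(image=image, identifier=key, fov_mask=fov, gt_mask=gt, path=img_path)
        )
    return items
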