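"""Channel extraction, response suppression, and field-of-view handling.

The green channel of a fundus photograph carries the best vessel/background
contrast, so all filtering operates on it.  The *preprocessing threshold*
suppresses weak rectified DoG responses before the COSFIRE combination
stage: every response below a fraction ``p`` of the map's maximum is zeroed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessParams:
    """Preprocessing settings.

    preprocessing_threshold
        Fraction of each DoG response map's maximum below which responses are
        zeroed (the first optimized parameter; searched over 0.1-0.6).
    invert
        Invert intensities before filtering.  Vessels are darker than the
        background in the green channel and the DoG kernel used here responds
        to dark lines, so this defaults to off; phantom generators that draw
        bright vessels can switch it on.
    auto_fov
        Estimate a field-of-view mask from image brightness when none is given.
    """

    preprocessing_threshold: float = 0.3
    invert: bool = False
    auto_fov: bool = False
    fov_threshold: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.preprocessing_threshold <= 1.0:
            raise ValueError(
                f"preprocessing_threshold must lie in [0, 1], got "
                f"{self.preprocessing_threshold}"
            )


def extract_green(raster: np.ndarray) -> np.ndarray:
    """Return the green channel of an RGB raster (values in [0, 1]).

    A single-channel input is returned unchanged (with a log note) so that
    grayscale phantoms flow through the same pipeline.
    """
    raster = np.asarray(raster, dtype=np.float64)
    if raster.ndim == 2:
        log.info("extract_green: input is single-channel; returned unchanged")
        return raster
    if raster.ndim == 3 and raster.shape[2] == 3:
        return raster[:, :, 1]
    raise ValueError(f"expected a 3-channel raster, got shape {raster.shape}")


def suppress_low(responses: np.ndarray, p: float) -> np.ndarray:
    """Zero every response below ``p`` times the map maximum.

    The operation is idempotent and anti-extensive: no pixel value ever
    increases, and the zeroed set grows monotonically with ``p``.  An all-zero
    map is returned unchanged.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"suppression fraction must lie in [0, 1], got {p}")
    responses = np.asarray(responses, dtype=np.float64)
    if responses.size and responses.min() < -1e-12:
        raise ValueError("suppress_low expects non-negative responses")
    m = responses.max(initial=0.0)
    if m <= 0.0:
        return responses.copy()
    return np.where(responses >= p * m, responses, 0.0)


_EIGHT = ndimage.generate_binary_structure(2, 2)


def make_fov(image: np.ndarray, threshold: float = 0.1) -> np.ndarray:
    """Estimate a field-of-view mask as the largest bright connected component.

    Pixels above ``threshold`` are labelled (8-connected); the largest
    component is kept and its holes filled.  If nothing exceeds the threshold
    an all-zero mask is returned with a warning.
    """
    image = np.asarray(image, dtype=np.float64)
    bright = image > threshold
    if not bright.any():
        log.warning("make_fov: no pixel above threshold %.3f; empty mask", threshold)
        return np.zeros(image.shape, dtype=np.uint8)
    labels, n = ndimage.label(bright, structure=_EIGHT)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(keep).astype(np.uint8)


def fill_outside_fov(image: np.ndarray, fov: np.ndarray | None) -> np.ndarray:
    """Replace pixels outside the FOV with the nearest inside-FOV intensity.

    Replicating border intensities prevents the strong spurious filter
    responses the camera-aperture rim would otherwise produce.
    """
    if fov is None:
        return image
    inside = np.asarray(fov, dtype=bool)
    if inside.all():
        return image
    if not inside.any():
        return image
    idx = ndimage.distance_transform_edt(
        ~inside, return_distances=False, return_indices=True
    )
    return image[tuple(idx)]
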