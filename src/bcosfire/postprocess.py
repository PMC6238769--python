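"""Binarization and background-artifact removal.

Three removal algorithms act on the binarized response:

* ``component_filter`` deletes every 8-connected component strictly smaller
  than the background-artifact size.
* ``kmedian`` clusters component areas into two groups by a deterministic
  1-D 2-median and deletes the low group when its median area falls below
  the artifact size.
* ``bw_clearance`` removes small components and then fills small 4-connected
  background holes.

All three are anti-extensive on components (no foreground is ever added),
except for the hole filling, which only converts enclosed background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

_EIGHT = ndimage.generate_binary_structure(2, 2)
_FOUR = ndimage.generate_binary_structure(2, 1)

REMOVAL_ALGORITHMS = ("component_filter", "kmedian", "bw_clearance")


@dataclass(frozen=True)
class SegmentationParams:
    """The three optimized parameters plus the removal-algorithm choice.

    filter_threshold is kept on its searched integer-percent scale (25-50)
    and divided by 100 wherever a fraction is required.
    """

    preprocessing_threshold: float = 0.3
    filter_threshold: int = 30
    artifact_size: int = 0
    removal_algorithm: str = "component_filter"
    hole_size: int | None = None

    def __post_init__(self) -> None:
        if self.filter_threshold < 0:
            raise ValueError("filter_threshold must be non-negative")
        if self.artifact_size < 0:
            raise ValueError("artifact_size must be non-negative")
        if self.removal_algorithm not in REMOVAL_ALGORITHMS:
            raise ValueError(
                f"unknown removal algorithm {self.removal_algorithm!r}; "
                f"expected one of {REMOVAL_ALGORITHMS}"
            )


def binarize(response: np.ndarray, filter_threshold: int | float) -> np.ndarray:
    """Threshold a response map at ``filter_threshold`` percent of its maximum.

    A pixel survives when its response is positive and at least
    ``filter_threshold/100`` times the map maximum; an all-zero response
    yields an all-zero mask.
    """
    if filter_threshold < 0:
        raise ValueError("filter_threshold must be non-negative")
    response = np.asarray(response, dtype=np.float64)
    if response.size and response.min() < -1e-12:
        raise ValueError("binarize expects a non-negative response")
    peak = response.max(initial=0.0)
    if peak <= 0.0:
        return np.zeros(response.shape, dtype=np.uint8)
    thr = (float(filter_threshold) / 100.0) * peak
    return ((response >= thr) & (response > 0.0)).astype(np.uint8)


def _component_areas(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels, n = ndimage.label(np.asarray(mask) > 0, structure=_EIGHT)
    if n == 0:
        return labels, np.array([], dtype=np.int64)
    areas = ndimage.sum_labels(
        np.ones_like(labels), labels, index=np.arange(1, n + 1)
    ).astype(np.int64)
    return labels, areas


def remove_small_components(mask: np.ndarray, artifact_size: int) -> np.ndarray:
    """Delete every 8-connected component with area strictly below the size.

    A component whose area equals ``artifact_size`` is kept; sizes 0 and 1
    are identities.
    """
    labels, areas = _component_areas(mask)
    out = (np.asarray(mask) > 0).astype(np.uint8)
    if areas.size == 0 or artifact_size <= 1:
        return out
    small = np.flatnonzero(areas < artifact_size) + 1
    if small.size:
        out[np.isin(labels, small)] = 0
    return out


def _two_median_split(areas: np.ndarray) -> np.ndarray:
    """Deterministic 1-D 2-median clustering of component areas.

    Centers start at the minimum and maximum area; points go to the nearest
    center (ties to the low cluster); centers move to their cluster medians;
    iterate to convergence.  Returns a boolean array, True for the low group.
    """
    lo, hi = float(areas.min()), float(areas.max())
    assign = np.abs(areas - lo) <= np.abs(areas - hi)
    for _ in range(100):
        if assign.all() or not assign.any():
            break
        lo = float(np.median(areas[assign]))
        hi = float(np.median(areas[~assign]))
        new = np.abs(areas - lo) <= np.abs(areas - hi)
        if np.array_equal(new, assign):
            break
        assign = new
    return assign


def kmedian_removal(mask: np.ndarray, artifact_size: int) -> np.ndarray:
    """Remove the low-area cluster of components when it looks like noise.

    Component areas are split into two groups by 1-D 2-median clustering;
    the low group is deleted iff its median area is strictly below
    ``artifact_size``.  Masks with fewer than two components, or with all
    components of equal area, are returned unchanged.
    """
    labels, areas = _component_areas(mask)
    out = (np.asarray(mask) > 0).astype(np.uint8)
    if areas.size <= 1 or np.all(areas == areas[0]):
        return out
    low = _two_median_split(areas)
    if not low.any() or low.all():
        return out
    if float(np.median(areas[low])) < artifact_size:
        doomed = np.flatnonzero(low) + 1
        out[np.isin(labels, doomed)] = 0
    return out


def fill_small_holes(mask: np.ndarray, hole_size: int) -> np.ndarray:
    """Fill every 4-connected background hole with area strictly below the size.

    A hole is a background component not touching the image border (the
    standard 8-connected-foreground / 4-connected-background duality).
    """
    out = (np.asarray(mask) > 0).astype(np.uint8)
    if hole_size <= 1:
        return out
    bg_labels, n = ndimage.label(out == 0, structure=_FOUR)
    if n == 0:
        return out
    border = np.unique(
        np.concatenate(
            [bg_labels[0, :], bg_labels[-1, :], bg_labels[:, 0], bg_labels[:, -1]]
        )
    )
    areas = ndimage.sum_labels(
        np.ones_like(bg_labels), bg_labels, index=np.arange(1, n + 1)
    ).astype(np.int64)
    fill = [
        lab
        for lab in range(1, n + 1)
        if lab not in border and areas[lab - 1] < hole_size
    ]
    if fill:
        out[np.isin(bg_labels, fill)] = 1
    return out


def bw_clearance(
    mask: np.ndarray, artifact_size: int, hole_size: int | None = None
) -> np.ndarray:
    """Black-and-white clearance: drop small objects, then fill small holes.

    ``hole_size`` defaults to half the artifact size (rounded down).
    """
    if hole_size is None:
        hole_size = artifact_size // 2
    return fill_small_holes(remove_small_components(mask, artifact_size), hole_size)


def remove_artifacts(mask: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Dispatch to the removal algorithm named in ``params``."""
    if params.removal_algorithm == "component_filter":
        return remove_small_components(mask, params.artifact_size)
    if params.removal_algorithm == "kmedian":
        return kmedian_removal(mask, params.artifact_size)
    return bw_clearance(mask, params.artifact_size, params.hole_size)
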