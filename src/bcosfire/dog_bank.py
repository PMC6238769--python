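"""Difference-of-Gaussians kernels and half-wave-rectified responses.

The DoG kernel is the difference of two isotropic Gaussians sharing a
center: an outer one of standard deviation sigma and an inner one of
standard deviation ``inner_factor * sigma`` (0.5 by default).  Each Gaussian
is normalized to unit mass on the discrete kernel grid, so the kernel sums
to zero exactly.  With the inner Gaussian narrower, the kernel has a
negative center and positive surround and therefore responds to dark lines
and blobs on a bright background, which is how vessels appear in the green
channel.

The rectified response is

    C_sigma = max(0, I * DoG_sigma)

computed with edge-replicated borders; negative convolution values are
clipped to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class DoGSpec:
    """Parameters of one DoG kernel.

    sigma : outer Gaussian standard deviation, in pixels.
    inner_factor : ratio of the inner to the outer standard deviation.
    kernel_radius : half side of the kernel; defaults to ceil(3 * sigma).
    """

    sigma: float
    inner_factor: float = 0.5
    kernel_radius: int | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not 0.0 < self.inner_factor < 1.0:
            raise ValueError(
                f"inner_factor must lie in (0, 1), got {self.inner_factor}"
            )
        if self.kernel_radius is not None and self.kernel_radius < math.ceil(
            3 * self.sigma
        ):
            raise ValueError(
                f"kernel_radius {self.kernel_radius} too small to hold three "
                f"standard deviations of sigma={self.sigma}"
            )

    @property
    def radius(self) -> int:
        return (
            self.kernel_radius
            if self.kernel_radius is not None
            else math.ceil(3 * self.sigma)
        )


def _unit_gaussian(radius: int, sigma: float) -> np.ndarray:
    """Sampled isotropic Gaussian normalized to unit mass on the grid."""
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    xx, yy = np.meshgrid(ax, ax)
    g = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    return g / g.sum()


def make_dog_kernel(spec: DoGSpec) -> np.ndarray:
    """Build the zero-sum DoG kernel for ``spec`` (side = 2*radius + 1)."""
    r = spec.radius
    return _unit_gaussian(r, spec.sigma) - _unit_gaussian(
        r, spec.inner_factor * spec.sigma
    )


def convolve_rectified(image: np.ndarray, spec: DoGSpec) -> np.ndarray:
    """Half-wave-rectified DoG response of ``image``.

    Borders are handled by edge replication; output shape equals input shape.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or image.size == 0:
        raise ValueError(f"expected a non-empty 2-D image, got shape {image.shape}")
    if not np.isfinite(image).all():
        raise ValueError("image contains non-finite values")
    kernel = make_dog_kernel(spec)
    response = ndimage.convolve(image, kernel, mode="nearest")
    return np.maximum(response, 0.0)
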