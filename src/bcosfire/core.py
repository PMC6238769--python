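"""B-COSFIRE filters: configuration, blur-and-shift, and the bank response.

A B-COSFIRE filter is a set *s* of tuples (sigma_i, rho_i, phi_i), each
naming a point at polar position (rho_i, phi_i) around the filter center at
which a DoG response of scale sigma_i is expected.  The filter response at a
pixel is the weighted geometric mean of the blurred DoG responses collected
at those points:

    r_s(x, y) = ( prod_i S_i(x, y)^{w_i} )^{1 / sum_i w_i}

with center-decaying weights w_i = exp(-rho_i^2 / (2 tau^2)),
tau = max_i(rho_i) / 3.  Each S_i is a "weighted max blur" of the rectified
DoG map — the maximum of the map in a Gaussian-weighted neighborhood of
standard deviation sigma' = sigma_0 + alpha * rho_i — shifted by
(-rho_i cos phi_i, -rho_i sin phi_i) so that the evidence at the point is
read off at the filter center.  The geometric mean acts as a soft AND: all
configured points must respond for the filter to fire.

Two prototypes are used: a full bar (symmetric filter, selective for the
vessel interior) and a half bar (asymmetric filter, selective for vessel
endings).  Rotation tolerance comes from a bank of rotated tuple sets —
12 orientations spanning 180 degrees for the symmetric filter (the bar is
symmetric under a half turn) and 360 degrees for the asymmetric one —
combined by pixelwise maximum.

Coordinates follow the package convention: arrays are indexed [row, col] =
[y, x]; an angle phi points toward (cos phi, sin phi) in (x, y).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .dog_bank import DoGSpec, convolve_rectified
from .preprocess import PreprocessParams, suppress_low

TWO_PI = 2.0 * math.pi


class FilterConfigurationError(RuntimeError):
    """Raised when a prototype yields no usable response on some circle."""


@dataclass(frozen=True)
class CosfireTuple:
    """One configured point: DoG scale, radial distance, polar angle."""

    sigma: float
    rho: float
    phi: float

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError(f"rho must be non-negative, got {self.rho}")
        object.__setattr__(self, "phi", float(self.phi) % TWO_PI)


@dataclass(frozen=True)
class BlurParams:
    """Blur growth law sigma' = sigma0 + alpha * rho."""

    sigma0: float = 0.5
    alpha: float = 0.1

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ValueError(f"sigma0 must be positive, got {self.sigma0}")
        if self.alpha < 0:
            raise ValueError(f"alpha must be non-negative, got {self.alpha}")


@dataclass(frozen=True)
class CosfireFilter:
    """A configured bar (symmetric) or half-bar (asymmetric) detector."""

    tuples: tuple[CosfireTuple, ...]
    blur: BlurParams = BlurParams()
    symmetric: bool = True
    t: float = 0.0

    def __post_init__(self) -> None:
        if len(self.tuples) < 1:
            raise ValueError("a COSFIRE filter needs at least one tuple")
        if not 0.0 <= self.t <= 1.0:
            raise ValueError(f"filter threshold t must lie in [0, 1], got {self.t}")
        object.__setattr__(self, "tuples", tuple(self.tuples))

    def rotated(self, psi: float) -> "CosfireFilter":
        """Filter with every tuple's angle advanced by ``psi`` radians."""
        return replace(
            self,
            tuples=tuple(replace(tp, phi=(tp.phi + psi) % TWO_PI) for tp in self.tuples),
        )


@dataclass(frozen=True)
class RotationBank:
    """A rotation-tolerant bank of one base filter.

    The default 12 orientations step by 15 degrees for the symmetric filter
    (covering [0, 180) — the bar repeats under a half turn) and by 30 degrees
    for the asymmetric one (covering [0, 360) so endings in every direction
    are caught).
    """

    base: CosfireFilter
    n_orientations: int = 12
    step: float | None = None

    def __post_init__(self) -> None:
        if self.n_orientations < 1:
            raise ValueError("n_orientations must be positive")

    @property
    def step_radians(self) -> float:
        if self.step is not None:
            return self.step
        span = math.pi if self.base.symmetric else TWO_PI
        return span / self.n_orientations

    def orientations(self) -> np.ndarray:
        return self.step_radians * np.arange(self.n_orientations)


def blur_sigma(blur: BlurParams, rho: float) -> float:
    """Blur standard deviation for a tuple at radius ``rho``."""
    if rho < 0:
        raise ValueError(f"rho must be non-negative, got {rho}")
    return blur.sigma0 + blur.alpha * rho


def shift_vector(rho: float, theta: float) -> tuple[float, float]:
    """Displacement (dx, dy) moving a point's evidence to the filter center."""
    if rho < 0:
        raise ValueError(f"rho must be non-negative, got {rho}")
    return (-rho * math.cos(theta), -rho * math.sin(theta))


# --- blur and shift ----------------------------------------------------------


def _max_pass(arr: np.ndarray, weights: np.ndarray, axis: int) -> np.ndarray:
    """1-D weighted maximum filter along ``axis`` with edge replication."""
    r = len(weights) // 2
    if r == 0:
        return arr * weights[0]
    pad = [(0, 0), (0, 0)]
    pad[axis] = (r, r)
    padded = np.pad(arr, pad, mode="edge")
    out = np.full_like(arr, -np.inf)
    n = arr.shape[axis]
    for k, w in enumerate(weights):
        sl = [slice(None), slice(None)]
        sl[axis] = slice(k, k + n)
        np.maximum(out, w * padded[tuple(sl)], out=out)
    return out


def weighted_max_blur(c_map: np.ndarray, sigma_prime: float) -> np.ndarray:
    """Gaussian-weighted maximum blur.

    D(x, y) = max over offsets (x', y') with |x'|,|y'| <= ceil(3 sigma') of
    c(x - x', y - y') * exp(-(x'^2 + y'^2) / (2 sigma'^2)).

    The weight is unit-peak (not unit-mass) so that the sigma' -> 0 limit is
    the identity.  The Gaussian factorizes, so the 2-D maximum separates into
    two 1-D passes, which is exact for the square neighborhood.
    """
    c_map = np.asarray(c_map, dtype=np.float64)
    r = math.ceil(3 * sigma_prime)
    offsets = np.arange(-r, r + 1, dtype=np.float64)
    weights = np.exp(-(offsets**2) / (2.0 * sigma_prime**2))
    out = _max_pass(c_map, weights, axis=0)
    return _max_pass(out, weights, axis=1)


def shift_map(d_map: np.ndarray, rho: float, phi: float) -> np.ndarray:
    """Translate a blurred map by the shift vector of (rho, phi).

    Sub-pixel displacements are resolved by bilinear interpolation with edge
    replication.
    """
    dx, dy = shift_vector(rho, phi)
    if dx == 0.0 and dy == 0.0:
        return d_map
    return ndimage.shift(d_map, (dy, dx), order=1, mode="nearest")


def blur_and_shift(
    c_map: np.ndarray, tup: CosfireTuple, blur: BlurParams
) -> np.ndarray:
    """Blurred, shifted response map S_{sigma_i, rho_i, phi_i} for one tuple."""
    sp = blur_sigma(blur, tup.rho)
    return shift_map(weighted_max_blur(c_map, sp), tup.rho, tup.phi)


# --- combination -------------------------------------------------------------

_TAU_FLOOR = 1e-6


def tuple_weights(tuples: tuple[CosfireTuple, ...]) -> np.ndarray:
    """Center-decaying geometric-mean weights w_i = exp(-rho_i^2/(2 tau^2))."""
    rhos = np.array([tp.rho for tp in tuples], dtype=np.float64)
    tau = max(rhos.max(initial=0.0) / 3.0, _TAU_FLOOR)
    return np.exp(-(rhos**2) / (2.0 * tau**2))


def compute_response(
    shifted_maps: list[np.ndarray] | tuple[np.ndarray, ...],
    flt: CosfireFilter,
) -> np.ndarray:
    """Weighted geometric mean of the per-tuple maps, then threshold at t.

    A zero in any tuple's map annihilates the response at that pixel (the
    AND-like behavior of the product).  Values below ``t`` times the response
    maximum are suppressed to zero.
    """
    if len(shifted_maps) != len(flt.tuples):
        raise ValueError(
            f"got {len(shifted_maps)} maps for {len(flt.tuples)} tuples"
        )
    shape = shifted_maps[0].shape
    for m in shifted_maps:
        if m.shape != shape:
            raise ValueError("all shifted maps must share one shape")

    weights = tuple_weights(flt.tuples)
    total_w = weights.sum()
    log_sum = np.zeros(shape, dtype=np.float64)
    alive = np.ones(shape, dtype=bool)
    for w, m in zip(weights, shifted_maps):
        m = np.asarray(m, dtype=np.float64)
        positive = m > 0.0
        alive &= positive
        with np.errstate(divide="ignore", invalid="ignore"):
            log_sum += np.where(positive, w * np.log(np.where(positive, m, 1.0)), 0.0)
    response = np.where(alive, np.exp(log_sum / total_w), 0.0)

    if flt.t > 0.0:
        peak = response.max(initial=0.0)
        if peak > 0.0:
            response = np.where(response >= flt.t * peak, response, 0.0)
    return response


# --- automatic configuration -------------------------------------------------


def bar_prototype(
    size: int = 101,
    width: float = 5.0,
    angle: float = math.pi / 2,
    half: bool = False,
    contrast: float = 1.0,
) -> np.ndarray:
    """Draw a dark bar (or half bar) on a bright background through the center.

    ``angle`` is the direction the bar runs toward, in the (x, y) convention;
    the default pi/2 draws a vertical bar.  A half bar occupies only the side
    of the center pointed to by ``angle``, modelling a vessel ending at the
    center.
    """
    if size % 2 == 0:
        size += 1  # keep an exact center pixel
    c = size // 2
    ys, xs = np.mgrid[0:size, 0:size].astype(np.float64)
    relx, rely = xs - c, ys - c
    dirx, diry = math.cos(angle), math.sin(angle)
    along = relx * dirx + rely * diry
    across = -relx * diry + rely * dirx
    # 1-px antialiased edge so rotated rasterizations agree closely
    coverage = np.clip(width / 2.0 + 0.5 - np.abs(across), 0.0, 1.0)
    if half:
        coverage *= np.clip(along + 0.5, 0.0, 1.0)
    return 1.0 - contrast * coverage


def _circle_maxima(values: np.ndarray, angles: np.ndarray) -> list[float]:
    """Angles of circular local maxima above half the circle maximum.

    Plateaus of equal values are merged into one detection at their circular
    centroid.
    """
    peak = values.max()
    thr = 0.5 * peak
    left = np.roll(values, 1)
    right = np.roll(values, -1)
    candidate = (values >= left) & (values >= right) & (values > thr)
    if not candidate.any():
        return []
    # group circularly adjacent candidates
    idx = np.flatnonzero(candidate)
    groups: list[list[int]] = [[int(idx[0])]]
    for i in idx[1:]:
        if i == groups[-1][-1] + 1:
            groups[-1].append(int(i))
        else:
            groups.append([int(i)])
    if len(groups) > 1 and groups[0][0] == 0 and groups[-1][-1] == len(values) - 1:
        groups[0] = groups.pop() + groups[0]
    out = []
    for grp in groups:
        w = values[grp]
        ang = angles[grp]
        # circular weighted centroid of the plateau
        phi = math.atan2(float((w * np.sin(ang)).sum()), float((w * np.cos(ang)).sum()))
        out.append(phi % TWO_PI)
    return sorted(out)


def configure_filter(
    prototype: np.ndarray,
    rho_list: list[float] | tuple[float, ...],
    spec: DoGSpec,
    symmetric: bool = True,
    blur: BlurParams | None = None,
    t: float = 0.0,
    n_samples: int = 360,
) -> CosfireFilter:
    """Configure a filter automatically from a drawn prototype pattern.

    The prototype's rectified DoG response is evaluated on circles of the
    requested radii around the image center; every angle at which the
    response is locally maximal and above half the circle's maximum emits one
    tuple.  A symmetric vertical bar with radii {0, rho1, rho2} yields five
    tuples (the center plus two per circle); a half bar yields one per circle.
    """
    prototype = np.asarray(prototype, dtype=np.float64)
    response = convolve_rectified(prototype, spec)
    cy, cx = prototype.shape[0] // 2, prototype.shape[1] // 2
    angles = TWO_PI * np.arange(n_samples) / n_samples

    tuples: list[CosfireTuple] = []
    for rho in sorted(float(r) for r in rho_list):
        if rho == 0.0:
            if response[cy, cx] <= 0.0:
                raise FilterConfigurationError(
                    "no DoG response at the prototype center (rho=0)"
                )
            tuples.append(CosfireTuple(spec.sigma, 0.0, 0.0))
            continue
        coords = np.vstack(
            [cy + rho * np.sin(angles), cx + rho * np.cos(angles)]
        )
        values = ndimage.map_coordinates(response, coords, order=1, mode="nearest")
        if values.max(initial=0.0) <= 1e-12:
            raise FilterConfigurationError(
                f"no above-threshold DoG response on the circle of radius {rho}"
            )
        for phi in _circle_maxima(values, angles):
            tuples.append(CosfireTuple(spec.sigma, rho, phi))

    tuples.sort(key=lambda tp: (tp.rho, tp.phi))
    return CosfireFilter(
        tuples=tuple(tuples),
        blur=blur if blur is not None else BlurParams(),
        symmetric=symmetric,
        t=t,
    )


# --- bank application --------------------------------------------------------


def _prep_threshold(prep: PreprocessParams | float | None) -> float:
    if prep is None:
        return 0.0
    if isinstance(prep, PreprocessParams):
        return prep.preprocessing_threshold
    return float(prep)


def apply_bank(
    image: np.ndarray,
    bank: RotationBank,
    prep: PreprocessParams | float | None = None,
) -> np.ndarray:
    """Rotation-tolerant response: pixelwise maximum over the bank.

    DoG maps are computed once per distinct sigma and suppressed with the
    preprocessing threshold; blurred maps are cached per (sigma, rho) —
    rotation only changes the shift — and the filter threshold ``t`` is
    applied once, relative to the global maximum over orientations.
    """
    flt = bank.base
    p = _prep_threshold(prep)

    c_maps: dict[float, np.ndarray] = {}
    for tp in flt.tuples:
        if tp.sigma not in c_maps:
            c_maps[tp.sigma] = suppress_low(
                convolve_rectified(image, DoGSpec(tp.sigma)), p
            )

    blurred: dict[tuple[float, float], np.ndarray] = {}
    for tp in flt.tuples:
        key = (tp.sigma, tp.rho)
        if key not in blurred:
            blurred[key] = weighted_max_blur(
                c_maps[tp.sigma], blur_sigma(flt.blur, tp.rho)
            )

    base_t0 = replace(flt, t=0.0)
    out = np.zeros(image.shape, dtype=np.float64)
    shifted_cache: dict[tuple[float, float, float], np.ndarray] = {}
    for psi in bank.orientations():
        maps = []
        for tp in flt.tuples:
            phi = (tp.phi + psi) % TWO_PI
            key = (tp.sigma, tp.rho, round(phi, 9))
            if key not in shifted_cache:
                shifted_cache[key] = shift_map(blurred[(tp.sigma, tp.rho)], tp.rho, phi)
            maps.append(shifted_cache[key])
        np.maximum(out, compute_response(maps, base_t0), out=out)

    if flt.t > 0.0:
        peak = out.max(initial=0.0)
        if peak > 0.0:
            out = np.where(out >= flt.t * peak, out, 0.0)
    return out


def segment_response(
    image: np.ndarray,
    symmetric_bank: RotationBank,
    asymmetric_bank: RotationBank | None = None,
    prep: PreprocessParams | float | None = None,
    asym_weight: float = 1.0,
) -> np.ndarray:
    """Combined vessel-likelihood map.

    The symmetric-bank response (vessel interior) and the asymmetric-bank
    response (vessel endings) are each rescaled to [0, 1] and summed; the
    asymmetric term can be weighted or disabled.
    """
    def _rescaled(r: np.ndarray) -> np.ndarray:
        peak = r.max(initial=0.0)
        return r / peak if peak > 0 else r

    out = _rescaled(apply_bank(image, symmetric_bank, prep))
    if asymmetric_bank is not None and asym_weight != 0.0:
        out = out + asym_weight * _rescaled(apply_bank(image, asymmetric_bank, prep))
    return out
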