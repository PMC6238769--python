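import math

import numpy as np
import pytest

import bcosfire as bc
from bcosfire.phantom import _fov_disc


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def fitted_segmenter():
    """One fitted default segmenter shared across tests (configuration is
    deterministic, so sharing is safe)."""
    return bc.VesselSegmenter().fit()


@pytest.fixture(scope="session")
def straight_vessel_scene():
    """Noise-free single vertical vessel of width 2*sigma on a FOV disc."""
    h = w = 256
    fov = _fov_disc(h, w)
    _, xs = np.mgrid[0:h, 0:w].astype(np.float64)
    sigma_v = 4.8 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    d = np.abs(xs - (w - 1) / 2.0)
    image = np.where(fov > 0, 0.78 - 0.5 * np.exp(-(d**2) / (2 * sigma_v**2)), 0.03)
    gt = ((d <= sigma_v * math.sqrt(2 * math.log(2))) & (fov > 0)).astype(np.uint8)
    return image, gt, fov


@pytest.fixture(scope="session")
def small_suite():
    """Four reduced-size phantoms for fast end-to-end tests."""
    spec = bc.PhantomSpec(height=160, width=160, n_vessels=3, n_artifacts=4)
    return bc.make_suite(4, spec, seed=11)
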