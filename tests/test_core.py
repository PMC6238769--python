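import math

import numpy as np
import pytest
from scipy import ndimage

import bcosfire as bc
from bcosfire.core import (
    BlurParams,
    CosfireFilter,
    CosfireTuple,
    FilterConfigurationError,
    RotationBank,
    shift_map,
    tuple_weights,
)
from bcosfire.dog_bank import DoGSpec

from _oracles import brute_force_blur_shift, brute_force_geometric_mean


class TestBlurSigma:
    def test_rho_zero_gives_sigma0(self):
        assert bc.blur_sigma(BlurParams(sigma0=2.0, alpha=0.1), 0.0) == 2.0

    def test_linear_growth(self):
        assert bc.blur_sigma(BlurParams(sigma0=2.0, alpha=0.1), 10.0) == pytest.approx(3.0)

    def test_strictly_increasing_when_alpha_positive(self):
        blur = BlurParams(sigma0=1.0, alpha=0.3)
        values = [bc.blur_sigma(blur, r) for r in (0, 1, 2, 5, 10)]
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_negative_rho_raises(self):
        with pytest.raises(ValueError):
            bc.blur_sigma(BlurParams(), -1.0)


class TestShiftVector:
    @pytest.mark.parametrize(
        "rho, theta, expected",
        [
            (2.0, 0.0, (-2.0, 0.0)),
            (0.0, 1.234, (0.0, 0.0)),
            (2.0, math.pi / 2, (0.0, -2.0)),
        ],
    )
    def test_examples(self, rho, theta, expected):
        dx, dy = bc.shift_vector(rho, theta)
        assert dx == pytest.approx(expected[0], abs=1e-12)
        assert dy == pytest.approx(expected[1], abs=1e-12)


class TestBlurAndShift:
    def test_identity_limit(self, rng):
        c = rng.random((9, 9))
        tup = CosfireTuple(2.4, 0.0, 0.0)
        out = bc.blur_and_shift(c, tup, BlurParams(sigma0=1e-3, alpha=0.0))
        assert np.allclose(out, c, atol=1e-9)

    def test_peak_moves_toward_filter_center(self):
        # a tuple at phi=0 sits at +x of the center, so its evidence moves
        # to -x (displacement (-3, 0)) to be read off at the center
        c = np.zeros((15, 15))
        c[7, 7] = 1.0
        out = bc.blur_and_shift(c, CosfireTuple(2.4, 3.0, 0.0), BlurParams(0.4, 0.0))
        assert np.unravel_index(np.argmax(out), out.shape) == (7, 4)

    @pytest.mark.parametrize("rho, phi", [(2.0, 0.0), (2.0, math.pi / 2), (3.0, math.pi)])
    def test_matches_brute_force_oracle(self, rng, rho, phi):
        c = rng.random((9, 9))
        blur = BlurParams(sigma0=0.7, alpha=0.1)
        sp = bc.blur_sigma(blur, rho)
        oracle = brute_force_blur_shift(c, rho, phi, sp)
        out = bc.blur_and_shift(c, CosfireTuple(1.0, rho, phi), blur)
        valid = ~np.isnan(oracle)
        assert valid.any()
        assert np.abs(out[valid] - oracle[valid]).max() < 1e-10

    def test_subpixel_shift_interpolates(self):
        c = np.zeros((11, 11))
        c[5, 5] = 1.0
        out = shift_map(c, 1.5, 0.0)
        # mass splits between columns 3 and 4 of row 5
        assert out[5, 3] == pytest.approx(0.5) and out[5, 4] == pytest.approx(0.5)


class TestComputeResponse:
    def _filter(self, rhos, t=0.0):
        tuples = tuple(CosfireTuple(1.0, r, 0.0) for r in rhos)
        return CosfireFilter(tuples=tuples, t=t)

    def test_constant_maps_give_constant(self):
        flt = self._filter([0.0, 2.0, 4.0])
        maps = [np.full((4, 4), 0.7)] * 3
        assert np.allclose(bc.compute_response(maps, flt), 0.7)

    def test_zero_annihilates(self, rng):
        flt = self._filter([0.0, 2.0])
        m1 = rng.random((4, 4)) + 0.1
        m2 = m1.copy()
        m2[1, 2] = 0.0
        out = bc.compute_response([m1, m2], flt)
        assert out[1, 2] == 0.0 and (out > 0).sum() == 15

    def test_matches_brute_force_oracle(self, rng):
        rhos = [0.0, 2.0, 4.0]
        flt = self._filter(rhos)
        maps = [rng.random((5, 5)) + 0.05 for _ in rhos]
        oracle = brute_force_geometric_mean(maps, rhos)
        assert np.abs(bc.compute_response(maps, flt) - oracle).max() < 1e-12

    def test_bounded_by_min_and_max_of_inputs(self, rng):
        flt = self._filter([0.0, 3.0, 6.0])
        maps = [rng.random((6, 6)) + 0.01 for _ in range(3)]
        out = bc.compute_response(maps, flt)
        lo = np.minimum.reduce(maps)
        hi = np.maximum.reduce(maps)
        assert (out >= lo - 1e-12).all() and (out <= hi + 1e-12).all()

    def test_threshold_suppresses_relative_to_max(self):
        flt = self._filter([0.0], t=0.5)
        out = bc.compute_response([np.array([[0.2, 0.6, 1.0]])], flt)
        assert out.tolist() == [[0.0, 0.6, 1.0]]

    def test_weights_decay_with_radius(self):
        tuples = tuple(CosfireTuple(1.0, r, 0.0) for r in (0.0, 2.0, 4.0, 8.0))
        w = tuple_weights(tuples)
        assert w[0] == pytest.approx(1.0)
        assert all(b < a for a, b in zip(w, w[1:]))

    def test_shape_mismatch_raises(self):
        flt = self._filter([0.0, 2.0])
        with pytest.raises(ValueError):
            bc.compute_response([np.zeros((3, 3)), np.zeros((4, 4))], flt)

    def test_invalid_threshold_raises(self):
        with pytest.raises(ValueError):
            self._filter([0.0], t=1.5)


class TestConfigureFilter:
    def test_vertical_bar_yields_five_tuples_at_forced_angles(self):
        bar = bc.bar_prototype(size=41, width=5.0)
        flt = bc.configure_filter(bar, [0, 2, 4], DoGSpec(2.4))
        got = sorted((t.rho, round(t.phi, 9)) for t in flt.tuples)
        expected = [
            (0.0, 0.0),
            (2.0, round(math.pi / 2, 9)),
            (2.0, round(3 * math.pi / 2, 9)),
            (4.0, round(math.pi / 2, 9)),
            (4.0, round(3 * math.pi / 2, 9)),
        ]
        assert len(got) == 5
        for (r1, p1), (r2, p2) in zip(got, expected):
            assert r1 == r2 and abs(p1 - p2) < 1e-6

    def test_half_bar_yields_three_tuples_one_side(self):
        half = bc.bar_prototype(size=41, width=5.0, half=True)
        flt = bc.configure_filter(half, [0, 2, 4], DoGSpec(2.4), symmetric=False)
        assert len(flt.tuples) == 3
        for t in flt.tuples[1:]:
            assert abs(t.phi - math.pi / 2) < 1e-6

    def test_rho_zero_alone(self):
        bar = bc.bar_prototype(size=41, width=5.0)
        flt = bc.configure_filter(bar, [0], DoGSpec(2.4))
        assert len(flt.tuples) == 1 and flt.tuples[0].rho == 0.0

    def test_blank_prototype_raises_naming_radius(self):
        with pytest.raises(FilterConfigurationError):
            bc.configure_filter(np.ones((41, 41)), [0, 4], DoGSpec(2.4))


class TestApplyBank:
    def test_bank_max_dominates_single_orientation(self, fitted_segmenter):
        bar = bc.bar_prototype(size=61, width=4.8, contrast=0.5)
        base = fitted_segmenter.symmetric_filter_
        full = bc.apply_bank(bar, RotationBank(base, n_orientations=12), 0.3)
        single = bc.apply_bank(bar, RotationBank(base, n_orientations=1), 0.3)
        assert (full >= single - 1e-12).all()

    def test_twelve_orientations_cover_half_turn(self, fitted_segmenter):
        bank = fitted_segmenter.symmetric_bank_
        ori = bank.orientations()
        assert len(ori) == 12
        assert ori[1] - ori[0] == pytest.approx(math.radians(15))

    def test_asymmetric_bank_covers_full_turn(self, fitted_segmenter):
        bank = fitted_segmenter.asymmetric_bank_
        assert bank.orientations()[-1] == pytest.approx(math.radians(330))

    def test_rotation_tolerance_zero_vs_thirty_degrees(self, fitted_segmenter):
        maxima = []
        for ang in (0.0, 30.0):
            bar = bc.bar_prototype(
                size=101, width=4.8, angle=math.radians(90 - ang), contrast=0.5
            )
            maxima.append(bc.apply_bank(bar, fitted_segmenter.symmetric_bank_, 0.3).max())
        assert abs(maxima[0] - maxima[1]) / maxima[0] < 0.05

    def test_contrast_doubling_doubles_response(self, fitted_segmenter):
        bar = bc.bar_prototype(size=61, width=4.8, contrast=0.3)
        r1 = bc.apply_bank(bar, fitted_segmenter.symmetric_bank_, 0.2)
        r2 = bc.apply_bank(2.0 * bar, fitted_segmenter.symmetric_bank_, 0.2)
        assert np.allclose(r2, 2.0 * r1, atol=1e-9)

    def test_equivariance_under_bank_rotation(self, fitted_segmenter):
        bar = bc.bar_prototype(size=101, width=4.8, contrast=0.5)
        bank = fitted_segmenter.symmetric_bank_
        r0 = bc.apply_bank(bar, bank, 0.3)
        rotated = ndimage.rotate(bar, 30.0, reshape=False, order=1, mode="nearest", cval=1.0)
        r30 = bc.apply_bank(rotated, bank, 0.3)
        back = ndimage.rotate(r30, -30.0, reshape=False, order=1)
        ys, xs = np.mgrid[0:101, 0:101]
        interior = (ys - 50) ** 2 + (xs - 50) ** 2 <= 30**2
        corr = np.corrcoef(r0[interior], back[interior])[0, 1]
        assert corr > 0.95


class TestSegmentResponse:
    def test_zero_asym_weight_gives_symmetric_alone(self, fitted_segmenter):
        bar = bc.bar_prototype(size=61, width=4.8, contrast=0.5)
        combined = bc.segment_response(
            bar, fitted_segmenter.symmetric_bank_, fitted_segmenter.asymmetric_bank_,
            prep=0.3, asym_weight=0.0,
        )
        sym = bc.apply_bank(bar, fitted_segmenter.symmetric_bank_, 0.3)
        assert np.allclose(combined, sym / sym.max())

    def test_endpoint_favors_asymmetric_filter(self, fitted_segmenter):
        # a bar ending mid-image: at the ending the half-bar detector must
        # outscore the full-bar detector (both on their own [0,1] scales)
        scene = bc.bar_prototype(size=81, width=4.8, half=True, contrast=0.5)
        sym = bc.apply_bank(scene, fitted_segmenter.symmetric_bank_, 0.3)
        asym = bc.apply_bank(scene, fitted_segmenter.asymmetric_bank_, 0.3)
        sym_n, asym_n = sym / sym.max(), asym / asym.max()
        end = (40, 40)  # the bar terminates at the image center
        assert asym_n[end] > sym_n[end]
        interior = (60, 40)  # deep inside the half bar
        assert sym_n[interior] >= asym_n[interior] - 0.05
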