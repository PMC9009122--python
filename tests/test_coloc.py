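"""Colocalization coefficients, LMP scoring and tandem-reporter classification."""

import numpy as np
import pytest

from lysoquant import (
    BinaryMask,
    CellROI,
    ValidationError,
    binary_and,
    classify_tandem,
    lmp_score,
    lmp_score_intensity,
    manders,
    pearson_r,
    verify_compartment,
)
from oracles import pearson_two_pass


def _mask(arr):
    return BinaryMask(np.asarray(arr, dtype=bool))


def _full(shape=(8, 8)):
    return BinaryMask(np.ones(shape, dtype=bool))


class TestBinaryAnd:
    def test_idempotent(self, rng):
        a = _mask(rng.random((8, 8)) > 0.5)
        np.testing.assert_array_equal(binary_and(a, a).pixels, a.pixels)

    def test_and_with_empty_is_empty(self, rng):
        a = _mask(rng.random((8, 8)) > 0.5)
        empty = _mask(np.zeros((8, 8)))
        assert binary_and(a, empty).area_px == 0

    def test_offset_squares_overlap_enumeration(self):
        a = np.zeros((10, 10), dtype=bool)
        b = np.zeros((10, 10), dtype=bool)
        a[2:6, 2:6] = True  # 4x4
        b[4:8, 2:6] = True  # shifted down 2 -> overlap rows 4..5, cols 2..5
        assert binary_and(_mask(a), _mask(b)).area_px == 8

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            binary_and(_mask(np.zeros((4, 4))), _mask(np.zeros((5, 5))))


class TestPearson:
    def test_identical_planes_give_one(self, rng):
        a = rng.random((8, 8))
        assert pearson_r(a, a, _full()) == pytest.approx(1.0)

    def test_inverted_plane_gives_minus_one(self, rng):
        a = rng.random((8, 8))
        assert pearson_r(a, 10.0 - a, _full()) == pytest.approx(-1.0)

    def test_hand_computed_four_pixel_example(self):
        a = np.array([[1.0, 2.0], [3.0, 4.0]])
        b = np.array([[2.0, 1.0], [4.0, 3.0]])
        assert pearson_r(a, b, _full((2, 2))) == pytest.approx(0.6)

    def test_agrees_with_two_pass_covariance_oracle(self, rng):
        roi = _mask(rng.random((32, 32)) > 0.3)
        for _ in range(20):
            a = rng.random((32, 32))
            b = rng.random((32, 32)) + 0.3 * a
            got = pearson_r(a, b, roi)
            want = pearson_two_pass(a[roi.pixels], b[roi.pixels])
            assert got == pytest.approx(want, abs=1e-12)

    def test_constant_plane_warns_and_returns_nan(self):
        with pytest.warns(UserWarning, match="constant"):
            out = pearson_r(np.ones((4, 4)), np.arange(16.0).reshape(4, 4), _full((4, 4)))
        assert np.isnan(out)

    def test_tiny_roi_rejected(self):
        roi = _mask(np.zeros((4, 4)))
        roi.pixels[0, 0] = True
        with pytest.raises(ValidationError):
            pearson_r(np.ones((4, 4)), np.ones((4, 4)), roi)


class TestManders:
    def test_nested_masks_give_m1_one(self, rng):
        plane = rng.random((8, 8)) + 0.1
        inner = np.zeros((8, 8), dtype=bool)
        inner[2:5, 2:5] = True
        outer = np.zeros((8, 8), dtype=bool)
        outer[1:7, 1:7] = True
        m1, _ = manders(plane, plane, _mask(inner), _mask(outer))
        assert m1 == pytest.approx(1.0)

    def test_disjoint_masks_give_zero(self, rng):
        plane = rng.random((8, 8)) + 0.1
        left = np.zeros((8, 8), dtype=bool)
        left[:, :4] = True
        right = ~left
        m1, m2 = manders(plane, plane, _mask(left), _mask(right))
        assert m1 == 0.0 and m2 == 0.0

    def test_uniform_plane_half_overlap_gives_half(self):
        plane = np.ones((8, 8))
        a = np.zeros((8, 8), dtype=bool)
        a[0:4, :] = True  # 32 px
        b = np.zeros((8, 8), dtype=bool)
        b[2:6, :] = True  # covers half of a
        m1, _ = manders(plane, plane, _mask(a), _mask(b))
        assert m1 == pytest.approx(0.5)

    def test_swapping_arguments_swaps_coefficients(self, rng):
        pa, pb = rng.random((8, 8)), rng.random((8, 8))
        ma = _mask(rng.random((8, 8)) > 0.4)
        mb = _mask(rng.random((8, 8)) > 0.4)
        m1, m2 = manders(pa, pb, ma, mb)
        m1s, m2s = manders(pb, pa, mb, ma)
        assert m1 == pytest.approx(m2s) and m2 == pytest.approx(m1s)

    def test_coefficients_bounded(self, rng):
        for _ in range(10):
            pa, pb = rng.random((8, 8)), rng.random((8, 8))
            ma = _mask(rng.random((8, 8)) > 0.3)
            mb = _mask(rng.random((8, 8)) > 0.3)
            m1, m2 = manders(pa, pb, ma, mb)
            assert 0.0 <= m1 <= 1.0 and 0.0 <= m2 <= 1.0

    def test_empty_mask_warns_and_gives_nan(self):
        plane = np.ones((4, 4))
        with pytest.warns(UserWarning):
            m1, _ = manders(plane, plane, _mask(np.zeros((4, 4))), _full((4, 4)))
        assert np.isnan(m1)


class TestLmpScore:
    def test_enzyme_inside_lysosomes_scores_zero(self):
        catd = np.zeros((8, 8), dtype=bool)
        catd[2:4, 2:4] = True
        lamp2 = np.zeros((8, 8), dtype=bool)
        lamp2[1:5, 1:5] = True
        res = lmp_score(_mask(catd), _mask(lamp2))
        assert res.cytosolic_fraction == 0.0

    def test_disjoint_masks_score_one(self):
        catd = np.zeros((8, 8), dtype=bool)
        catd[:2] = True
        lamp2 = np.zeros((8, 8), dtype=bool)
        lamp2[6:] = True
        assert lmp_score(_mask(catd), _mask(lamp2)).cytosolic_fraction == 1.0

    def test_seventy_of_hundred_overlap_scores_point_three(self):
        catd = np.zeros((20, 20), dtype=bool)
        catd[0:10, 0:10] = True  # 100 px
        lamp2 = np.zeros((20, 20), dtype=bool)
        lamp2[0:7, 0:10] = True  # overlaps 70 px
        res = lmp_score(_mask(catd), _mask(lamp2))
        assert res.total_catd_area_px == 100
        assert res.lysosomal_catd_area_px == 70
        assert res.cytosolic_fraction == pytest.approx(0.30)

    def test_no_enzyme_signal_is_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            out = lmp_score(_mask(np.zeros((8, 8))), _full())
        assert out is None

    def test_intensity_variant_low_for_pure_punctate_signal(self):
        # bright spot fully inside the lysosome mask, no diffuse signal
        yy, xx = np.mgrid[0:64, 0:64]
        plane = 100 * np.exp(-((yy - 32) ** 2 + (xx - 32) ** 2) / (2 * 2.0**2))
        lamp2 = _mask(plane > 10)
        cell = np.hypot(yy - 32, xx - 32) < 28
        nuc = np.hypot(yy - 12, xx - 32) < 1.5
        roi = CellROI("c", BinaryMask(cell & ~nuc), BinaryMask(nuc))
        res = lmp_score_intensity(plane, lamp2, roi)
        assert res.cytosolic_fraction < 0.05


class TestClassifyTandem:
    def test_empty_gfp_makes_everything_red(self):
        mch = np.zeros((32, 32), dtype=bool)
        mch[4:9, 4:9] = True
        mch[20:25, 20:25] = True
        res = classify_tandem(_mask(np.zeros((32, 32))), _mask(mch), min_area_px=10)
        assert res.yellow_count == 0
        assert res.red_count == 2
        assert res.yellow_area_px == 0 and res.red_area_px == 50

    def test_identical_masks_leave_no_red_area(self, rng):
        m = rng.random((32, 32)) > 0.6
        res = classify_tandem(_mask(m), _mask(m), min_area_px=1)
        assert res.red_area_px == 0
        assert res.yellow_area_px == int(m.sum())

    def test_partition_is_exact_on_random_masks(self, rng):
        for _ in range(20):
            gfp = _mask(rng.random((32, 32)) > 0.5)
            mch = _mask(rng.random((32, 32)) > 0.5)
            res = classify_tandem(gfp, mch, min_area_px=7)
            assert res.yellow_area_px + res.red_area_px == mch.area_px


class TestVerifyCompartment:
    def test_empty_organelle_gives_zero_overlap(self):
        nonlyso = _mask(np.ones((8, 8)))
        report = verify_compartment(nonlyso, {"er": _mask(np.zeros((8, 8)))})
        assert report["er"] == 0.0

    def test_nested_mask_gives_full_overlap(self):
        nl = np.zeros((8, 8), dtype=bool)
        nl[2:4, 2:4] = True
        report = verify_compartment(_mask(nl), {"golgi": _full()})
        assert report["golgi"] == 1.0

    def test_uniform_diffuse_overlap_matches_area_fraction(self, rng):
        # uniformly scattered non-lysosomal pixels across the cytosol overlap
        # a disjoint organelle mask in proportion to the organelle area
        cytosol = np.ones((100, 100), dtype=bool)
        nonlyso = rng.random((100, 100)) < 0.3
        organelle = np.zeros((100, 100), dtype=bool)
        organelle[:, :25] = True  # 25% of the cytosol
        report = verify_compartment(_mask(nonlyso & cytosol), {"er": _mask(organelle)})
        assert report["er"] == pytest.approx(0.25, abs=0.03)
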