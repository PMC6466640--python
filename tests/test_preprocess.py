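"""Denoising, HU transfer function, search region, air triage, prostate."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from rectseg.config import RunConfig
from rectseg.geometry import mvct_geometry
from rectseg.preprocess import (air_contour, build_search_region, denoise_slice,
                                detect_air, detect_spine_limit, mask_prostate,
                                rescale_hu)

from conftest import disk_mask


class TestDenoise:
    def test_constant_unchanged(self):
        img = np.full((32, 32), 17.0)
        np.testing.assert_array_equal(denoise_slice(img), img)

    def test_impulse_removed(self):
        img = np.zeros((32, 32))
        img[10, 10] = 1000.0
        assert denoise_slice(img, width=5).max() == 0.0

    def test_width_one_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(16, 16))
        np.testing.assert_array_equal(denoise_slice(img, width=1), img)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError):
            denoise_slice(np.zeros((8, 8)), width=4)


class TestRescaleHU:
    """The piecewise-linear transfer function: gas -> 1, critical range
    ramps, plateau 1 on 30..60 HU, 0 elsewhere."""

    @pytest.mark.parametrize("hu,expected", [
        (-200.0, 1.0),   # rectal gas
        (-131.0, 1.0),
        (-130.0, 0.0),   # gap below critical range
        (-50.0, 0.0),
        (-10.0, 0.0),    # ramp start
        (10.0, 0.5),     # midpoint of rising ramp
        (30.0, 1.0),     # plateau
        (45.0, 1.0),
        (60.0, 1.0),
        (80.0, 0.5),     # midpoint of falling ramp
        (100.0, 0.0),
        (150.0, 0.0),
    ])
    def test_breakpoints_and_midpoints(self, hu, expected):
        assert rescale_hu(hu) == pytest.approx(expected, abs=1e-12)

    def test_dense_sweep_bounded_continuous_monotone(self):
        hu = np.linspace(-10.0, 100.0, 11001)
        out = rescale_hu(hu)
        assert out.min() >= 0.0 and out.max() <= 1.0
        # continuity on the critical range: small HU step, small jump
        assert np.abs(np.diff(out)).max() < 1e-3
        rising = out[(hu >= -10) & (hu <= 30)]
        falling = out[(hu >= 60) & (hu <= 100)]
        assert (np.diff(rising) >= -1e-12).all()
        assert (np.diff(falling) <= 1e-12).all()

    @settings(deadline=None)
    @given(st.floats(-1100, 3100, allow_nan=False))
    def test_always_in_unit_interval(self, hu):
        assert 0.0 <= rescale_hu(hu) <= 1.0

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            rescale_hu(float("nan"))


class TestSpineLimit:
    def test_posterior_bone_block_found(self):
        img = np.zeros((200, 200))
        img[150:170, 90:110] = 800.0   # 400 px in the posterior half
        assert detect_spine_limit(img) == 150

    def test_no_bone_returns_none(self):
        assert detect_spine_limit(np.full((64, 64), 40.0)) is None

    def test_anterior_bone_ignored(self):
        img = np.zeros((200, 200))
        img[20:40, 90:110] = 800.0     # anterior half only
        assert detect_spine_limit(img) is None

    def test_tiny_bone_speck_ignored(self):
        img = np.zeros((200, 200))
        img[150:155, 100:105] = 800.0  # 25 px < minimum component size
        assert detect_spine_limit(img) is None


class TestSearchRegion:
    def test_stated_expansions(self, mv_geom):
        mask = np.zeros((512, 512), bool)
        mask[251:261, 251:261] = True  # 10 x 10 prior
        roi = build_search_region(mask, None, mv_geom)
        rows = np.nonzero(roi.mask.any(axis=1))[0]
        cols = np.nonzero(roi.mask.any(axis=0))[0]
        assert rows.max() - rows.min() + 1 == 10 + 50 + 20
        assert cols.max() - cols.min() + 1 == 10 + 40 + 40

    def test_contains_prior_and_clips_at_spine(self, mv_geom):
        mask = np.zeros((512, 512), bool)
        mask[251:261, 251:261] = True
        roi = build_search_region(mask, 261, mv_geom)
        assert (roi.mask & mask).sum() == mask.sum()
        assert not roi.mask[261:, :].any()      # posterior expansion gone

    def test_clipped_at_image_edge(self, mv_geom):
        mask = np.zeros((512, 512), bool)
        mask[0:10, 0:10] = True
        roi = build_search_region(mask, None, mv_geom)
        assert roi.mask.any()

    def test_empty_prior_rejected(self, mv_geom):
        with pytest.raises(ValueError):
            build_search_region(np.zeros((512, 512), bool), None, mv_geom)


class TestDetectAir:
    def _planning(self):
        return disk_mask((256, 256), (128, 128), 40)

    def test_no_air(self):
        air = detect_air(np.full((256, 256), 40.0), self._planning())
        assert air.tier == "none" and not air.mask.any()

    def test_medium_blob_inside_prior_is_valid(self):
        img = np.full((256, 256), 40.0)
        blob = disk_mask((256, 256), (128, 128), 9.8)   # ~300 px
        img[blob] = -500.0
        air = detect_air(img, self._planning())
        assert air.tier == "medium" and air.valid
        assert 150 <= air.area_px <= 600

    def test_blob_outside_prior_is_invalid(self):
        img = np.full((256, 256), 40.0)
        img[disk_mask((256, 256), (30, 30), 9.8)] = -500.0
        air = detect_air(img, self._planning())
        assert air.tier == "medium" and not air.valid

    def test_large_tier(self):
        img = np.full((256, 256), 40.0)
        img[disk_mask((256, 256), (128, 128), 16)] = -500.0   # ~800 px
        air = detect_air(img, self._planning())
        assert air.tier == "large" and air.valid and air.area_px > 600

    def test_tier_boundaries_by_construction(self):
        img = np.full((256, 256), 40.0)
        img[120:130, 118:132] = -500.0   # exactly 140 px -> small
        air = detect_air(img, self._planning())
        assert air.area_px == 140 and air.tier == "small"

    def test_roi_restriction(self):
        img = np.full((256, 256), 40.0)
        img[0:50, 0:50] = -900.0          # huge exterior air
        img[disk_mask((256, 256), (128, 128), 9.8)] = -500.0
        roi = disk_mask((256, 256), (128, 128), 60)
        air = detect_air(img, self._planning(), roi=roi)
        assert air.valid and air.tier == "medium"


class TestAirContour:
    def test_medium_hole_filled_and_dilated(self, mv_geom):
        comp = disk_mask((256, 256), (128, 128), 9.8)
        hole = disk_mask((256, 256), (128, 128), 2.5)
        region = detect_air(np.where(comp & ~hole, -500.0, 40.0),
                            disk_mask((256, 256), (128, 128), 40))
        out = air_contour(region, mv_geom)
        assert out.sum() > comp.sum()
        assert not (ndimage.binary_fill_holes(out) ^ out).any()

    def test_large_margin_at_least_8px(self, mv_geom):
        comp = disk_mask((256, 256), (128, 128), 16)
        region = detect_air(np.where(comp, -500.0, 40.0),
                            disk_mask((256, 256), (128, 128), 40))
        out = air_contour(region, mv_geom)
        assert (out & comp).sum() == comp.sum()
        dist = ndimage.distance_transform_edt(out)
        assert dist[comp].min() >= 8.0 - 1e-9  # chessboard-8 dilation covers it

    def test_disk_grows_to_radius_plus_margin(self, mv_geom):
        r = 14
        comp = disk_mask((256, 256), (128, 128), r)
        region = detect_air(np.where(comp, -500.0, 40.0),
                            disk_mask((256, 256), (128, 128), 40))
        out = air_contour(region, mv_geom)
        # 3x3 dilation is chessboard distance: grows to between r+8 and
        # r+8*sqrt(2); assert the lower analytic bound within 5%
        assert out.sum() >= 0.95 * np.pi * (r + 8) ** 2

    def test_small_tier_rejected(self, mv_geom):
        img = np.full((256, 256), 40.0)
        img[120:125, 120:125] = -500.0
        region = detect_air(img, disk_mask((256, 256), (122, 122), 30))
        with pytest.raises(ValueError):
            air_contour(region, mv_geom)


class TestMaskProstate:
    def test_empty_mask_no_change(self):
        img = np.random.default_rng(0).uniform(size=(32, 32))
        out = mask_prostate(img, np.zeros((32, 32), bool))
        np.testing.assert_array_equal(out, img)

    def test_sum_drops_by_mask_size_and_idempotent(self):
        img = np.ones((32, 32))
        pro = np.zeros((32, 32), bool)
        pro[5:15, 5:15] = True
        out = mask_prostate(img, pro)
        assert out.sum() == img.sum() - 100
        np.testing.assert_array_equal(mask_prostate(out, pro), out)
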