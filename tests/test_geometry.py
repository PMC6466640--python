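"""Grid geometry, unit conversions, transforms and structure regridding."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rectseg.geometry import (Geometry, RigidTransform, Volume, grid_metrics,
                              kvct_geometry, mvct_geometry, volume_from_nifti,
                              volume_to_nifti)
from rectseg.metrics import dice
from rectseg.resample import resample_structure
from rectseg.structures import StructureSet

from conftest import disk_mask


class TestGridMetrics:
    """The printed pixel <-> mm conversions on the MVCT grid."""

    @pytest.mark.parametrize("count,mode,expected,sig", [
        (2500, "area", 1420.0, 3),      # implausible-contour cut-off
        (50, "distance", 37.7, 3),      # anterior search expansion (38 mm)
        (20, "distance", 15.08, 2),     # posterior expansion (15 mm)
        (150, "area", 85.0, 2),         # small/medium air tier bound
        (600, "area", 341.0, 2),        # medium/large air tier bound (340 mm^2)
        (8, "distance", 6.0, 1),        # rectal-wall margin around gas
        (40, "distance", 30.2, 2),      # lateral expansion (30 mm)
        (2950, "area", 1680.0, 3),      # over-contoured example area
    ])
    def test_printed_constants(self, mv_geom, count, mode, expected, sig):
        value = grid_metrics(count, mv_geom, mode)
        assert value == pytest.approx(expected, rel=10 ** -sig * 5)

    def test_zero_and_negative(self, mv_geom):
        assert grid_metrics(0, mv_geom, "area") == 0.0
        with pytest.raises(ValueError):
            grid_metrics(-1, mv_geom, "area")

    @settings(deadline=None)
    @given(a=st.integers(0, 10000), b=st.integers(0, 10000))
    def test_area_is_linear(self, a, b):
        g = mvct_geometry(1)
        assert grid_metrics(a + b, g, "area") == pytest.approx(
            grid_metrics(a, g, "area") + grid_metrics(b, g, "area"))


class TestVolume:
    def test_shape_mismatch_rejected(self, mv_geom):
        with pytest.raises(ValueError, match="shape"):
            Volume(np.zeros((2, 3, 3)), mv_geom, "MVCT")

    def test_insane_hu_rejected(self):
        g = mvct_geometry(2, 4, 4)
        data = np.zeros(g.shape)
        data[0, 0, 0] = 5000
        with pytest.raises(ValueError, match="sane"):
            Volume(data, g, "MVCT")

    def test_nifti_round_trip(self, tmp_path):
        g = mvct_geometry(3, 8, 8)
        vol = Volume(np.arange(3 * 64).reshape(g.shape).astype(float), g, "MVCT")
        volume_to_nifti(vol, tmp_path / "v.nii.gz")
        back = volume_from_nifti(tmp_path / "v.nii.gz")
        np.testing.assert_allclose(back.data, vol.data, atol=1e-4)
        assert back.geometry.pixel_size == pytest.approx(g.pixel_size)
        assert back.geometry.slice_thickness == pytest.approx(g.slice_thickness)
        assert back.modality == "MVCT"


class TestRigidTransform:
    def test_roll_limit(self):
        with pytest.raises(ValueError):
            RigidTransform(roll_deg=20.0)

    def test_inverse_composes_to_identity(self):
        t = RigidTransform(dx=3.1, dy=-2.0, dz=6.0, roll_deg=4.0)
        x, y, z = t.apply(10.0, -5.0, 2.0)
        xb, yb, zb = t.inverse().apply(x, y, z)
        assert (xb, yb, zb) == pytest.approx((10.0, -5.0, 2.0))

    def test_json_round_trip(self, tmp_path):
        t = RigidTransform(dx=1.5, dy=-0.5, dz=3.0, roll_deg=-2.0)
        t.to_json(tmp_path / "t.json")
        assert RigidTransform.from_json(tmp_path / "t.json") == t


class TestResampleStructure:
    def test_identity_same_grid(self):
        g = mvct_geometry(3, 64, 64)
        mask = np.zeros(g.shape, bool)
        mask[1] = disk_mask((64, 64), (32, 32), 10)
        out = resample_structure(mask, g, g, RigidTransform())
        np.testing.assert_array_equal(out, mask)

    def test_empty_mask_gives_empty_output(self):
        g = mvct_geometry(2, 16, 16)
        out = resample_structure(np.zeros(g.shape, bool), g, g)
        assert not out.any()

    def test_kv_square_to_mv_grid_preserves_area(self):
        """Regridding a 10x10 kVCT square to the MVCT grid keeps its mm^2
        area within one boundary-pixel ring (pixel-coverage oracle)."""
        kv = kvct_geometry(3, 64, 64)
        mv = mvct_geometry(3, 166, 166)
        mask = np.zeros(kv.shape, bool)
        mask[1, 27:37, 27:37] = True
        out = resample_structure(mask, kv, mv, RigidTransform())
        area_in = mask[1].sum() * kv.pixel_size**2
        area_out = out.sum() * mv.pixel_size**2
        perimeter_mm = 4 * 10 * kv.pixel_size
        assert abs(area_out - area_in) <= perimeter_mm * mv.pixel_size
        # through-plane: kv slice 1 (3 mm thick) maps near mv slice 1 only
        assert not out[0].any() or out[1].any()

    def test_pure_translation_equals_pixel_shift(self):
        """+5 mm posterior on the same grid shifts by round(5/pixel) rows."""
        g = mvct_geometry(1, 96, 96)
        mask = np.zeros(g.shape, bool)
        mask[0] = disk_mask((96, 96), (40, 48), 9)
        # transform maps dst world -> src world; dst row r samples src at
        # y + 5 mm, so the shape appears at lower rows (anterior shift)
        out = resample_structure(mask, g, g, RigidTransform(dy=5.0))
        shift = round(5.0 / g.pixel_size)
        expected = np.zeros_like(mask)
        expected[0] = np.roll(mask[0], -shift, axis=0)
        assert (out ^ expected).sum() <= 0.05 * mask.sum()

    def test_round_trip_through_inverse_transform(self):
        """Mapping to the daily grid and back recovers the mask (Dice >= 0.95)."""
        kv = kvct_geometry(3, 64, 64)
        mv = mvct_geometry(3, 166, 166)
        mask = np.zeros(kv.shape, bool)
        mask[1] = disk_mask((64, 64), (32, 30), 8)   # 201 px, convex
        t = RigidTransform(dx=4.0, dy=-3.0, roll_deg=2.0)
        fwd = resample_structure(mask, kv, mv, t)
        back = resample_structure(fwd, mv, kv, t.inverse())
        assert dice(back[1], mask[1]) >= 0.95


class TestStructureSet:
    def test_overlap_rejected(self, mv_geom):
        m = np.zeros(mv_geom.shape, bool)
        m[2, 100:110, 100:110] = True
        with pytest.raises(ValueError, match="overlap"):
            StructureSet(mv_geom, {"rectum": m, "prostate": m.copy()})

    def test_json_round_trip(self, tmp_path):
        g = mvct_geometry(4, 64, 64)
        rect = np.zeros(g.shape, bool)
        rect[1] = disk_mask((64, 64), (30, 30), 8)
        rect[2] = disk_mask((64, 64), (31, 29), 10)
        ss = StructureSet(g, {"rectum": rect})
        ss.to_json(tmp_path / "s.json")
        back = StructureSet.from_json(tmp_path / "s.json")
        for k in (1, 2):
            assert dice(back["rectum"][k], rect[k]) >= 0.99
        assert back.geometry.shape == g.shape
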