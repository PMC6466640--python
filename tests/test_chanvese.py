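"""Seeding, seed-shift optimisation and the Chan-Vese active contour."""

import numpy as np
import pytest
from scipy import ndimage

from rectseg.chanvese import (CVParams, chan_vese_segment, optimise_seed_shift,
                              seed_from_planning)
from rectseg.config import RunConfig
from rectseg.metrics import dice

from conftest import disk_mask


class TestSeedFromPlanning:
    def test_square_shrinks_by_one_ring(self):
        mask = np.zeros((32, 32), bool)
        mask[10:20, 10:20] = True
        out = seed_from_planning(mask)
        expected = np.zeros_like(mask)
        expected[11:19, 11:19] = True
        np.testing.assert_array_equal(out, expected)

    def test_single_pixel_returned_unchanged(self):
        mask = np.zeros((16, 16), bool)
        mask[8, 8] = True
        np.testing.assert_array_equal(seed_from_planning(mask), mask)

    def test_disk_area_strictly_smaller(self):
        mask = disk_mask((64, 64), (32, 32), 20)
        out = seed_from_planning(mask)
        assert 0 < out.sum() < mask.sum()
        assert (out & ~mask).sum() == 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            seed_from_planning(np.zeros((8, 8), bool))


def _oracle_shift(seed, intensity, max_shift):
    """Independent exhaustive search: scores via explicit mask rolling."""
    best = None
    rows = np.nonzero(seed.any(axis=1))[0]
    cols = np.nonzero(seed.any(axis=0))[0]
    for dr in range(-max_shift, max_shift + 1):
        if rows.min() + dr < 0 or rows.max() + dr >= seed.shape[0]:
            continue
        for dc in range(-max_shift, max_shift + 1):
            if cols.min() + dc < 0 or cols.max() + dc >= seed.shape[1]:
                continue
            shifted = np.roll(np.roll(seed, dr, axis=0), dc, axis=1)
            score = intensity[shifted].sum()
            key = (-round(score, 9), dr * dr + dc * dc, dr, dc)
            if best is None or key < best[0]:
                best = (key, (dr, dc))
    return best[1]


class TestOptimiseSeedShift:
    def test_self_correlation_gives_zero_shift(self):
        seed = disk_mask((64, 64), (32, 32), 8)
        _, shift = optimise_seed_shift(seed, seed.astype(float), max_shift=10)
        assert shift == (0, 0)

    def test_recovers_known_translation(self):
        seed = disk_mask((64, 64), (30, 30), 8)
        target = np.roll(np.roll(seed, 5, axis=0), -3, axis=1)
        shifted, shift = optimise_seed_shift(seed, target.astype(float),
                                             max_shift=10)
        assert shift == (5, -3)
        np.testing.assert_array_equal(shifted, target)

    def test_uniform_image_tie_breaks_to_zero(self):
        seed = disk_mask((64, 64), (32, 32), 8)
        _, shift = optimise_seed_shift(seed, np.ones((64, 64)), max_shift=6)
        assert shift == (0, 0)

    def test_matches_exhaustive_oracle_on_random_cases(self):
        """50 random seed/intensity pairs against the brute-force oracle."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            shape = (40, 40)
            seed = disk_mask(shape, (int(rng.integers(12, 28)),
                                     int(rng.integers(12, 28))),
                             int(rng.integers(3, 6)))
            intensity = rng.uniform(size=shape)
            _, shift = optimise_seed_shift(seed, intensity, max_shift=5)
            assert shift == _oracle_shift(seed, intensity, 5)


@pytest.fixture(scope="module")
def bright_disk_problem():
    truth = disk_mask((96, 96), (48, 48), 20)
    intensity = truth.astype(float)
    seed = ndimage.binary_erosion(truth, np.ones((3, 3)), iterations=3)
    roi = np.zeros((96, 96), bool)
    roi[8:88, 8:88] = True
    return intensity, seed, roi, truth


class TestChanVese:
    def test_bright_disk_recovered(self, bright_disk_problem):
        intensity, seed, roi, truth = bright_disk_problem
        res = chan_vese_segment(intensity, seed, roi,
                                CVParams(smoothing=6, contraction_bias=0.0))
        assert dice(res.mask, truth) >= 0.98

    def test_seed_equal_to_bright_region_is_fixed_point(self):
        truth = disk_mask((64, 64), (32, 32), 12)
        roi = disk_mask((64, 64), (32, 32), 25)
        res = chan_vese_segment(truth.astype(float), truth, roi,
                                CVParams(smoothing=6, contraction_bias=0.0))
        assert dice(res.mask, truth) >= 0.99

    def test_energy_monotone_nonincreasing(self, bright_disk_problem):
        intensity, seed, roi, truth = bright_disk_problem
        res = chan_vese_segment(intensity + 0.05, seed, roi, CVParams())
        e = np.asarray(res.energies)
        tol = 1e-6 * np.maximum(1.0, np.abs(e[:-1]))
        assert (np.diff(e) <= tol).all()

    def test_invariant_to_intensity_offset(self, bright_disk_problem):
        intensity, seed, roi, _ = bright_disk_problem
        a = chan_vese_segment(intensity, seed, roi, CVParams())
        b = chan_vese_segment(intensity + 0.37, seed, roi, CVParams())
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_deterministic(self, bright_disk_problem):
        intensity, seed, roi, _ = bright_disk_problem
        a = chan_vese_segment(intensity, seed, roi, CVParams())
        b = chan_vese_segment(intensity, seed, roi, CVParams())
        np.testing.assert_array_equal(a.mask, b.mask)
        assert a.energies == b.energies

    def test_area_monotone_in_contraction_bias(self, daily_scan, planning_case):
        """More negative bias never shrinks the contour (the tuning grid)."""
        from rectseg.preprocess import (build_search_region, denoise_slice,
                                        mask_prostate, rescale_hu)
        from rectseg.resample import resample_structure

        geom = daily_scan.volume.geometry
        kvr = resample_structure(planning_case.structures["rectum"],
                                 planning_case.volume.geometry, geom,
                                 daily_scan.transform)
        k = geom.n_slices // 2
        den = denoise_slice(daily_scan.volume.data[k])
        roi = build_search_region(kvr[k], None, geom)
        intensity = rescale_hu(den) * roi.mask
        seed = seed_from_planning(kvr[k]) & roi.mask
        areas = []
        for bias in (-0.9, -1.0, -1.1):
            res = chan_vese_segment(intensity, seed, roi.mask,
                                    CVParams(smoothing=6, contraction_bias=bias))
            areas.append(res.mask.sum())
        assert areas[0] <= areas[1] <= areas[2]

    def test_uniform_image_expands_until_roi(self):
        seed = disk_mask((64, 64), (32, 32), 5)
        roi = disk_mask((64, 64), (32, 32), 18)
        res = chan_vese_segment(np.full((64, 64), 0.5), seed, roi,
                                CVParams(smoothing=6, contraction_bias=-1.0))
        # area term dominates: the contour grows to (nearly) fill the ROI
        assert res.mask.sum() >= 0.9 * roi.sum()

    def test_seed_outside_roi_rejected(self):
        seed = disk_mask((64, 64), (10, 10), 5)
        roi = disk_mask((64, 64), (40, 40), 15)
        with pytest.raises(ValueError, match="outside"):
            chan_vese_segment(np.zeros((64, 64)), seed, roi, CVParams())

    def test_nonfinite_intensity_rejected(self):
        seed = disk_mask((32, 32), (16, 16), 4)
        roi = disk_mask((32, 32), (16, 16), 10)
        img = np.zeros((32, 32))
        img[0, 0] = np.inf
        with pytest.raises(ValueError):
            chan_vese_segment(img, seed, roi, CVParams())
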