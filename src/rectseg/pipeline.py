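"""End-to-end per-scan orchestration of the autosegmentation pipeline.

Order of operations per daily scan (mirroring the flow of the method):
register planning structures onto the daily grid -> denoise -> intensity
rescale -> search region with spine limit -> air detection (daily and
planning) -> prostate blanking -> seeded, shift-optimised Chan-Vese
(pass 1) -> per-slice QC -> muscle-associated-region fallback to the
planning contour (plain, air-driven, or air-modified) -> polar surface
fit -> 3D self-check -> Chan-Vese pass 2 seeded from the smoothed shape,
falling back to the interpolated contour -> edge slices revert to the
planning contour.  No manual input anywhere; identical inputs give
bit-identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .chanvese import CVParams, chan_vese_segment, optimise_seed_shift, seed_from_planning
from .config import DEFAULT_CONFIG, RunConfig
from .geometry import Geometry, RigidTransform, Volume
from .metrics import jaccard, prostate_reference_slice
from .polar import PolarSurface, build_surface, fit_smoothed_surface, surface_slice_mask
from .postprocess import (SliceResult, find_muscle_region,
                          kv_fallback_contour, net_area_px, qc_slice)
from .preprocess import (AirRegion, SearchRegion, air_contour, build_search_region,
                         denoise_slice, detect_air, detect_spine_limit,
                         mask_prostate, rescale_hu)
from .resample import resample_image, resample_structure
from .structures import StructureSet

log = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), bool)


@dataclass
class ScanResult:
    """Per-slice best estimates plus the smoothed surface for one scan."""

    slices: list[SliceResult | None]
    smoothed: PolarSurface | None
    reference_slice: int
    kv_rectum: np.ndarray           # planning rectum resampled to the daily grid
    geometry: Geometry
    config_digest: str = ""

    def provenance_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.slices:
            if s is not None:
                counts[s.provenance] = counts.get(s.provenance, 0) + 1
        return counts

    def final_masks(self) -> np.ndarray:
        out = np.zeros(self.geometry.shape, bool)
        for k, s in enumerate(self.slices):
            if s is not None:
                out[k] = s.mask
        return out

    def provenance_table(self) -> pd.DataFrame:
        rows = []
        for k, s in enumerate(self.slices):
            if s is None:
                continue
            rows.append({
                "slice": k,
                "slice_offset": k - self.reference_slice,
                "provenance": s.provenance,
                "abuts_roi": s.flags.abuts_roi,
                "implausibly_large": s.flags.implausibly_large,
                "erroneous_vs_smooth": s.flags.erroneous_vs_smooth,
                "net_area_px": s.net_area_px,
                "jci_vs_smoothed": s.jci_vs_smoothed,
                "seed_shift_r": s.seed_shift[0],
                "seed_shift_c": s.seed_shift[1],
                "cv_iterations": s.cv_iterations,
                "cv_energy": s.cv_energy,
            })
        return pd.DataFrame(rows)


def _clip_seed(seed: np.ndarray, roi: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    clipped = seed & roi
    return clipped if clipped.any() else (fallback & roi)


def _significant_air(air: AirRegion) -> bool:
    return air.valid and air.tier in ("medium", "large")


def assemble_best_estimate(daily: Volume, planning: Volume,
                           planning_structures: StructureSet,
                           transform: RigidTransform,
                           params: CVParams | None = None,
                           config: RunConfig = DEFAULT_CONFIG) -> ScanResult:
    """Run the full autosegmentation pipeline on one daily scan."""
    if params is None:
        params = CVParams.from_config(config)
    geom = daily.geometry
    kv_geom = planning.geometry

    kv_rectum = resample_structure(planning_structures["rectum"], kv_geom, geom, transform)
    if not kv_rectum.any():
        raise ValueError("daily field of view has no planning rectum overlap")
    kv_prostate = (
        resample_structure(planning_structures["prostate"], kv_geom, geom, transform)
        if "prostate" in planning_structures
        else np.zeros(geom.shape, bool)
    )
    kv_img = resample_image(planning, geom, transform, fill=0.0)

    if kv_prostate.any():
        ref_slice = prostate_reference_slice(kv_prostate)
    else:
        ref_slice = geom.n_slices // 2
        log.warning("no prostate in field of view; using the central slice as origin")

    n = geom.n_slices
    results: list[SliceResult | None] = [None] * n
    rois: list[SearchRegion | None] = [None] * n
    airs: list[AirRegion | None] = [None] * n
    intensities: list[np.ndarray | None] = [None] * n

    for k in range(n):
        if not kv_rectum[k].any():
            continue
        try:
            results[k] = _segment_slice(
                k, daily.data[k], kv_img[k], kv_rectum[k], kv_prostate[k],
                geom, params, config, rois, airs, intensities,
            )
        except Exception:
            log.exception("slice %d failed; degrading to the planning contour", k)
            results[k] = SliceResult(mask=kv_rectum[k].copy(), provenance="kv_planning")

    processed = [k for k in range(n) if results[k] is not None]
    if not processed:
        raise ValueError("no slice produced a contour")

    # ---- muscle-associated region -------------------------------------
    implausible = [bool(results[k] and results[k].flags.implausibly_large)
                   for k in range(n)]
    muscle_top = find_muscle_region(implausible, n, config)
    for k in processed:
        if k > muscle_top:
            continue
        res = results[k]
        if res.provenance == "air":
            continue  # significant daily air wins even in the muscle region
        air_kv = detect_air(denoise_slice(kv_img[k], config.median_width_px),
                            kv_rectum[k], roi=rois[k].mask if rois[k] else None,
                            config=config)
        mv_area = airs[k].area_px if airs[k] and airs[k].valid else 0
        if _significant_air(air_kv) and air_kv.area_px > mv_area:
            mask = kv_fallback_contour(kv_rectum[k], air_kv.area_px, mv_area)
            res.mask = mask
            res.provenance = "kv_air_modified"
        else:
            res.mask = kv_rectum[k].copy()
            res.provenance = "kv_planning"
        res.flags.implausibly_large = False
        res.net_area_px = net_area_px(res.mask, airs[k])

    # ---- 3D self-check -------------------------------------------------
    current = [results[k].mask if results[k] is not None else None for k in range(n)]
    excluded = {
        k for k in processed
        if results[k].flags.abuts_roi or results[k].flags.implausibly_large
    }
    smoothed: PolarSurface | None = None
    usable = [k for k in processed if k not in excluded]
    if len(usable) >= 3:
        surface = build_surface(current, geom, ref_slice, config.n_theta)
        # slices whose profile failed also drop out of the fit
        bad_profile = {k for k in processed if not np.isfinite(surface.r[k]).all()}
        try:
            smoothed = fit_smoothed_surface(surface, excluded | bad_profile,
                                            config.fourier_harmonics)
        except ValueError:
            log.warning("too few usable slices for the smoothed surface")
    if smoothed is not None:
        _second_pass(results, smoothed, processed, muscle_top, geom, params,
                     config, rois, intensities, kv_rectum)

    # final diagnostics
    for k in processed:
        res = results[k]
        if smoothed is not None:
            sm = surface_slice_mask(smoothed, k, geom)
            res.jci_vs_smoothed = jaccard(res.mask, sm)
        res.net_area_px = net_area_px(res.mask, airs[k])

    return ScanResult(slices=results, smoothed=smoothed, reference_slice=ref_slice,
                      kv_rectum=kv_rectum, geometry=geom,
                      config_digest=config.digest())


def _segment_slice(k: int, raw_hu: np.ndarray, kv_hu: np.ndarray,
                   kv_rectum_slice: np.ndarray, kv_prostate_slice: np.ndarray,
                   geom: Geometry, params: CVParams, config: RunConfig,
                   rois: list, airs: list, intensities: list) -> SliceResult:
    """Pass-1 best estimate for one slice (pre muscle-region logic)."""
    den = denoise_slice(raw_hu, config.median_width_px)
    spine = detect_spine_limit(den, config)
    roi = build_search_region(kv_rectum_slice, spine, geom, config)
    rois[k] = roi
    air = detect_air(den, kv_rectum_slice, roi=roi.mask, config=config)
    airs[k] = air

    intensity = rescale_hu(den, config)
    intensity = mask_prostate(intensity, kv_prostate_slice)
    intensity *= roi.mask  # outside the search region reads as background
    intensities[k] = intensity

    if air.valid and air.tier == "large":
        mask = air_contour(air, geom, config) & roi.mask
        return SliceResult(mask=mask, provenance="air",
                           net_area_px=net_area_px(mask, air))

    seed = seed_from_planning(kv_rectum_slice)
    if air.valid and air.tier == "medium":
        seed = seed | (air_contour(air, geom, config) & roi.mask)
    seed = _clip_seed(seed, roi.mask, kv_rectum_slice)
    seed, shift = optimise_seed_shift(seed, intensity, config.seed_max_shift_px)
    seed = _clip_seed(seed, roi.mask, kv_rectum_slice)

    cv = chan_vese_segment(intensity, seed, roi.mask, params, config)
    mask = cv.mask
    if not mask.any():
        return SliceResult(mask=kv_rectum_slice.copy(), provenance="kv_planning",
                           seed_shift=shift)
    if air.valid and air.tier == "medium":
        mask = ndimage.binary_fill_holes(mask | (air_contour(air, geom, config)
                                                 & roi.mask))
    flags = qc_slice(mask, air, roi, in_muscle_region=False, config=config)
    return SliceResult(mask=mask, provenance="cv_pass1", flags=flags,
                       net_area_px=net_area_px(mask, air), seed_shift=shift,
                       cv_iterations=cv.iterations, cv_energy=cv.final_energy)


def _second_pass(results: list, smoothed: PolarSurface, processed: list[int],
                 muscle_top: int, geom: Geometry, params: CVParams,
                 config: RunConfig, rois: list, intensities: list,
                 kv_rectum: np.ndarray) -> None:
    """Repair slices inconsistent with the smoothed 3D shape."""
    k_lo, k_hi = min(processed), max(processed)
    for k in processed:
        res = results[k]
        if k <= muscle_top or res.provenance in ("air", "kv_planning",
                                                 "kv_air_modified"):
            continue
        sm = surface_slice_mask(smoothed, k, geom)
        bad_vs_smooth = jaccard(res.mask, sm) < config.jci_threshold
        res.flags.erroneous_vs_smooth = bad_vs_smooth
        needs_repair = bad_vs_smooth or res.flags.abuts_roi or res.flags.implausibly_large
        if not needs_repair:
            continue
        if k in (k_lo, k_hi):
            # no extrapolation at the scan edges: revert to planning contour
            res.mask = kv_rectum[k].copy()
            res.provenance = "kv_planning"
            continue
        roi = rois[k]
        intensity = intensities[k]
        seed2 = ndimage.binary_erosion(sm, structure=_STRUCT8)
        if not seed2.any():
            seed2 = sm
        seed2 = seed2 & roi.mask
        if not seed2.any():
            res.mask = sm & roi.mask
            res.provenance = "interpolated"
            continue
        cv2 = chan_vese_segment(intensity, seed2, roi.mask, params, config)
        if cv2.mask.any() and jaccard(cv2.mask, sm) > config.jci_threshold:
            res.mask = cv2.mask
            res.provenance = "cv_pass2"
            res.cv_iterations = cv2.iterations
            res.cv_energy = cv2.final_energy
        else:
            out = sm & roi.mask
            res.mask = out if out.any() else sm
            res.provenance = "interpolated"
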