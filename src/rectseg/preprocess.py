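"""Pre-processing of a registered daily guidance slice.

These steps turn the raw MVCT slice plus the propagated planning priors
into the inputs the active contour needs:

* median denoising (width 5);
* the HU -> [0, 1] intensity transfer function that maps rectal wall and
  contents toward 1, gas pockets (< -130 HU) to 1, and everything else
  toward 0;
* the anisotropic search region grown around the planning rectum, with an
  optional posterior limit at the spine;
* detection and triage of rectal gas by connected-component area;
* blanking of the planning prostate so the expanding contour cannot leak
  across the anterior rectal wall.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .config import DEFAULT_CONFIG, RunConfig
from .geometry import Geometry

log = logging.getLogger(__name__)

# 8-connected in-plane components and 3x3 square structuring element
_STRUCT8 = np.ones((3, 3), bool)

AirTier = Literal["none", "small", "medium", "large"]


def denoise_slice(slice_hu: np.ndarray, width: int = 5) -> np.ndarray:
    """2D median filter of odd ``width``; edges handled by reflection."""
    if width < 1 or width % 2 == 0:
        raise ValueError("median filter width must be odd and >= 1")
    img = np.asarray(slice_hu, float)
    if width == 1:
        return img.copy()
    return ndimage.median_filter(img, size=width, mode="reflect")


def rescale_hu(hu, config: RunConfig = DEFAULT_CONFIG):
    """Piecewise-linear HU -> intensity transfer function on [0, 1].

    Gas (< -130 HU) maps to 1 so pockets read as rectal content; the
    critical range -10..100 HU carries the ramps, with a plateau of 1 on
    30..60 HU; HU in (-130, -10) and above 100 map to 0.  Scalar in,
    scalar out; array in, array out.
    """
    arr = np.asarray(hu, float)
    if np.isnan(arr).any():
        raise ValueError("NaN HU value")
    c = config
    out = np.zeros_like(arr)
    out[arr < c.gas_hu] = 1.0
    rising = (arr >= c.critical_low_hu) & (arr < c.plateau_low_hu)
    out[rising] = (arr[rising] - c.critical_low_hu) / (c.plateau_low_hu - c.critical_low_hu)
    out[(arr >= c.plateau_low_hu) & (arr <= c.plateau_high_hu)] = 1.0
    falling = (arr > c.plateau_high_hu) & (arr <= c.critical_high_hu)
    out[falling] = (c.critical_high_hu - arr[falling]) / (c.critical_high_hu - c.plateau_high_hu)
    if np.isscalar(hu) or np.ndim(hu) == 0:
        return float(out)
    return out


@dataclass
class SearchRegion:
    """Region of interest for contour evolution on one slice."""

    mask: np.ndarray
    expansions: dict[str, int]
    posterior_limit_row: int | None = None


def detect_spine_limit(slice_hu: np.ndarray, config: RunConfig = DEFAULT_CONFIG
                       ) -> int | None:
    """Most anterior row of the spine, if identifiable, else ``None``.

    Bone is thresholded on the (denoised) HU slice; only components in the
    posterior half of the image count, and only if large enough that soft
    tissue cannot trigger the limit.
    """
    img = np.asarray(slice_hu, float)
    n_rows = img.shape[0]
    bone = img >= config.spine_threshold_hu
    bone[: n_rows // 2, :] = False  # spine must be posterior
    if not bone.any():
        return None
    labels, n = ndimage.label(bone, structure=_STRUCT8)
    if n == 0:
        return None
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    if sizes[largest - 1] < config.spine_min_area_px:
        return None
    rows = np.nonzero(labels == largest)[0]
    return int(rows.min())


def build_search_region(planning_rectum_slice_mask: np.ndarray,
                        spine_limit: int | None,
                        geometry: Geometry,
                        config: RunConfig = DEFAULT_CONFIG) -> SearchRegion:
    """Grow the registered planning rectum anisotropically into an ROI.

    Expansion is 50 px anterior (low rows), 20 px posterior, 40 px left and
    right on the MVCT grid; the region is clipped at the spine limit when
    one was found, and always contains the planning mask itself.
    """
    mask = np.asarray(planning_rectum_slice_mask, bool)
    if not mask.any():
        raise ValueError("planning rectum mask is empty on this slice")
    rows = np.nonzero(mask.any(axis=1))[0]
    cols = np.nonzero(mask.any(axis=0))[0]
    c = config
    r0 = max(0, int(rows.min()) - c.expand_anterior_px)
    r1 = min(mask.shape[0] - 1, int(rows.max()) + c.expand_posterior_px)
    c0 = max(0, int(cols.min()) - c.expand_right_px)   # low col = patient right
    c1 = min(mask.shape[1] - 1, int(cols.max()) + c.expand_left_px)
    out = np.zeros_like(mask)
    out[r0 : r1 + 1, c0 : c1 + 1] = True
    if spine_limit is not None:
        out[spine_limit:, :] = False
    out |= mask  # the prior itself is never clipped away
    return SearchRegion(
        mask=out,
        expansions={
            "anterior": c.expand_anterior_px,
            "posterior": c.expand_posterior_px,
            "left": c.expand_left_px,
            "right": c.expand_right_px,
        },
        posterior_limit_row=spine_limit,
    )


@dataclass
class AirRegion:
    """Largest connected gas component on a slice, triaged by area.

    Tiers: ``small`` (< 150 px) is left to the transfer function, ``medium``
    (150-600 px) contributes a wall-margin contour, ``large`` (> 600 px)
    becomes the rectal contour outright.  A region whose centroid falls
    outside the planning rectum is marked invalid and ignored downstream.
    """

    mask: np.ndarray
    area_px: int
    tier: AirTier
    valid: bool


def detect_air(slice_hu: np.ndarray, planning_rectum_slice_mask: np.ndarray,
               roi: np.ndarray | None = None,
               config: RunConfig = DEFAULT_CONFIG) -> AirRegion:
    """Find and triage the largest connected gas region on a slice.

    Gas pixels are HU < -130.  ``roi`` optionally restricts the search to
    the search region (without it, air outside the patient would dominate
    on clinical scans).
    """
    img = np.asarray(slice_hu, float)
    mask = np.asarray(planning_rectum_slice_mask, bool)
    air = img < config.gas_hu
    if roi is not None:
        air &= np.asarray(roi, bool)
    if not air.any():
        return AirRegion(np.zeros_like(air), 0, "none", False)
    labels, n = ndimage.label(air, structure=_STRUCT8)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    largest = int(np.argmax(sizes)) + 1
    comp = labels == largest
    area = int(sizes[largest - 1])
    if area < config.air_small_max_px:
        tier: AirTier = "small"
    elif area <= config.air_medium_max_px:
        tier = "medium"
    else:
        tier = "large"
    r_c, c_c = ndimage.center_of_mass(comp)
    rr, cc = int(round(r_c)), int(round(c_c))
    inside = (
        0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1] and bool(mask[rr, cc])
    )
    return AirRegion(comp, area, tier, inside)


def air_contour(region: AirRegion, geometry: Geometry,
                config: RunConfig = DEFAULT_CONFIG) -> np.ndarray:
    """Rectal-contour estimate from a medium or large valid air region.

    The component is hole-filled and enlarged by 8 px (6 mm) of rectal
    wall; large regions additionally get boundary smoothing (morphological
    closing then opening) for a realistic outline.  Output is a single
    connected, hole-free mask.
    """
    if region.tier not in ("medium", "large") or not region.valid:
        raise ValueError("air contour requires a valid medium or large air region")
    comp = ndimage.binary_fill_holes(region.mask)
    grown = ndimage.binary_dilation(comp, structure=_STRUCT8,
                                    iterations=config.air_wall_margin_px)
    if region.tier == "large":
        r = config.air_smooth_radius_px
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        disk = (yy**2 + xx**2) <= r**2
        grown = ndimage.binary_closing(grown, structure=disk)
        grown = ndimage.binary_opening(grown, structure=disk)
        grown |= comp  # smoothing must never lose the gas itself
    out = ndimage.binary_fill_holes(grown)
    labels, n = ndimage.label(out, structure=_STRUCT8)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        out = labels == (int(np.argmax(sizes)) + 1)
    return out


def mask_prostate(intensity: np.ndarray, prostate_slice_mask: np.ndarray) -> np.ndarray:
    """Zero the intensity on prostate pixels; everything else untouched."""
    out = np.asarray(intensity, float).copy()
    out[np.asarray(prostate_slice_mask, bool)] = 0.0
    return out
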