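"""Polar (r-theta-z) representation of the stacked rectal contours.

Each slice contour becomes a radius profile r(theta) about its own
centroid, sampled at 100 evenly spaced angles; the stack of profiles over
slices forms a regular (theta, z) grid with z measured from the prostate
reference slice.  A smooth surface is fitted to this grid — a truncated
Fourier series in theta (periodic by construction) and a cubic smoothing
spline in z with generalised cross-validation — to provide the 3D
self-check and the interpolated fallback contours.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import draw

from .geometry import Geometry

log = logging.getLogger(__name__)


@dataclass
class PolarSurface:
    """Radii (mm) on a regular grid of ``n_theta`` angles x ``Nz`` slices.

    ``z_offsets`` are slice indices relative to the prostate reference
    slice; ``centroids`` holds the per-slice (row, col) pixel origin of
    the rays.  Slices with no contour carry NaN radii.
    """

    r: np.ndarray                    # (n_slices, n_theta) mm
    theta: np.ndarray                # (n_theta,) radians, [0, 2pi)
    z_offsets: np.ndarray            # (n_slices,) ints
    centroids: np.ndarray            # (n_slices, 2) float (row, col)

    def __post_init__(self) -> None:
        if self.r.shape != (len(self.z_offsets), len(self.theta)):
            raise ValueError("r grid shape mismatch")


def contour_to_polar(mask: np.ndarray, geometry: Geometry, n_theta: int = 100
                     ) -> tuple[np.ndarray, tuple[float, float]]:
    """Radius profile r(theta) in mm about the mask centroid.

    For each evenly spaced angle the radius is the outermost boundary
    crossing along the ray (outermost so that mildly non-star-shaped
    contours still produce a usable profile; a warning is logged if the
    centroid itself falls outside the mask).
    """
    m = np.asarray(mask, bool)
    if not m.any():
        raise ValueError("empty mask has no polar profile")
    cr, cc = ndimage.center_of_mass(m)
    if not m[int(round(cr)), int(round(cc))]:
        log.warning("contour centroid lies outside the mask (non-convex shape)")
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    # outermost sub-pixel boundary crossing per angular bin (marching
    # squares); pixel-centre boundaries would put a half-pixel ripple on r
    from .structures import mask_to_polygons

    pts = np.vstack([np.asarray(p, float) for p in mask_to_polygons(m)])
    dist = np.hypot(pts[:, 0] - cr, pts[:, 1] - cc)
    ang = np.mod(np.arctan2(pts[:, 0] - cr, pts[:, 1] - cc), 2.0 * np.pi)
    idx = np.mod(np.round(ang / (2.0 * np.pi / n_theta)).astype(int), n_theta)
    r_px = np.zeros(n_theta)
    np.maximum.at(r_px, idx, dist)
    # bins with no boundary pixel are filled by periodic interpolation
    if (r_px == 0).any() and (r_px > 0).any():
        good = r_px > 0
        r_px[~good] = np.interp(
            theta[~good], theta[good], r_px[good], period=2.0 * np.pi
        )
    r_px = np.maximum(r_px, 0.5)  # single-pixel masks still have extent
    return r_px * geometry.pixel_size, (float(cr), float(cc))


def polar_to_contour(r_mm: np.ndarray, centroid: tuple[float, float],
                     geometry: Geometry,
                     shape: tuple[int, int] | None = None) -> np.ndarray:
    """Rasterise the closed polygon with vertices centroid + r(theta)."""
    r_mm = np.asarray(r_mm, float)
    if (r_mm <= 0).any():
        raise ValueError("all radii must be positive")
    n_theta = len(r_mm)
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    r_px = r_mm / geometry.pixel_size
    rows = centroid[0] + r_px * np.sin(theta)
    cols = centroid[1] + r_px * np.cos(theta)
    if shape is None:
        shape = (geometry.n_rows, geometry.n_cols)
    return draw.polygon2mask(shape, np.column_stack([rows, cols]))


def build_surface(masks: list[np.ndarray | None], geometry: Geometry,
                  reference_slice: int, n_theta: int = 100) -> PolarSurface:
    """Stack per-slice polar profiles into a regular (theta, z) grid."""
    n = len(masks)
    r = np.full((n, n_theta), np.nan)
    centroids = np.full((n, 2), np.nan)
    for k, m in enumerate(masks):
        if m is None or not np.asarray(m, bool).any():
            continue
        r[k], centroids[k] = contour_to_polar(m, geometry, n_theta)
    return PolarSurface(
        r=r,
        theta=np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False),
        z_offsets=np.arange(n) - reference_slice,
        centroids=centroids,
    )


def _fourier_design(theta: np.ndarray, harmonics: int) -> np.ndarray:
    cols = [np.ones_like(theta)]
    for h in range(1, harmonics + 1):
        cols.append(np.cos(h * theta))
        cols.append(np.sin(h * theta))
    return np.column_stack(cols)


def _smooth_z(z: np.ndarray, y: np.ndarray, z_eval: np.ndarray) -> np.ndarray:
    """Robust low-order polynomial fit across slices.

    Guidance scans carry only 8-12 slices, so the cranio-caudal trend is
    modelled as a cubic (degree shrinks for fewer points) fitted by
    Huber-reweighted least squares: a single erroneous slice then produces
    a large residual against the surface instead of dragging it along.
    """
    z = np.asarray(z, float)
    y = np.asarray(y, float)
    if len(z) == 1:
        return np.full(len(z_eval), y[0])
    if len(z) >= 3:
        # running median first: a lone corrupted slice cannot steer the
        # fit even from an endpoint, where polynomial leverage is high
        y = ndimage.median_filter(y, size=3, mode="mirror")
    deg = int(min(3, len(z) - 2)) if len(z) > 2 else 1
    w = np.ones_like(y)
    coef = np.polyfit(z, y, deg)
    for _ in range(3):
        resid = y - np.polyval(coef, z)
        scale = 1.4826 * np.median(np.abs(resid)) + 1e-9
        w = np.minimum(1.0, 1.345 * scale / (np.abs(resid) + 1e-12))
        coef = np.polyfit(z, y, deg, w=np.sqrt(w))
    return np.polyval(coef, np.asarray(z_eval, float))


def fit_smoothed_surface(surface: PolarSurface, excluded_slices: set[int],
                         harmonics: int = 5) -> PolarSurface:
    """Fit the smooth r(theta, z) surface, ignoring excluded slices.

    Per usable slice the radius profile is projected onto Fourier
    harmonics 0..``harmonics`` (periodic in theta); each Fourier
    coefficient is then smoothed across z with a GCV cubic smoothing
    spline and evaluated on *all* slices, excluded ones included, so the
    surface provides an interpolated contour wherever the per-slice result
    was rejected.  Centroids of excluded slices are interpolated the same
    way.  Requires at least three usable slices.
    """
    usable = [
        k for k in range(surface.r.shape[0])
        if k not in excluded_slices and np.isfinite(surface.r[k]).all()
    ]
    if len(usable) < 3:
        raise ValueError(f"need >= 3 usable slices to fit a surface, have {len(usable)}")
    design = _fourier_design(surface.theta, harmonics)
    coef = np.empty((len(usable), design.shape[1]))
    for i, k in enumerate(usable):
        coef[i], *_ = np.linalg.lstsq(design, surface.r[k], rcond=None)

    z_use = surface.z_offsets[usable].astype(float)
    z_all = surface.z_offsets.astype(float)
    coef_all = np.empty((len(z_all), design.shape[1]))
    for j in range(design.shape[1]):
        coef_all[:, j] = _smooth_z(z_use, coef[:, j], z_all)

    r_fit = coef_all @ design.T
    min_r = 0.5 * 1.0  # never collapse below half a millimetre
    if (r_fit <= 0).any():
        log.warning("smoothed surface clipped at %g mm on some rays", min_r)
        r_fit = np.maximum(r_fit, min_r)

    # centroids are smoothed across z as well: a displaced slice contour
    # must disagree with the surface, not drag it along
    cen = surface.centroids.copy()
    cen_use = surface.centroids[usable]
    for j in range(2):
        cen[:, j] = _smooth_z(z_use, cen_use[:, j], z_all)
    return PolarSurface(r=r_fit, theta=surface.theta.copy(),
                        z_offsets=surface.z_offsets.copy(), centroids=cen)


def surface_slice_mask(surface: PolarSurface, k: int, geometry: Geometry,
                       shape: tuple[int, int] | None = None) -> np.ndarray:
    """Rasterise slice ``k`` of a (smoothed) surface back to a mask."""
    return polar_to_contour(surface.r[k], tuple(surface.centroids[k]), geometry,
                            shape=shape)
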