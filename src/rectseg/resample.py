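"""Rigid propagation of planning structures and images onto the daily grid.

Planning (kVCT) structures are regridded onto the MVCT guidance grid by
transforming their polygonal boundaries through the setup-correction
transform and rasterising on the destination grid.  Images are resampled
bilinearly in-plane; through-plane, the nearest source slice is used (the
couch correction is in-plane, and slice thicknesses differ).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage
from skimage import draw

from .geometry import Geometry, RigidTransform, Volume
from .structures import mask_to_polygons

log = logging.getLogger(__name__)


def _dst_slice_to_src(k_dst: int, src: Geometry, dst: Geometry,
                      transform: RigidTransform) -> int | None:
    """Nearest source slice for a destination slice, or None if outside."""
    z_dst = float(dst.slice_z(np.array(k_dst)))
    z_src = z_dst + transform.dz
    k_src = src.nearest_slice(z_src)
    if k_src < 0 or k_src >= src.n_slices:
        return None
    # reject if the nearest source slice centre is more than one source
    # slice away (grids that do not overlap at this z)
    if abs(float(src.slice_z(np.array(k_src))) - z_src) > src.slice_thickness:
        return None
    return k_src


def resample_structure(mask: np.ndarray, src: Geometry, dst: Geometry,
                       transform: RigidTransform = RigidTransform()) -> np.ndarray:
    """Regrid a 3D binary mask from ``src`` onto ``dst`` through ``transform``.

    ``transform`` maps destination-grid world coordinates to source-grid
    world coordinates (the convention of :class:`RigidTransform` with the
    planning grid as source and the daily grid as destination).  Boundary
    polygons are extracted on the source grid, mapped through the inverse
    transform, and rasterised with a pixel-centre-inside rule (the >= 0.5
    coverage rule for straight boundaries).  Destination slices outside the
    source extent come back empty.
    """
    mask = np.asarray(mask, bool)
    if mask.shape != src.shape:
        raise ValueError(f"mask shape {mask.shape} != source grid {src.shape}")
    out = np.zeros(dst.shape, bool)
    if not mask.any():
        log.warning("resample_structure: empty input mask")
        return out

    same_grid = (
        src.shape == dst.shape
        and abs(src.pixel_size - dst.pixel_size) < 1e-12
        and abs(src.slice_thickness - dst.slice_thickness) < 1e-12
        and np.allclose(src.origin, dst.origin)
    )
    if same_grid and transform.is_identity:
        return mask.copy()

    inv = transform.inverse()  # src world -> dst world
    shape2d = (dst.n_rows, dst.n_cols)
    for k_dst in range(dst.n_slices):
        k_src = _dst_slice_to_src(k_dst, src, dst, transform)
        if k_src is None or not mask[k_src].any():
            continue
        for poly in mask_to_polygons(mask[k_src]):
            pts = np.asarray(poly, float)
            x, y = src.world_xy(pts[:, 0], pts[:, 1])
            xd, yd, _ = inv.apply(x, y, np.zeros_like(x))
            r, c = dst.pixel_rc(xd, yd)
            out[k_dst] |= draw.polygon2mask(shape2d, np.column_stack([r, c]))
    return out


def resample_image(vol: Volume, dst: Geometry,
                   transform: RigidTransform = RigidTransform(),
                   fill: float = 0.0) -> np.ndarray:
    """Resample an HU volume onto ``dst``: bilinear in-plane, nearest slice."""
    out = np.full(dst.shape, fill, float)
    rows, cols = np.meshgrid(np.arange(dst.n_rows), np.arange(dst.n_cols),
                             indexing="ij")
    xd, yd = dst.world_xy(rows, cols)
    xs, ys, _ = transform.apply(xd, yd, np.zeros_like(xd))
    rs, cs = vol.geometry.pixel_rc(xs, ys)
    coords = np.stack([rs.ravel(), cs.ravel()])
    for k_dst in range(dst.n_slices):
        k_src = _dst_slice_to_src(k_dst, vol.geometry, dst, transform)
        if k_src is None:
            continue
        vals = ndimage.map_coordinates(vol.data[k_src], coords, order=1,
                                       mode="constant", cval=fill)
        out[k_dst] = vals.reshape(dst.n_rows, dst.n_cols)
    return out
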