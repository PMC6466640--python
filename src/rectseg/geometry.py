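"""Grid geometry, units, volumes and rigid setup-correction transforms.

Conventions (fixed package-wide):

* array axis order is ``(slice, row, col)``, 0-based;
* row index increases in the **posterior** direction (the spine sits at
  high row index), column index increases toward **patient left**, slice
  index increases **inferior -> superior**;
* world coordinates are millimetres: ``x`` along columns, ``y`` along rows,
  ``z`` along slices, so anterior is -y and superior is +z.

Two grids are in play throughout: the kVCT planning grid (1.953 mm pixels,
3 mm slices) and the MVCT daily image-guidance grid (0.754 mm pixels, 6 mm
slices, a short 8-12 slice field of view).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np

# CT sanity bounds in Hounsfield units
HU_MIN = -1100.0
HU_MAX = 3100.0

#: Published grid constants for the two modalities.
KVCT_PIXEL_MM = 1.953
KVCT_SLICE_MM = 3.0
MVCT_PIXEL_MM = 0.754
MVCT_SLICE_MM = 6.0

Modality = Literal["kVCT", "MVCT"]


@dataclass(frozen=True)
class Geometry:
    """Regular image grid: square in-plane pixels, uniform slice spacing.

    ``origin_mm`` is the world position of the centre of voxel
    ``(slice=0, row=0, col=0)`` as ``(x0, y0, z0)``.  When ``None`` the
    volume is centred on the world origin, which is the convention used for
    phantom volumes (both grids share the patient isocentre).
    """

    pixel_size: float
    slice_thickness: float
    n_rows: int
    n_cols: int
    n_slices: int
    orientation: str = "RAI-style (row->posterior, col->left, slice->superior)"
    origin_mm: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not (self.pixel_size > 0 and self.slice_thickness > 0):
            raise ValueError("pixel_size and slice_thickness must be positive")
        if min(self.n_rows, self.n_cols, self.n_slices) < 1:
            raise ValueError("grid dimensions must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return (self.n_slices, self.n_rows, self.n_cols)

    @property
    def origin(self) -> np.ndarray:
        if self.origin_mm is not None:
            return np.asarray(self.origin_mm, dtype=float)
        # centre the volume on the world origin
        return np.array(
            [
                -(self.n_cols - 1) / 2.0 * self.pixel_size,
                -(self.n_rows - 1) / 2.0 * self.pixel_size,
                -(self.n_slices - 1) / 2.0 * self.slice_thickness,
            ]
        )

    # -- index <-> world ---------------------------------------------------
    def world_xy(self, rows: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """In-plane pixel indices (float ok) -> world (x, y) in mm."""
        o = self.origin
        return o[0] + np.asarray(cols, float) * self.pixel_size, o[1] + np.asarray(
            rows, float
        ) * self.pixel_size

    def pixel_rc(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """World (x, y) mm -> fractional (row, col) indices."""
        o = self.origin
        return (np.asarray(y, float) - o[1]) / self.pixel_size, (
            np.asarray(x, float) - o[0]
        ) / self.pixel_size

    def slice_z(self, k: np.ndarray) -> np.ndarray:
        return self.origin[2] + np.asarray(k, float) * self.slice_thickness

    def nearest_slice(self, z: float) -> int:
        """Index of the slice whose centre is nearest to world z (unclipped)."""
        return int(round((z - self.origin[2]) / self.slice_thickness))


def mvct_geometry(n_slices: int = 10, n_rows: int = 512, n_cols: int = 512,
                  origin_mm: tuple[float, float, float] | None = None) -> Geometry:
    return Geometry(MVCT_PIXEL_MM, MVCT_SLICE_MM, n_rows, n_cols, n_slices,
                    origin_mm=origin_mm)


def kvct_geometry(n_slices: int = 32, n_rows: int = 272, n_cols: int = 272,
                  origin_mm: tuple[float, float, float] | None = None) -> Geometry:
    return Geometry(KVCT_PIXEL_MM, KVCT_SLICE_MM, n_rows, n_cols, n_slices,
                    origin_mm=origin_mm)


@dataclass
class Volume:
    """A 3D HU image bound to a :class:`Geometry` and a modality tag."""

    data: np.ndarray
    geometry: Geometry
    modality: Modality

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != self.geometry.shape:
            raise ValueError(
                f"data shape {self.data.shape} != geometry shape {self.geometry.shape}"
            )
        lo, hi = float(self.data.min()), float(self.data.max())
        if lo < HU_MIN or hi > HU_MAX:
            raise ValueError(f"HU values [{lo}, {hi}] outside sane CT range")
        if self.modality not in ("kVCT", "MVCT"):
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass(frozen=True)
class RigidTransform:
    """Rigid setup correction: translations in mm, roll about the z axis.

    The transform maps world coordinates on the *daily* grid into world
    coordinates on the *planning* grid (the couch correction applied at
    treatment).  ``apply`` therefore sends daily points to planning points;
    use :meth:`inverse` for the other direction.
    """

    dx: float = 0.0
    dy: float = 0.0
    dz: float = 0.0
    roll_deg: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.dx, self.dy, self.dz, self.roll_deg)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("transform parameters must be finite")
        if abs(self.roll_deg) >= 15.0:
            raise ValueError("|roll| must be < 15 degrees")

    def apply(self, x: np.ndarray, y: np.ndarray, z: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        th = np.deg2rad(self.roll_deg)
        c, s = np.cos(th), np.sin(th)
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        return c * x - s * y + self.dx, s * x + c * y + self.dy, np.asarray(z, float) + self.dz

    def inverse(self) -> "RigidTransform":
        th = np.deg2rad(self.roll_deg)
        c, s = np.cos(th), np.sin(th)
        # inverse of p' = R p + t is p = R^T p' - R^T t
        return RigidTransform(
            dx=-(c * self.dx + s * self.dy),
            dy=-(-s * self.dx + c * self.dy),
            dz=-self.dz,
            roll_deg=-self.roll_deg,
        )

    @property
    def is_identity(self) -> bool:
        return self.dx == self.dy == self.dz == self.roll_deg == 0.0

    # -- JSON --------------------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"dx_mm": self.dx, "dy_mm": self.dy, "dz_mm": self.dz,
                 "roll_deg": self.roll_deg},
                indent=1,
            )
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RigidTransform":
        d = json.loads(Path(path).read_text())
        return cls(dx=d["dx_mm"], dy=d["dy_mm"], dz=d["dz_mm"], roll_deg=d["roll_deg"])


def grid_metrics(count_or_length: float, geometry: Geometry,
                 mode: Literal["area", "distance"]) -> float:
    """Convert a pixel count (area) or pixel length (distance) to mm units.

    ``area`` returns ``count * pixel_size**2`` in mm^2; ``distance`` returns
    ``length * pixel_size`` in mm.  This is the conversion behind every
    pixel/mm pair quoted for thresholds and margins (e.g. the 2500 px =
    1420 mm^2 implausible-contour cut-off on the MVCT grid).
    """
    if count_or_length < 0:
        raise ValueError("pixel count/length must be non-negative")
    if mode == "area":
        return float(count_or_length) * geometry.pixel_size**2
    if mode == "distance":
        return float(count_or_length) * geometry.pixel_size
    raise ValueError(f"unknown mode {mode!r}")


# -- NIfTI I/O -------------------------------------------------------------

def volume_to_nifti(vol: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI; voxel sizes go in the header zooms.

    Array axes (slice, row, col) are stored transposed to (col, row, slice)
    so the fastest NIfTI axis is in-plane.
    """
    arr = np.ascontiguousarray(np.transpose(vol.data, (2, 1, 0)))
    aff = np.diag([vol.geometry.pixel_size, vol.geometry.pixel_size,
                   vol.geometry.slice_thickness, 1.0])
    aff[:3, 3] = vol.geometry.origin
    img = nib.Nifti1Image(arr.astype(np.float32), aff)
    img.header.set_zooms((vol.geometry.pixel_size, vol.geometry.pixel_size,
                          vol.geometry.slice_thickness))
    img.header["descrip"] = vol.modality.encode()
    nib.save(img, str(path))


def volume_from_nifti(path: str | Path, modality: Modality | None = None) -> Volume:
    img = nib.load(str(path))
    arr = np.transpose(np.asanyarray(img.dataobj), (2, 1, 0)).astype(float)
    zx, zy, zz = img.header.get_zooms()[:3]
    if abs(zx - zy) > 1e-6:
        raise ValueError("anisotropic in-plane pixels are not supported")
    origin = tuple(float(v) for v in img.affine[:3, 3])
    geom = Geometry(float(zx), float(zz), arr.shape[1], arr.shape[2], arr.shape[0],
                    origin_mm=origin)
    if modality is None:
        desc = bytes(img.header["descrip"]).rstrip(b"\x00").decode() or "MVCT"
        modality = "kVCT" if desc == "kVCT" else "MVCT"
    return Volume(arr, geom, modality)
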