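"""Named per-slice binary structure masks bound to a grid.

Structures (rectum, prostate) are stored as full 3D boolean masks on a
stated :class:`~rectseg.geometry.Geometry`; slices where a structure is
absent are simply empty.  Serialisation uses closed polygons in a JSON
document, or binary-mask NIfTI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import draw, measure

from .geometry import Geometry, Volume, volume_to_nifti

KNOWN_NAMES = ("rectum", "prostate")


def mask_to_polygons(mask2d: np.ndarray) -> list[list[list[float]]]:
    """Closed [[row, col], ...] boundary polygons of a binary slice mask."""
    m = np.asarray(mask2d, bool)
    if not m.any():
        return []
    padded = np.pad(m.astype(float), 1)
    polys = []
    for contour in measure.find_contours(padded, 0.5):
        poly = contour - 1.0  # undo padding
        polys.append([[float(r), float(c)] for r, c in poly])
    return polys


def polygons_to_mask(polys: list[list[list[float]]], shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, bool)
    for poly in polys:
        out |= draw.polygon2mask(shape, np.asarray(poly, float))
    return out


@dataclass
class StructureSet:
    """Map of structure name -> 3D boolean mask on ``geometry``."""

    geometry: Geometry
    structures: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mask in self.structures.items():
            self.structures[name] = self._check(name, mask)
        self._check_disjoint()

    def _check(self, name: str, mask: np.ndarray) -> np.ndarray:
        mask = np.asarray(mask, bool)
        if mask.shape != self.geometry.shape:
            raise ValueError(f"mask {name!r} shape {mask.shape} != grid {self.geometry.shape}")
        return mask

    def _check_disjoint(self) -> None:
        if "rectum" in self.structures and "prostate" in self.structures:
            if (self.structures["rectum"] & self.structures["prostate"]).any():
                raise ValueError("rectum and prostate masks overlap")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.structures[name]

    def __contains__(self, name: str) -> bool:
        return name in self.structures

    def add(self, name: str, mask: np.ndarray) -> None:
        self.structures[name] = self._check(name, mask)
        self._check_disjoint()

    def slices_present(self, name: str) -> list[int]:
        m = self.structures[name]
        return [int(k) for k in range(m.shape[0]) if m[k].any()]

    # -- JSON polygons -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        doc = {
            "geometry": {
                "pixel_size_mm": self.geometry.pixel_size,
                "slice_thickness_mm": self.geometry.slice_thickness,
                "n_rows": self.geometry.n_rows,
                "n_cols": self.geometry.n_cols,
                "n_slices": self.geometry.n_slices,
                "origin_mm": list(self.geometry.origin),
            },
            "structures": {
                name: {
                    str(k): mask_to_polygons(mask[k])
                    for k in range(mask.shape[0])
                    if mask[k].any()
                }
                for name, mask in self.structures.items()
            },
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "StructureSet":
        doc = json.loads(Path(path).read_text())
        g = doc["geometry"]
        geom = Geometry(
            g["pixel_size_mm"], g["slice_thickness_mm"], g["n_rows"], g["n_cols"],
            g["n_slices"], origin_mm=tuple(g["origin_mm"]),
        )
        structures = {}
        for name, slices in doc["structures"].items():
            mask = np.zeros(geom.shape, bool)
            for k, polys in slices.items():
                mask[int(k)] = polygons_to_mask(polys, (geom.n_rows, geom.n_cols))
            structures[name] = mask
        return cls(geom, structures)

    # -- NIfTI export ------------------------------------------------------
    def to_nifti(self, name: str, path: str | Path) -> None:
        vol = Volume(self.structures[name].astype(float), self.geometry, "MVCT")
        volume_to_nifti(vol, path)
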