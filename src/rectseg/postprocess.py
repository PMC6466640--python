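"""Quality control of per-slice autocontours and fallback rules.

Three failure modes are policed: contours that expanded to the edge of
the search region, implausibly large contours (net area above 2500 px =
1420 mm^2 on the MVCT grid, after subtracting any gas inside), and
contours inconsistent with the smoothed 3D shape (JCI < 0.5).  The
inferior muscle-associated slices — where musculature is isointense with
the rectum and the active contour systematically over-segments — fall
back to the propagated planning contour, optionally eroded to account
for gas present in the planning scan but absent on the day.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .config import DEFAULT_CONFIG, RunConfig
from .geometry import Geometry
from .metrics import jaccard
from .polar import PolarSurface, surface_slice_mask
from .preprocess import AirRegion, SearchRegion

_STRUCT8 = np.ones((3, 3), bool)

Provenance = Literal["air", "kv_planning", "kv_air_modified", "cv_pass1",
                     "cv_pass2", "interpolated"]

PROVENANCE_LABELS: tuple[str, ...] = (
    "air", "kv_planning", "kv_air_modified", "cv_pass1", "cv_pass2", "interpolated",
)


@dataclass
class QCFlags:
    abuts_roi: bool = False
    implausibly_large: bool = False
    erroneous_vs_smooth: bool = False


@dataclass
class SliceResult:
    """Final rectal mask for one slice with provenance and diagnostics."""

    mask: np.ndarray
    provenance: Provenance
    flags: QCFlags = field(default_factory=QCFlags)
    net_area_px: int = 0
    jci_vs_smoothed: float = float("nan")
    seed_shift: tuple[int, int] = (0, 0)
    cv_iterations: int = 0
    cv_energy: float = float("nan")


def qc_slice(mask: np.ndarray, air: AirRegion | None, roi: SearchRegion,
             in_muscle_region: bool = False,
             config: RunConfig = DEFAULT_CONFIG) -> QCFlags:
    """Flag a candidate contour that abuts the ROI edge or is over-large.

    The area test subtracts gas pixels *inside* the candidate (exterior
    gas is irrelevant to how big the contour itself is) and is suspended
    inside the muscle-associated region, where over-contouring is the
    expected failure handled by the planning-contour fallback.
    """
    m = np.asarray(mask, bool)
    roi_m = np.asarray(roi.mask, bool)
    interior = ndimage.binary_erosion(roi_m, structure=_STRUCT8, border_value=0)
    abuts = bool((m & ~interior).any())
    area = int(m.sum())
    air_in = int((m & air.mask).sum()) if air is not None else 0
    net = area - air_in
    implausible = (net > config.implausible_area_px) and not in_muscle_region
    return QCFlags(abuts_roi=abuts, implausibly_large=implausible)


def net_area_px(mask: np.ndarray, air: AirRegion | None) -> int:
    m = np.asarray(mask, bool)
    air_in = int((m & air.mask).sum()) if air is not None else 0
    return int(m.sum()) - air_in


def find_muscle_region(implausible_flags: Sequence[bool], n_slices: int,
                       config: RunConfig = DEFAULT_CONFIG) -> int:
    """Top (0-based, inferior->superior) of the muscle-associated region.

    The most superior over-large slice among the bottom six sets the top;
    with no such slice, the default is the second-most inferior slice
    (index 1).  Every slice at or below the returned index is treated as
    muscle-associated.
    """
    if n_slices < 2:
        raise ValueError("need at least two slices")
    flags = list(implausible_flags)
    if len(flags) != n_slices:
        raise ValueError("one flag per slice required")
    cap = min(config.muscle_cap_slices, n_slices)  # bottom six slices
    flagged = [k for k in range(cap) if flags[k]]
    if flagged:
        return max(flagged)
    return 1


def kv_fallback_contour(kv_mask: np.ndarray, kv_air_area_px: int,
                        mv_air_area_px: int) -> np.ndarray:
    """Planning contour, eroded by the gas-area excess of the planning scan.

    When the planning slice held more gas than the daily slice, the
    propagated contour is too large by roughly that area; it is eroded
    (3x3) until the area has dropped by at least the difference, without
    ever eroding to nothing.
    """
    kv = np.asarray(kv_mask, bool)
    if not kv.any():
        raise ValueError("planning mask is empty")
    deficit = kv_air_area_px - mv_air_area_px
    if deficit <= 0:
        return kv.copy()
    target = int(kv.sum()) - deficit
    out = kv.copy()
    while int(out.sum()) > max(target, 0):
        nxt = ndimage.binary_erosion(out, structure=_STRUCT8)
        if not nxt.any():
            break  # never erode to empty
        out = nxt
    return out


def flag_erroneous_slices(contours: Sequence[np.ndarray | None],
                          smoothed: PolarSurface, geometry: Geometry,
                          config: RunConfig = DEFAULT_CONFIG) -> list[bool]:
    """True per slice where JCI(contour, smoothed contour) < threshold."""
    flags: list[bool] = []
    for k, m in enumerate(contours):
        if m is None or not np.asarray(m, bool).any():
            flags.append(False)
            continue
        smooth_mask = surface_slice_mask(smoothed, k, geometry,
                                         shape=np.asarray(m).shape)
        flags.append(jaccard(m, smooth_mask) < config.jci_threshold)
    return flags
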