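"""2D Chan-Vese active contour with prior-knowledge seeding.

The segmentation minimises the piecewise-constant two-phase energy

    E(Omega) = mu * Length(dOmega) + nu * Area(Omega)
             + int_Omega (I - c1)^2 + int_{ROI \\ Omega} (I - c2)^2

over regions Omega inside a search region (ROI), where c1 and c2 are the
mean intensities inside and outside the evolving region.  A negative area
weight nu (the "contraction bias") drives expansion, which is how the
eroded planning-contour seed grows back onto the daily rectum.

Evolution is by gradient descent on a signed level set (positive inside
here).  Each step is accepted only if the sharp-interface energy does not
increase (backtracking on the step size), so the recorded energy is
non-increasing by construction; the candidate region is regularised by a
3x3 majority filter so the front advances as coherent rings, and the
level set is reinitialised to a signed distance after every accepted
step (which preserves the region, hence the logged energy).  The scheme
is fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import DEFAULT_CONFIG, RunConfig

log = logging.getLogger(__name__)

_STRUCT8 = np.ones((3, 3), bool)
_EPS_DELTA = 1.0  # half-width of the smeared delta driving the flow


@dataclass(frozen=True)
class CVParams:
    """User-facing Chan-Vese parameters.

    ``smoothing`` scales the contour-length weight (clinically tuned value
    6); ``contraction_bias`` scales the area weight (tuned value -1.0;
    negative expands).  The internal weights are
    ``mu = smoothing * mu_scale * range^2`` and
    ``nu = contraction_bias * nu_scale * range^2`` where ``range`` is the
    intensity peak-to-peak inside the ROI (1 for [0, 1] images).
    """

    smoothing: float = 6.0
    contraction_bias: float = -1.0
    max_iterations: int = 300
    convergence_fraction: float = 0.001

    def __post_init__(self) -> None:
        if self.smoothing < 0:
            raise ValueError("smoothing must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")

    @classmethod
    def from_config(cls, config: RunConfig) -> "CVParams":
        return cls(
            smoothing=config.cv_smoothing,
            contraction_bias=config.cv_contraction_bias,
            max_iterations=config.cv_max_iterations,
            convergence_fraction=config.cv_convergence_fraction,
        )


@dataclass
class CVResult:
    mask: np.ndarray
    iterations: int
    converged: bool
    energies: list[float] = field(default_factory=list)

    @property
    def final_energy(self) -> float:
        return self.energies[-1] if self.energies else float("nan")


def seed_from_planning(planning_rectum_slice_mask: np.ndarray) -> np.ndarray:
    """Erode the propagated planning contour once (3x3) to make the seed.

    Starting slightly inside lets the negative contraction bias control
    the outward growth.  A prior too thin to survive erosion is returned
    unchanged.
    """
    mask = np.asarray(planning_rectum_slice_mask, bool)
    if not mask.any():
        raise ValueError("planning rectum mask is empty")
    eroded = ndimage.binary_erosion(mask, structure=_STRUCT8)
    if not eroded.any():
        return mask.copy()
    return eroded


def optimise_seed_shift(seed: np.ndarray, intensity: np.ndarray,
                        max_shift: int = 20) -> tuple[np.ndarray, tuple[int, int]]:
    """Exhaustively shift the seed within +/-``max_shift`` px to the
    brightest placement.

    The score of a shift is the summed intensity under the shifted mask
    (the correlation of mask and image).  Ties are broken by the smallest
    shift norm, then row-major order, so the result is deterministic.
    Shifts that would push the seed outside the image are not considered.
    """
    seed = np.asarray(seed, bool)
    img = np.asarray(intensity, float)
    if not seed.any():
        raise ValueError("seed is empty")
    rows = np.nonzero(seed.any(axis=1))[0]
    cols = np.nonzero(seed.any(axis=0))[0]
    r0, r1, c0, c1 = rows.min(), rows.max(), cols.min(), cols.max()
    sub = seed[r0 : r1 + 1, c0 : c1 + 1]

    best: tuple[float, float, int, int] | None = None  # (-score, norm, dr, dc)
    best_score = -np.inf
    candidates: list[tuple[int, int]] = []
    for dr in range(-max_shift, max_shift + 1):
        if r0 + dr < 0 or r1 + dr >= img.shape[0]:
            continue
        for dc in range(-max_shift, max_shift + 1):
            if c0 + dc < 0 or c1 + dc >= img.shape[1]:
                continue
            window = img[r0 + dr : r1 + dr + 1, c0 + dc : c1 + dc + 1]
            score = float(window[sub].sum())
            if score > best_score + 1e-9:
                best_score = score
                candidates = [(dr, dc)]
            elif score >= best_score - 1e-9:
                candidates.append((dr, dc))
    if not candidates:
        return seed.copy(), (0, 0)
    candidates.sort(key=lambda s: (s[0] * s[0] + s[1] * s[1], s[0], s[1]))
    dr, dc = candidates[0]
    shifted = np.zeros_like(seed)
    shifted[r0 + dr : r1 + dr + 1, c0 + dc : c1 + dc + 1] = sub
    return shifted, (dr, dc)


def _perimeter(interior: np.ndarray) -> float:
    """Euclidean boundary length estimate (Crofton, 4 directions, pixels)."""
    from skimage.measure import perimeter_crofton

    return float(perimeter_crofton(interior, directions=4))


def _sharp_energy(interior: np.ndarray, img: np.ndarray, roi: np.ndarray,
                  mu: float, nu: float) -> float:
    """Sharp-interface Chan-Vese energy of a binary region.

    Uses optimal region means, so recomputing c1/c2 can only lower it.
    Invariant under level-set reinitialisation (depends on the region
    only), which is why it is the quantity logged per iteration.
    """
    inside = interior & roi
    outside = roi & ~interior
    e = mu * _perimeter(inside) + nu * float(inside.sum())
    if inside.any():
        c1 = float(img[inside].mean())
        e += float(((img[inside] - c1) ** 2).sum())
    if outside.any():
        c2 = float(img[outside].mean())
        e += float(((img[outside] - c2) ** 2).sum())
    return e


def _curvature(psi: np.ndarray) -> np.ndarray:
    """div(grad psi / |grad psi|) by central differences."""
    py, px = np.gradient(psi)
    norm = np.sqrt(px**2 + py**2) + 1e-8
    ny, nx = py / norm, px / norm
    div_y, _ = np.gradient(ny)
    _, div_x = np.gradient(nx)
    return div_y + div_x


def _signed_distance(interior: np.ndarray) -> np.ndarray:
    """Signed distance, positive inside, in pixels."""
    if not interior.any():
        return -np.ones(interior.shape) - ndimage.distance_transform_edt(~interior)
    if interior.all():
        return np.ones(interior.shape) + ndimage.distance_transform_edt(interior)
    return ndimage.distance_transform_edt(interior) - ndimage.distance_transform_edt(
        ~interior
    )


def chan_vese_segment(intensity: np.ndarray, seed: np.ndarray, roi: np.ndarray,
                      params: CVParams | None = None,
                      config: RunConfig = DEFAULT_CONFIG) -> CVResult:
    """Evolve the seed under the Chan-Vese energy, restricted to the ROI.

    Returns the largest connected component of the converged interior with
    holes filled (the rectal cross-section is a single hole-free region).
    Identical inputs give bit-identical results.
    """
    img = np.asarray(intensity, float)
    seed = np.asarray(seed, bool)
    roi = np.asarray(roi, bool)
    if params is None:
        params = CVParams.from_config(config)
    if not np.isfinite(img).all():
        raise ValueError("intensity contains non-finite values")
    if not seed.any():
        raise ValueError("seed is empty")
    if (seed & ~roi).any():
        raise ValueError("seed extends outside the search region")

    rng = float(np.ptp(img[roi])) if roi.any() else 0.0
    if rng <= 0:
        rng = 1.0
    mu = params.smoothing * config.cv_mu_scale * rng**2
    nu = params.contraction_bias * config.cv_nu_scale * rng**2

    # work on the ROI bounding box, padded a little
    rows = np.nonzero(roi.any(axis=1))[0]
    cols = np.nonzero(roi.any(axis=0))[0]
    pad = 2
    r0 = max(0, rows.min() - pad)
    r1 = min(roi.shape[0], rows.max() + 1 + pad)
    c0 = max(0, cols.min() - pad)
    c1 = min(roi.shape[1], cols.max() + 1 + pad)
    sub = np.s_[r0:r1, c0:c1]
    img_s, roi_s, seed_s = img[sub], roi[sub], seed[sub]

    psi = _signed_distance(seed_s)
    psi[~roi_s] = np.minimum(psi[~roi_s], -1.0)
    interior = (psi > 0) & roi_s
    energy = _sharp_energy(interior, img_s, roi_s, mu, nu)
    energies = [energy]

    dt, dt_min, dt_max = 1.0, 1e-3, 2.0
    recent_changes: list[int] = []
    n_roi = max(1, int(roi_s.sum()))
    it = 0
    converged = False
    ones3 = np.ones((3, 3))
    for it in range(1, params.max_iterations + 1):
        inside = interior
        outside = roi_s & ~interior
        c1_v = float(img_s[inside].mean()) if inside.any() else 0.0
        c2_v = float(img_s[outside].mean()) if outside.any() else c1_v
        delta = _EPS_DELTA / (np.pi * (_EPS_DELTA**2 + psi**2))
        force = delta * (
            mu * _curvature(psi) - nu - (img_s - c1_v) ** 2 + (img_s - c2_v) ** 2
        )
        force[~roi_s] = 0.0
        fmax = float(np.abs(force).max())
        if fmax > 0:
            force = force / fmax  # unit-speed front; backtracking guards energy

        accepted = False
        trial_dt = dt
        while trial_dt >= dt_min:
            cand = psi + trial_dt * force
            cand_interior = (cand > 0) & roi_s
            # regularise the flipped set (3x3 majority) so fronts advance
            # as coherent rings rather than jagged pixel sets
            counts = ndimage.convolve(cand_interior.astype(np.uint8), ones3,
                                      mode="constant")
            reg = (counts >= 5) & roi_s
            if reg.any():
                cand_interior = reg
            cand_energy = _sharp_energy(cand_interior, img_s, roi_s, mu, nu)
            if cand_energy <= energy + 1e-12:
                accepted = True
                break
            trial_dt *= 0.5
        if accepted:
            changed = int(np.count_nonzero(cand_interior != interior))
            interior, energy = cand_interior, cand_energy
            dt = min(trial_dt * 1.2, dt_max)
            # reinitialise to a signed distance of the accepted region;
            # preserves the sign pattern, hence the logged (sharp) energy
            psi = _signed_distance(interior)
            psi[~roi_s] = np.minimum(psi[~roi_s], -1.0)
        else:
            changed = 0
        energies.append(energy)

        # converged once sign flips over the last window fall below the
        # stated fraction of ROI pixels
        recent_changes.append(changed)
        if len(recent_changes) > config.cv_convergence_window:
            recent_changes.pop(0)
        if (len(recent_changes) == config.cv_convergence_window
                and sum(recent_changes) < params.convergence_fraction * n_roi):
            converged = True
            break

    out = np.zeros(roi.shape, bool)
    if interior.any():
        labels, n = ndimage.label(interior, structure=_STRUCT8)
        if n > 1:
            sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                       index=np.arange(1, n + 1))
            interior = labels == (int(np.argmax(sizes)) + 1)
        interior = ndimage.binary_fill_holes(interior)
        out[sub] = interior & roi_s
    else:
        log.warning("Chan-Vese interior vanished; returning empty mask")
    return CVResult(mask=out, iterations=it, converged=converged, energies=energies)
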