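"""Synthetic pelvic phantom: paired planning (kVCT) and daily (MVCT) scans
with known ground truth.

The phantom emulates the features the pipeline must survive on clinical
guidance imaging:

* the two grids (1.953 mm / 3 mm planning, 0.754 mm / 6 mm daily with a
  short 8-12 slice field of view containing the prostate);
* a rectal tube (wall 30-60 HU, lumen -10..30 HU) whose centre and radius
  deform from day to day within the search-region margins;
* gas pockets (-1000..-200 HU) wholly inside the lumen, locally
  distending the rectum;
* a prostate ellipsoid (40 +/- 10 HU, inside the bright transfer-function
  band) abutting the rectum anteriorly;
* spine and ischial bone (>= 700 HU) giving the posterior ROI limit;
* an inferior muscle-associated band isointense with the rectal wall and
  directly abutting it, reproducing the systematic over-contouring that
  triggers the planning-contour fallback;
* MVCT degradation: soft-tissue contrast compression and Gaussian noise;
* a per-scan couch shift whose inverse is returned as the
  setup-correction transform.

All randomness flows through explicit integer seeds; identical seeds give
bit-identical volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import RigidTransform, Volume, kvct_geometry, mvct_geometry
from .structures import StructureSet


@dataclass(frozen=True)
class PhantomParams:
    """Study-condition knobs for the synthetic cohort."""

    # grids
    n_slices_planning: int = 28
    planning_rows: int = 272
    daily_rows: int = 512
    n_slices_daily_range: tuple[int, int] = (8, 12)

    # anatomy (per-patient draws are made within these bands)
    rectum_radius_mm: tuple[float, float] = (11.0, 15.0)
    wall_thickness_mm: float = 3.5
    wall_hu: tuple[float, float] = (30.0, 60.0)
    lumen_hu: tuple[float, float] = (-10.0, 30.0)
    prostate_hu: tuple[float, float] = (40.0, 10.0)      # mean, sd
    background_hu_sd: float = 20.0
    bone_hu: float = 800.0
    muscle_hu: tuple[float, float] = (35.0, 55.0)
    muscle_outer_mm: float = 15.0
    muscle_z_top_mm: float = -18.0

    # transient adjacent bowel (daily scans only)
    bowel_prob_daily: float = 0.4
    bowel_gap_mm: tuple[float, float] = (1.0, 4.0)

    # gas pockets
    gas_hu: tuple[float, float] = (-1000.0, -200.0)
    gas_prob_daily: float = 1.0 / 3.0
    gas_prob_planning: float = 1.0 / 3.0
    gas_large_prob: float = 0.5       # of daily pockets, fraction that are large
    gas_medium_radius_mm: tuple[float, float] = (6.5, 9.5)
    gas_large_radius_mm: tuple[float, float] = (11.5, 13.0)

    # interfraction deformation (per scan)
    displacement_sd_mm: float = 4.0
    displacement_cap_mm: float = 12.0
    radius_scale_range: tuple[float, float] = (0.9, 1.15)

    # MVCT degradation
    mvct_noise_sd_hu: float = 25.0
    mvct_contrast_scale: float = 0.7

    # couch setup error
    couch_shift_sd_mm: float = 3.0
    couch_shift_cap_mm: float = 8.0
    couch_dz_sd_mm: float = 2.0
    couch_dz_cap_mm: float = 4.0
    couch_roll_sd_deg: float = 1.0
    couch_roll_cap_deg: float = 3.0

    # search-region margins the deformation must respect (mm, MVCT grid)
    margin_anterior_mm: float = 38.0
    margin_posterior_mm: float = 15.0
    margin_lateral_mm: float = 30.0

    def __post_init__(self) -> None:
        lo, hi = self.n_slices_daily_range
        if not (8 <= lo <= hi <= 12):
            raise ValueError("daily FOV must span 8-12 slices")
        if self.wall_thickness_mm <= 0 or self.rectum_radius_mm[0] <= self.wall_thickness_mm:
            raise ValueError("rectum radius must exceed wall thickness")
        if not 0 < self.mvct_contrast_scale <= 1:
            raise ValueError("contrast scale must be in (0, 1]")
        if self.mvct_noise_sd_hu < 0:
            raise ValueError("noise sd must be >= 0")


DEFAULT_PARAMS = PhantomParams()


@dataclass(frozen=True)
class GasPocket:
    z_lo: float   # mm, patient coords
    z_hi: float
    radius_mm: float


@dataclass
class PatientAnatomy:
    """Smooth analytic description of one patient, in patient mm coords."""

    rect_cx0: float
    rect_cy0: float
    rect_wiggle_amp: tuple[float, float]
    rect_wiggle_phase: tuple[float, float]
    rect_wiggle_wavelength: float
    rect_r0: float
    rect_r_amp: float
    rect_r_phase: float
    ellipticity: float
    wall_hu: float
    lumen_hu: float
    prostate_center: tuple[float, float, float]
    prostate_axes: tuple[float, float, float]
    planning_gas: list[GasPocket] = field(default_factory=list)

    def centre(self, z: float) -> tuple[float, float]:
        wx = self.rect_wiggle_amp[0] * np.sin(
            2 * np.pi * z / self.rect_wiggle_wavelength + self.rect_wiggle_phase[0])
        wy = self.rect_wiggle_amp[1] * np.sin(
            2 * np.pi * z / self.rect_wiggle_wavelength + self.rect_wiggle_phase[1])
        return self.rect_cx0 + wx, self.rect_cy0 + wy

    def radius(self, z: float) -> float:
        return self.rect_r0 + self.rect_r_amp * np.sin(
            2 * np.pi * z / (2.2 * self.rect_wiggle_wavelength) + self.rect_r_phase)


@dataclass
class PlanningCase:
    volume: Volume
    structures: StructureSet
    anatomy: PatientAnatomy
    params: PhantomParams


@dataclass
class DailyScan:
    volume: Volume
    transform: RigidTransform
    truth: StructureSet            # deformed ground truth on the daily grid
    deformation: dict


@dataclass(frozen=True)
class BowelLoop:
    """Transient bowel-like structure lateral to the rectum.

    Isointense with the rectal wall, it mimics the rectal cross-section
    and can mislead the seed placement or capture part of the contour —
    the adjacent-organ poor-contrast failure mode the 3D self-check and
    second segmentation pass exist to repair.
    """

    z_lo: float
    z_hi: float
    side: int            # +1 patient left, -1 patient right
    gap_mm: float        # clearance from the rectal wall
    radius_mm: float


@dataclass(frozen=True)
class Deformation:
    """Per-scan rigid-ish interfraction change of the rectum."""

    dx_mm: float = 0.0
    dy_mm: float = 0.0
    radius_scale: float = 1.0
    daily_gas: list[GasPocket] = field(default_factory=list)
    bowel: BowelLoop | None = None


def _draw_anatomy(params: PhantomParams, rng: np.random.Generator) -> PatientAnatomy:
    r_lo, r_hi = params.rectum_radius_mm
    pr_cy = float(rng.uniform(32.0, 44.0))
    r0 = float(rng.uniform(r_lo, r_hi))
    anatomy = PatientAnatomy(
        rect_cx0=float(rng.uniform(-4.0, 4.0)),
        rect_cy0=pr_cy,
        rect_wiggle_amp=(float(rng.uniform(1.0, 3.0)), float(rng.uniform(1.0, 3.0))),
        rect_wiggle_phase=(float(rng.uniform(0, 2 * np.pi)),
                           float(rng.uniform(0, 2 * np.pi))),
        rect_wiggle_wavelength=float(rng.uniform(90.0, 150.0)),
        rect_r0=r0,
        rect_r_amp=float(rng.uniform(0.5, 2.0)),
        rect_r_phase=float(rng.uniform(0, 2 * np.pi)),
        ellipticity=float(rng.uniform(0.9, 1.1)),
        wall_hu=float(rng.uniform(38.0, 55.0)),
        lumen_hu=float(rng.uniform(0.0, 25.0)),
        prostate_center=(0.0, 0.0, 8.0),   # y set below, anterior to the rectum
        prostate_axes=(float(rng.uniform(18.0, 24.0)),
                       float(rng.uniform(15.0, 19.0)),
                       float(rng.uniform(13.0, 17.0))),
    )
    # place the prostate just anterior (low y) of the rectum's anterior wall
    cy_at_zp = anatomy.centre(8.0)[1]
    r_at_zp = anatomy.radius(8.0)
    y_pro = cy_at_zp - r_at_zp - anatomy.prostate_axes[1] - 2.0
    anatomy.prostate_center = (anatomy.rect_cx0 * 0.5, float(y_pro), 8.0)
    if rng.uniform() < params.gas_prob_planning:
        # planning gas in the inferior rectum exercises the air-modified
        # planning-contour fallback when the daily slice has none
        z0 = float(rng.uniform(-30.0, -12.0))
        anatomy.planning_gas.append(GasPocket(
            z_lo=z0, z_hi=z0 + float(rng.uniform(8.0, 14.0)),
            radius_mm=float(rng.uniform(*params.gas_medium_radius_mm)),
        ))
    return anatomy


def _effective_rectum(anatomy: PatientAnatomy, params: PhantomParams, z: float,
                      deform: Deformation | None) -> tuple[float, float, float, GasPocket | None]:
    """Deformed centre (cx, cy) and radius at height z, plus active gas."""
    cx, cy = anatomy.centre(z)
    r = anatomy.radius(z)
    pockets = list(anatomy.planning_gas)
    if deform is not None:
        cx += deform.dx_mm
        cy += deform.dy_mm
        r *= deform.radius_scale
        pockets = list(deform.daily_gas)  # daily gas replaces planning gas
    active = None
    for p in pockets:
        if p.z_lo <= z <= p.z_hi:
            active = p
            break
    if active is not None:
        # gas distends the rectum so the pocket always fits in the lumen
        r = max(r, active.radius_mm + params.wall_thickness_mm + 1.0)
    return float(cx), float(cy), float(r), active


def _render_slice(anatomy: PatientAnatomy, params: PhantomParams, z: float,
                  X: np.ndarray, Y: np.ndarray, rng: np.random.Generator,
                  deform: Deformation | None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """HU image plus ground-truth rectum and prostate masks at height z."""
    cx, cy, r, gas = _effective_rectum(anatomy, params, z, deform)
    lumen_r = max(r - params.wall_thickness_mm, 2.0)
    d = np.hypot((X - cx) / anatomy.ellipticity, Y - cy)

    hu = rng.normal(0.0, params.background_hu_sd, X.shape)

    # inferior muscle band isointense with the rectal wall, abutting it
    if z <= params.muscle_z_top_mm:
        muscle = (d > r) & (d <= r + params.muscle_outer_mm)
        hu[muscle] = rng.uniform(*params.muscle_hu, size=int(muscle.sum()))

    rect = d <= r
    wall = rect & (d > lumen_r)
    lumen = d <= lumen_r
    hu[wall] = np.clip(rng.normal(anatomy.wall_hu, 4.0, int(wall.sum())),
                       *params.wall_hu)
    hu[lumen] = np.clip(rng.normal(anatomy.lumen_hu, 6.0, int(lumen.sum())),
                        *params.lumen_hu)
    if gas is not None:
        g = d <= min(gas.radius_mm, lumen_r - 0.5)  # same ellipticity as lumen
        hu[g] = rng.uniform(*params.gas_hu, size=int(g.sum()))

    # transient bowel loop lateral to the rectum, isointense with the wall
    if (deform is not None and deform.bowel is not None
            and deform.bowel.z_lo <= z <= deform.bowel.z_hi):
        b = deform.bowel
        bx = cx + b.side * (r + b.gap_mm + b.radius_mm)
        loop = (np.hypot(X - bx, Y - cy) <= b.radius_mm) & ~rect
        hu[loop] = np.clip(rng.normal(anatomy.wall_hu, 4.0, int(loop.sum())),
                           *params.wall_hu)

    # prostate ellipsoid (bright band 40 +/- 10 HU), never overlapping rectum
    px, py, pz = anatomy.prostate_center
    ax, ay, az = anatomy.prostate_axes
    pro = ((X - px) / ax) ** 2 + ((Y - py) / ay) ** 2 + ((z - pz) / az) ** 2 <= 1.0
    pro &= ~rect
    mean, sd = params.prostate_hu
    hu[pro] = np.clip(rng.normal(mean, sd, int(pro.sum())), 10.0, 70.0)

    # spine posterior to the rectum, ischial blocks inferolaterally
    spine = (np.abs(X) < 15.0) & (Y > cy + r + 15.0) & (Y < cy + r + 40.0)
    hu[spine] = rng.normal(params.bone_hu, 50.0, int(spine.sum()))
    if z <= params.muscle_z_top_mm + 6.0:
        isch = (np.abs(np.abs(X) - 48.0) < 8.0) & (np.abs(Y - 15.0) < 12.0)
        hu[isch] = rng.normal(params.bone_hu, 50.0, int(isch.sum()))

    return np.clip(hu, -1090.0, 3090.0), rect, pro


def generate_planning_case(params: PhantomParams = DEFAULT_PARAMS,
                           seed: int = 0) -> PlanningCase:
    """Planning kVCT covering the full rectum, with ground-truth structures."""
    rng = np.random.default_rng(seed)
    anatomy = _draw_anatomy(params, rng)
    geom = kvct_geometry(params.n_slices_planning, params.planning_rows,
                         params.planning_rows)
    rows, cols = np.meshgrid(np.arange(geom.n_rows), np.arange(geom.n_cols),
                             indexing="ij")
    X, Y = geom.world_xy(rows, cols)
    data = np.empty(geom.shape)
    rect = np.zeros(geom.shape, bool)
    pro = np.zeros(geom.shape, bool)
    for k in range(geom.n_slices):
        z = float(geom.slice_z(np.array(k)))
        data[k], rect[k], pro[k] = _render_slice(anatomy, params, z, X, Y, rng,
                                                 deform=None)
    vol = Volume(data, geom, "kVCT")
    structs = StructureSet(geom, {"rectum": rect, "prostate": pro})
    return PlanningCase(vol, structs, anatomy, params)


def _draw_deformation(params: PhantomParams, anatomy: PatientAnatomy,
                      rng: np.random.Generator) -> Deformation:
    cap = params.displacement_cap_mm
    dx = float(np.clip(rng.normal(0, params.displacement_sd_mm), -cap, cap))
    dy = float(np.clip(rng.normal(0, params.displacement_sd_mm), -cap, cap))
    scale = float(rng.uniform(*params.radius_scale_range))
    # the pipeline's prior assumes motion within the search margins
    if dy < -params.margin_anterior_mm or dy > params.margin_posterior_mm:
        raise ValueError("anterior/posterior deformation exceeds search margins")
    if abs(dx) > params.margin_lateral_mm:
        raise ValueError("lateral deformation exceeds search margins")
    gas: list[GasPocket] = []
    if rng.uniform() < params.gas_prob_daily:
        large = rng.uniform() < params.gas_large_prob
        rad = float(rng.uniform(*(params.gas_large_radius_mm if large
                                  else params.gas_medium_radius_mm)))
        z0 = float(rng.uniform(-12.0, 18.0))
        gas.append(GasPocket(z_lo=z0, z_hi=z0 + float(rng.uniform(7.0, 13.0)),
                             radius_mm=rad))
    bowel = None
    if rng.uniform() < params.bowel_prob_daily:
        z0 = float(rng.uniform(-10.0, 14.0))
        bowel = BowelLoop(
            z_lo=z0, z_hi=z0 + float(rng.uniform(8.0, 14.0)),
            side=int(rng.choice([-1, 1])),
            gap_mm=float(rng.uniform(*params.bowel_gap_mm)),
            radius_mm=float(rng.uniform(0.8, 1.1)) * anatomy.rect_r0,
        )
    return Deformation(dx_mm=dx, dy_mm=dy, radius_scale=scale, daily_gas=gas,
                       bowel=bowel)


def generate_daily_scan(planning: PlanningCase, seed: int = 0,
                        params: PhantomParams | None = None,
                        deformation: Deformation | None = None,
                        transform: RigidTransform | None = None,
                        n_slices: int | None = None,
                        fov_center_mm: float | None = None) -> DailyScan:
    """Daily MVCT over a short FOV containing the prostate.

    The rectum is deformed (centre displacement and radius scaling within
    the search margins), gas pockets may appear or vanish, soft-tissue
    contrast is compressed and Gaussian noise added, and a couch setup
    error is applied; its inverse is returned as the setup-correction
    transform, exactly as the clinical registration provides it.
    """
    params = params or planning.params
    anatomy = planning.anatomy
    rng = np.random.default_rng(seed)
    deform = deformation if deformation is not None else _draw_deformation(
        params, anatomy, rng)
    if deform.dy_mm < -params.margin_anterior_mm or deform.dy_mm > params.margin_posterior_mm \
            or abs(deform.dx_mm) > params.margin_lateral_mm:
        raise ValueError("deformation exceeds the search-region margins")

    if n_slices is None:
        n_slices = int(rng.integers(params.n_slices_daily_range[0],
                                    params.n_slices_daily_range[1] + 1))
    fov_center = (float(rng.uniform(-4.0, 4.0)) if fov_center_mm is None
                  else fov_center_mm)  # patient z of FOV centre

    if transform is None:
        # couch setup error: patient coords = R(roll) @ machine + (dx, dy, dz)
        t_dx = float(np.clip(rng.normal(0, params.couch_shift_sd_mm),
                             -params.couch_shift_cap_mm, params.couch_shift_cap_mm))
        t_dy = float(np.clip(rng.normal(0, params.couch_shift_sd_mm),
                             -params.couch_shift_cap_mm, params.couch_shift_cap_mm))
        t_dz = float(np.clip(rng.normal(0, params.couch_dz_sd_mm),
                             -params.couch_dz_cap_mm, params.couch_dz_cap_mm))
        roll = float(np.clip(rng.normal(0, params.couch_roll_sd_deg),
                             -params.couch_roll_cap_deg, params.couch_roll_cap_deg))
        transform = RigidTransform(dx=t_dx, dy=t_dy, dz=t_dz, roll_deg=roll)
    t_dz = transform.dz

    z0_patient = fov_center - (n_slices - 1) / 2.0 * 6.0
    half = (params.daily_rows - 1) / 2.0 * 0.754
    geom = mvct_geometry(n_slices, params.daily_rows, params.daily_rows,
                         origin_mm=(-half, -half, z0_patient - t_dz))

    rows, cols = np.meshgrid(np.arange(geom.n_rows), np.arange(geom.n_cols),
                             indexing="ij")
    Xm, Ym = geom.world_xy(rows, cols)          # machine coords
    Xp, Yp, _ = transform.apply(Xm, Ym, np.zeros_like(Xm))  # patient coords

    data = np.empty(geom.shape)
    rect = np.zeros(geom.shape, bool)
    pro = np.zeros(geom.shape, bool)
    cs = params.mvct_contrast_scale
    for k in range(geom.n_slices):
        z = float(geom.slice_z(np.array(k))) + t_dz   # patient z
        hu, rect[k], pro[k] = _render_slice(anatomy, params, z, Xp, Yp, rng,
                                            deform=deform)
        # degrade soft tissue only: compress contrast about 20 HU, add noise
        soft = (hu >= -130.0) & (hu < 300.0)
        hu[soft] = cs * (hu[soft] - 20.0) + 20.0
        if params.mvct_noise_sd_hu > 0:
            hu[soft] += rng.normal(0.0, params.mvct_noise_sd_hu, int(soft.sum()))
        data[k] = np.clip(hu, -1090.0, 3090.0)

    vol = Volume(data, geom, "MVCT")
    truth = StructureSet(geom, {"rectum": rect, "prostate": pro})
    return DailyScan(volume=vol, transform=transform, truth=truth,
                     deformation={
                         "dx_mm": deform.dx_mm, "dy_mm": deform.dy_mm,
                         "radius_scale": deform.radius_scale,
                         "n_gas_pockets": len(deform.daily_gas),
                         "n_slices": n_slices,
                     })


def generate_cohort(n_patients: int = 10, scans_per_patient: int = 3,
                    seed: int = 42, params: PhantomParams = DEFAULT_PARAMS):
    """Yield (patient_id, scan_id, PlanningCase, DailyScan) reproducibly.

    The default cohort (10 patients x 3 daily scans) mirrors the clinical
    validation set of 30 guidance scans from 10 patients.
    """
    ss = np.random.SeedSequence(seed)
    patient_seeds = ss.generate_state(n_patients * (scans_per_patient + 1)) % (2**31)
    i = 0
    for p in range(n_patients):
        planning = generate_planning_case(params, seed=int(patient_seeds[i]))
        i += 1
        for s in range(scans_per_patient):
            daily = generate_daily_scan(planning, seed=int(patient_seeds[i]),
                                        params=params)
            i += 1
            yield p, s, planning, daily
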