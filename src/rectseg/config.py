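"""Validated run configuration: every tunable of the pipeline in one place.

Defaults are the clinically tuned values: the HU transfer-function
breakpoints, air-region tiers, search-region expansions, spine threshold,
Chan-Vese smoothing/bias, the implausible-area cut-off and the conformity
threshold for the 3D self-check.  A serialised config plus the input files
and seed fully determines every output byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, model_validator


class RunConfig(BaseModel):
    # HU -> intensity transfer function breakpoints (HU)
    gas_hu: float = -130.0
    critical_low_hu: float = -10.0
    plateau_low_hu: float = 30.0
    plateau_high_hu: float = 60.0
    critical_high_hu: float = 100.0

    # median denoising
    median_width_px: int = 5

    # search-region expansions around the registered planning rectum (pixels)
    expand_anterior_px: int = 50
    expand_posterior_px: int = 20
    expand_left_px: int = 40
    expand_right_px: int = 40

    # spine detection (posterior ROI limit)
    spine_threshold_hu: float = 300.0
    spine_min_area_px: int = 100

    # air-region tiers (pixels) and wall margin
    air_small_max_px: int = 150
    air_medium_max_px: int = 600
    air_wall_margin_px: int = 8
    air_smooth_radius_px: int = 3

    # Chan-Vese
    cv_smoothing: float = 6.0
    cv_contraction_bias: float = -1.0
    cv_max_iterations: int = 300
    cv_convergence_fraction: float = 0.001
    cv_convergence_window: int = 10
    cv_reinit_every: int = 20
    cv_mu_scale: float = 0.05   # mu = smoothing * mu_scale * range^2
    cv_nu_scale: float = 0.1    # nu = bias * nu_scale * range^2
    seed_max_shift_px: int = 20

    # post-processing
    implausible_area_px: int = 2500
    muscle_cap_slices: int = 6
    jci_threshold: float = 0.5
    n_theta: int = 100
    fourier_harmonics: int = 5

    # cohort summaries
    min_scans_per_offset: int = 5

    @model_validator(mode="after")
    def _ordered(self) -> "RunConfig":
        bp = (self.gas_hu, self.critical_low_hu, self.plateau_low_hu,
              self.plateau_high_hu, self.critical_high_hu)
        if not all(a < b for a, b in zip(bp, bp[1:])):
            raise ValueError(f"transfer-function breakpoints must increase: {bp}")
        if self.median_width_px < 1 or self.median_width_px % 2 == 0:
            raise ValueError("median_width_px must be odd and >= 1")
        if self.cv_smoothing < 0:
            raise ValueError("cv_smoothing must be non-negative")
        if self.cv_max_iterations < 1:
            raise ValueError("cv_max_iterations must be >= 1")
        if not 0 < self.jci_threshold < 1:
            raise ValueError("jci_threshold must be in (0, 1)")
        if self.air_small_max_px >= self.air_medium_max_px:
            raise ValueError("air tiers must satisfy small < medium")
        return self

    # -- (de)serialisation -------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def digest(self) -> str:
        """Short stable hash identifying this configuration."""
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


DEFAULT_CONFIG = RunConfig()
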