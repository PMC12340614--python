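"""Validated run configuration and deterministic per-stage seeding.

A :class:`RunConfig` describes one simulated experiment end to end: the
optical medium, the probe geometry, per-modality detector parameters and
the scenario (forearm cuff occlusion or temperature-ramped microsphere
phantom). Configs round-trip losslessly through YAML. Every stochastic
stage draws from its own generator derived from the mandatory master seed
via ``numpy.random.SeedSequence(master, spawn_key=(stage_index, k))``, so
runs are reproducible stage by stage.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import numpy as np
import yaml
from pydantic import BaseModel, Field

#: fixed stage indices for seed derivation (order is part of the contract)
STAGE_INDEX = {
    "flow_program": 0,
    "dcs": 1,
    "idws": 2,
    "idws_reference": 3,
    "scos": 4,
    "scos_dark": 5,
}


def stage_rng(master_seed: int, stage: str, k: int = 0) -> np.random.Generator:
    """Generator for one named stage (and optional sub-record index ``k``)."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(STAGE_INDEX[stage], k))
    return np.random.default_rng(ss)


class MediumConfig(BaseModel):
    """Optical properties; defaults are the assumed in-vivo values."""

    mua: float = Field(0.1, gt=0, description="absorption coefficient, 1/cm")
    musp: float = Field(6.0, gt=0, description="reduced scattering, 1/cm")
    n_in: float = Field(1.33, ge=1)
    n_out: float = Field(1.0, ge=1)
    wavelength: float = Field(785.0, gt=0, description="vacuum wavelength, nm")


class DcsConfig(BaseModel):
    """Photon-counting channel parameters."""

    n_channels: int = Field(4, ge=1)
    dt: float = Field(1e-6, gt=0, description="count bin width, s")
    mean_rate: float = Field(3e5, gt=0, description="mean count rate per channel, 1/s")
    n_bins: int = Field(100_000, ge=200, description="default record length, bins")
    integration: float = Field(0.05, gt=0, description="correlator window, s")


class IdwsConfig(BaseModel):
    """Heterodyne line-scan parameters."""

    n_pixels: int = Field(64, ge=2)
    dt: float = Field(3e-6, gt=0, description="line period, s")
    record_s: float = Field(0.5, gt=0, description="default record duration, s")
    reference_level: float = Field(100.0, gt=0, description="mean reference counts")
    sample_level: float = Field(2.0, ge=0, description="mean sample counts")
    spatial_hwhm: float = Field(1.5, gt=0, description="speckle HWHM, px")
    read_sigma: float = Field(1.0, ge=0)
    fit_mode: Literal["g1sq_all", "g1_all", "g1_over_1e"] = "g1sq_all"
    n_lags: int = Field(4000, ge=10)


class ScosConfig(BaseModel):
    """CMOS speckle-camera parameters."""

    height: int = Field(128, ge=7)
    width: int = Field(128, ge=7)
    n_frames: int = Field(120, ge=1)
    n_dark: int = Field(100, ge=10)
    frame_rate: float = Field(120.0, gt=0)
    t_exp: float = Field(1e-3, gt=0)
    substeps: int = Field(512, ge=2)
    flux: float = Field(2e5, gt=0, description="photoelectrons / pixel / s")
    speckle_pixel_ratio: float = Field(2.3, gt=0)
    gain: float = Field(9.64, gt=0, description="counts / photoelectron")
    read_sigma: float = Field(2.0, ge=0)
    dark_offset: float = Field(100.0, ge=0)
    window: int = Field(7, ge=2)
    n_avg: int = Field(100, ge=2)
    beta_assumed: float = Field(0.3, gt=0, le=1)


class CuffConfig(BaseModel):
    """Forearm cuff-occlusion protocol (defaults: 1/2/2 min)."""

    baseline_s: float = Field(60.0, gt=0)
    occlusion_s: float = Field(120.0, gt=0)
    recovery_s: float = Field(120.0, gt=0)
    baseline_bfi: float = Field(1e-8, gt=0)
    occlusion_floor: float = Field(1e-9, gt=0)
    hyperemia_peak_rbfi: float = Field(2.5, gt=1)
    cardiac_freq: float = Field(1.2, gt=0)
    pi: float = Field(0.4, ge=0)
    respiration_amp: float = Field(0.0, ge=0)


class PhantomConfig(BaseModel):
    """Temperature-ramped microsphere phantom (195 nm spheres in water)."""

    t_start_c: float = 7.0
    t_end_c: float = 22.0
    n_points: int = Field(16, ge=2, description="sampled temperatures along the ramp")
    radius_m: float = Field(97.5e-9, gt=0)
    dcs_record_s: float = Field(2.0, gt=0, description="DCS record per point, s")
    idws_record_s: float = Field(0.5, gt=0)
    scos_frames: int = Field(20, ge=2)


class RunConfig(BaseModel):
    """Complete description of one simulated comparison run."""

    scenario: Literal["cuff", "phantom_ramp"]
    seed: int = Field(..., description="master seed; every stage derives from it")
    rho: float = Field(2.5, gt=0, description="source-detector separation, cm")
    medium: MediumConfig = MediumConfig()
    dcs: DcsConfig = DcsConfig()
    idws: IdwsConfig = IdwsConfig()
    scos: ScosConfig = ScosConfig()
    cuff: CuffConfig = CuffConfig()
    phantom: PhantomConfig = PhantomConfig()
    output_dir: str = "speckleflow_run"
    save_raw: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))
        return path


def phantom_defaults() -> RunConfig:
    """Phantom-ramp config with the measured phantom optical properties."""
    return RunConfig(
        scenario="phantom_ramp",
        seed=0,
        medium=MediumConfig(mua=0.104, musp=6.30),
    )
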