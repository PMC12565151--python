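"""Pipeline configuration: defaults, YAML round trip, validation.

Every constant with an established physical value is pinned here as a
default (blood ρ = 1060 kg/m³, μ = 3.71×10⁻³ Pa·s; Re_ref = 500;
Rp = 3.31×10⁷ Pa·s/m³, C = 10⁻⁹ m³/Pa, Rd_ref = 3.35×10⁸ at CO_ref = 5
L/min; inlet harmonics A1..A3, φ1, φ2; Gaussian widths σ_d, σ_s). Model
choices the underlying formulation leaves open (α/β/γ fusion coefficients,
weight floor δ, torsion guard ε, compliance β, wall modulus E, inlet mode)
are exposed and echoed into every run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "dump_config", "config_hash"]


@dataclass
class SyntheticSection:
    vessel_length_mm: float = 60.0
    vessel_radius_mm: float = 2.0
    n_axial: int = 61
    n_theta: int = 24
    stenosis_severity: float = 0.6
    stenosis_center: float = 0.5
    stenosis_width: float = 0.08
    radial_strain_amplitude: float = 0.04
    ellipticity_amplitude: float = 0.05
    bend_motion_amplitude: float = 0.5
    n_phases: int = 11
    edv_ml: float = 120.0
    esv_ml: float = 50.0
    regurgitant_volume_ml: float = 5.0
    aortic_area_mm2: float = 700.0


@dataclass
class ProfileSection:
    hr_bpm: float = 70.0
    Vd_max: float = 1.0
    Vs_max: float = 0.4
    sigma_d: float = 0.15
    sigma_s: float = 0.1
    hu_base: float = 40.0
    hu_peak: float = 440.0
    alpha_calibration: float | None = None  # None → flow-matched default
    inlet_velocity_scale_mm_s: float = 200.0


@dataclass
class FusionSection:
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    eps_torsion: float = 1e-8
    Re_ref: float = 500.0
    weight_floor: float = 1e-6


@dataclass
class FluidSection:
    rho: float = 1060.0
    mu: float = 3.71e-3


@dataclass
class BoundarySection:
    Rp: float = 3.31e7
    C: float = 1.0e-9
    Rd_ref: float = 3.35e8
    CO_ref_l_min: float = 5.0
    inlet_mode: str = "renormalized"
    f_coronary: float = 0.035
    beta_compliance: float = 0.5
    p0_mmhg: float = 80.0
    wall_modulus_pa: float = 1.0e6
    wall_thickness_mm: float = 0.5
    alpha_res: float = 1.0
    p_venous_mmhg: float = 5.0
    hyperemic_flow_factor: float = 3.0


@dataclass
class PipelineConfig:
    synthetic: SyntheticSection = field(default_factory=SyntheticSection)
    profile: ProfileSection = field(default_factory=ProfileSection)
    fusion: FusionSection = field(default_factory=FusionSection)
    fluid: FluidSection = field(default_factory=FluidSection)
    boundary: BoundarySection = field(default_factory=BoundarySection)
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        sections = {
            "synthetic": SyntheticSection,
            "profile": ProfileSection,
            "fusion": FusionSection,
            "fluid": FluidSection,
            "boundary": BoundarySection,
        }
        kwargs: dict = {}
        for key, val in d.items():
            if key in sections:
                known = {f.name for f in dataclasses.fields(sections[key])}
                unknown = set(val) - known
                if unknown:
                    raise ValueError(
                        f"unknown key(s) in config section '{key}': {sorted(unknown)}"
                    )
                kwargs[key] = sections[key](**val)
            elif key == "seed":
                kwargs["seed"] = int(val)
            else:
                raise ValueError(f"unknown config section: {key!r}")
        return cls(**kwargs)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def dump_config(path, cfg: PipelineConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def config_hash(cfg: PipelineConfig) -> str:
    """Stable short hash of the full parameter set, recorded in manifests."""
    canon = json.dumps(cfg.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
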