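"""Cardiac functional parameters from dynamic surface sequences.

LV volumes come from the divergence theorem applied to the closed endocardial
surface; stroke volume is the EDV−ESV excursion of the volume–time curve,
corrected for aortic regurgitation (estimated from diastolic aortic-root area
excess) to give the effective stroke volume and cardiac output that set the
coronary flow allocation. Aortic pressures are estimated from root-area
pulsation through the linearized Bramwell–Hill relation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import trimesh

__all__ = [
    "CardiacMetrics",
    "AorticPressureEstimate",
    "lv_volume",
    "stroke_volume",
    "regurgitant_volume",
    "regurgitant_volume_from_flow",
    "effective_output",
    "coronary_allocation",
    "bramwell_hill_pressures",
    "outlet_pressure_waveform",
]

MMHG_PER_PA = 1.0 / 133.322


@dataclass
class CardiacMetrics:
    """Summary of LV function feeding the boundary-condition stage."""

    v_lv_ml: np.ndarray  # per-phase LV volume
    edv_ml: float
    esv_ml: float
    sv_ml: float
    rv_ml: float
    sv_eff_ml: float
    hr_bpm: float
    co_eff_l_min: float
    f_coronary: float
    q_coronary_l_min: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.rv_ml <= self.sv_ml + 1e-12):
            raise ValueError("regurgitant volume must lie in [0, SV]")
        if not (0.01 <= self.f_coronary <= 0.10):
            raise ValueError("coronary fraction outside [0.01, 0.10]")


@dataclass
class AorticPressureEstimate:
    """Aortic pressures inferred from root-area pulsation."""

    p0_mmhg: float
    a0_mm2: float
    beta_compliance: float
    p_t_mmhg: np.ndarray = field(repr=False)
    p_sys_mmhg: float = 0.0
    p_dia_mmhg: float = 0.0

    def __post_init__(self) -> None:
        self.p_t_mmhg = np.asarray(self.p_t_mmhg, dtype=float)
        self.p_sys_mmhg = float(self.p_t_mmhg.max())
        self.p_dia_mmhg = float(self.p_t_mmhg.min())
        if not (self.p_sys_mmhg >= self.p_dia_mmhg > 0):
            raise ValueError("need P_sys >= P_dia > 0")


def lv_volume(mesh: trimesh.Trimesh) -> float:
    """Enclosed volume of a closed surface via the divergence theorem, in mL.

    V = (1/3) ∮ r·n dS, evaluated per triangle as (centroid·normal)·area/3.
    The mesh must be watertight and consistently outward-oriented; an open or
    inverted mesh is rejected with a defect report.
    """
    if not mesh.is_watertight:
        raise ValueError(
            f"mesh is not closed ({len(mesh.vertices)} vertices, {len(mesh.faces)} faces): "
            "every edge must be shared by exactly two faces"
        )
    centroids = mesh.triangles_center
    normals = mesh.face_normals
    areas = mesh.area_faces
    vol_mm3 = float(np.einsum("ij,ij->i", centroids, normals) @ areas) / 3.0
    if vol_mm3 <= 0:
        raise ValueError(
            f"non-positive enclosed volume ({vol_mm3:.3g} mm³): face normals appear inverted"
        )
    return vol_mm3 / 1e3


def stroke_volume(v_lv_ml) -> tuple[float, float, float]:
    """(EDV, ESV, SV) from the volume–time curve: max, min, difference."""
    v = np.asarray(v_lv_ml, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 phases")
    edv, esv = float(v.max()), float(v.min())
    return edv, esv, edv - esv


def regurgitant_volume(
    z_mm: np.ndarray, a_dia_mm2: np.ndarray, a_avc_mm2: np.ndarray
) -> float:
    """Aortic regurgitant volume from diastolic root-area excess, in mL.

    RV = ∫ (A(z, t_dia) − A(z, t_AVC)) dz over the root axis [z1, z2]
    (trapezoid rule), comparing mid-diastole against valve closure. A
    negative raw integral signals measurement noise rather than antegrade
    gain and is clamped to 0 with a warning.
    """
    z = np.asarray(z_mm, dtype=float)
    if z.size < 2:
        raise ValueError("z-grid needs at least 2 points")
    diff = np.asarray(a_dia_mm2, dtype=float) - np.asarray(a_avc_mm2, dtype=float)
    rv_mm3 = float(np.trapezoid(diff, z))
    if rv_mm3 < 0:
        warnings.warn(
            f"negative raw regurgitant integral ({rv_mm3 / 1e3:.3g} mL); clamped to 0",
            stacklevel=2,
        )
        rv_mm3 = 0.0
    return rv_mm3 / 1e3


def regurgitant_volume_from_flow(t_s: np.ndarray, q_retro_ml_s: np.ndarray) -> float:
    """Direct RV = ∫ Q_retro dt over diastole (mL) for a user-supplied
    retrograde-flow series — the flow-based definition the area surrogate
    approximates."""
    rv = float(np.trapezoid(np.asarray(q_retro_ml_s, dtype=float), np.asarray(t_s, dtype=float)))
    return max(rv, 0.0)


def effective_output(sv_ml: float, rv_ml: float, hr_bpm: float) -> tuple[float, float]:
    """Effective stroke volume SV_eff = SV − RV (mL) and CO_eff = SV_eff·HR (L/min)."""
    if not (0.0 <= rv_ml <= sv_ml):
        raise ValueError("need 0 <= RV <= SV")
    if hr_bpm <= 0:
        raise ValueError("heart rate must be positive")
    sv_eff = sv_ml - rv_ml
    return sv_eff, sv_eff * hr_bpm / 1e3


def coronary_allocation(co_eff_l_min: float, f_coronary: float = 0.035) -> float:
    """Coronary flow allocation Q_cor = CO_eff · f (L/min); f typically 3–4 % at rest."""
    if not (0.01 <= f_coronary <= 0.10):
        raise ValueError("coronary fraction must lie in [0.01, 0.10]")
    return co_eff_l_min * f_coronary


def bramwell_hill_pressures(
    a_t_mm2: np.ndarray, p0_mmhg: float, beta_compliance: float = 0.5, a0_mm2: float | None = None
) -> AorticPressureEstimate:
    """Aortic pressure waveform from root-area pulsation.

    Linearized Bramwell–Hill: ΔP/P0 = (1/β)·ΔA/A0, so
    P(t) = P0·(1 + (A(t) − A0)/(β·A0)). A0 defaults to the minimum (diastolic
    reference) area; P_sys/P_dia are the waveform extremes.
    """
    if beta_compliance <= 0:
        raise ValueError("compliance coefficient beta must be positive")
    a = np.asarray(a_t_mm2, dtype=float)
    if np.any(a <= 0):
        raise ValueError("areas must be positive")
    a0 = float(a.min()) if a0_mm2 is None else float(a0_mm2)
    p_t = p0_mmhg * (1.0 + (a - a0) / (beta_compliance * a0))
    return AorticPressureEstimate(
        p0_mmhg=p0_mmhg, a0_mm2=a0, beta_compliance=beta_compliance, p_t_mmhg=p_t
    )


def outlet_pressure_waveform(
    p_sys_mmhg: float, p_dia_mmhg: float, tau_s: float, t_s: np.ndarray
) -> np.ndarray:
    """Monotone diastolic-decay outlet pressure P(t) = P_sys·exp(−t/τ) + P_dia (mmHg)."""
    if tau_s <= 0:
        raise ValueError("time constant tau must be positive")
    t = np.asarray(t_s, dtype=float)
    return p_sys_mmhg * np.exp(-t / tau_s) + p_dia_mmhg


def metrics_from_sequences(
    lv_meshes: list[trimesh.Trimesh],
    hr_bpm: float,
    rv_ml: float = 0.0,
    f_coronary: float = 0.035,
) -> CardiacMetrics:
    """Full metric pipeline: volumes → SV → regurgitation correction → CO_eff → Q_cor."""
    v = np.array([lv_volume(m) for m in lv_meshes])
    edv, esv, sv = stroke_volume(v)
    rv = min(max(rv_ml, 0.0), sv)
    sv_eff, co_eff = effective_output(sv, rv, hr_bpm)
    q_cor = coronary_allocation(co_eff, f_coronary)
    return CardiacMetrics(
        v_lv_ml=v,
        edv_ml=edv,
        esv_ml=esv,
        sv_ml=sv,
        rv_ml=rv,
        sv_eff_ml=sv_eff,
        hr_bpm=hr_bpm,
        co_eff_l_min=co_eff,
        f_coronary=f_coronary,
        q_coronary_l_min=q_cor,
    )
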