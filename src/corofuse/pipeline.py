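"""End-to-end driver: synthetic study → fusion → metrics → boundaries → FFR.

Mirrors how the method would run on a real dynamic coronary CTA study, with
the synthetic-dynamics module standing in for the imaging-derived inputs:

1. generate the 11-phase stenosed vessel and the LV / aortic-root phantoms;
2. personalize the biphasic inlet profile with a contrast-enhancement series;
3. compute temporal fusion weights and the fused effective geometry;
4. quantify cardiac function (EDV/ESV/SV, regurgitation, CO_eff, Q_coronary,
   aortic pressures);
5. build inlet waveform and outlet Windkessel parameters;
6. solve the reduced-order network over one cycle and report FFR.

Every artifact is deterministic given (config, seed); the manifest records
the config hash, the seed and all open-choice parameter values.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .boundary import (
    InletWaveform,
    Windkessel3,
    export_boundary_config,
    scale_rd,
    windkessel2_from_geometry,
)
from .cardiac import (
    bramwell_hill_pressures,
    coronary_allocation,
    effective_output,
    lv_volume,
    regurgitant_volume,
    stroke_volume,
)
from .config import PipelineConfig, config_hash, dump_config
from .flow_profile import FlowProfileParams, contrast_ratio, personalize, velocity
from .fusion import FluidProperties, FusionConfig, compute_fusion_weights, fuse
from .io import FLOAT_FMT, write_json_report, write_mesh
from .network import (
    BranchGeometry,
    MMHG_PER_PA,
    ResistorOutlet,
    ffr_from_solution,
    segment_resistance,
    solve_network,
    time_average,
)
from .synthetic import (
    MotionParams,
    TubeParams,
    generate_aortic_root_sequence,
    generate_lv_sequence,
    generate_stenosed_vessel,
)

log = logging.getLogger(__name__)

PA_PER_MMHG = 1.0 / MMHG_PER_PA


def synthetic_hu_series(phase_fractions: np.ndarray, hu_base: float, hu_peak: float) -> np.ndarray:
    """Plausible coronary-inlet enhancement curve over the cycle.

    Smooth rise toward a plateau near peak enhancement; deterministic — the
    stand-in for a measured HU time series.
    """
    rise = 0.85 + 0.15 * np.sin(np.pi * np.clip(phase_fractions, 0, 1)) ** 2
    return hu_base + (hu_peak - hu_base) * rise


def run_pipeline(cfg: PipelineConfig, outdir, seed: int | None = None) -> dict:
    """Run the full synthetic pipeline; returns the FFR summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed if seed is None else seed
    syn, prof, bc = cfg.synthetic, cfg.profile, cfg.boundary
    fluid = FluidProperties(rho=cfg.fluid.rho, mu=cfg.fluid.mu)
    fus_cfg = FusionConfig(
        alpha=cfg.fusion.alpha,
        beta=cfg.fusion.beta,
        gamma=cfg.fusion.gamma,
        eps_torsion=cfg.fusion.eps_torsion,
        Re_ref=cfg.fusion.Re_ref,
        weight_floor=cfg.fusion.weight_floor,
    )
    log.info(
        "open-choice parameters: fusion alpha=%g beta=%g gamma=%g delta=%g eps=%g; "
        "beta_compliance=%g E=%g Pa; inlet mode=%s",
        fus_cfg.alpha, fus_cfg.beta, fus_cfg.gamma, fus_cfg.weight_floor,
        fus_cfg.eps_torsion, bc.beta_compliance, bc.wall_modulus_pa, bc.inlet_mode,
    )

    # 1. synthetic dynamic study ------------------------------------------------
    tube = TubeParams(
        length=syn.vessel_length_mm,
        radius=syn.vessel_radius_mm,
        n_axial=syn.n_axial,
        n_theta=syn.n_theta,
    )
    motion = MotionParams(
        radial_strain_amplitude=syn.radial_strain_amplitude,
        ellipticity_amplitude=syn.ellipticity_amplitude,
        bend_motion_amplitude=syn.bend_motion_amplitude,
    )
    models, s_throat = generate_stenosed_vessel(
        syn.stenosis_severity,
        tube,
        motion,
        stenosis_center=syn.stenosis_center,
        stenosis_width=syn.stenosis_width,
        n_phases=syn.n_phases,
        seed=seed,
    )
    phase_fractions = np.array([m.phase_fraction for m in models])

    # 2. personalized inlet profile --------------------------------------------
    params = FlowProfileParams(
        Vd_max=prof.Vd_max,
        Vs_max=prof.Vs_max,
        sigma_d=prof.sigma_d,
        sigma_s=prof.sigma_s,
        T=60.0 / prof.hr_bpm,
    )
    hu = synthetic_hu_series(phase_fractions, prof.hu_base, prof.hu_peak)
    ratios = contrast_ratio(hu, prof.hu_base, prof.hu_peak)
    alpha_cal = prof.alpha_calibration if prof.alpha_calibration is not None else 1.0
    profile = personalize(params, phase_fractions * params.T, ratios, alpha_cal)

    # 3. temporal fusion --------------------------------------------------------
    weights = compute_fusion_weights(
        models, profile.Vp, fus_cfg, fluid, inlet_velocity_scale=prof.inlet_velocity_scale_mm_s
    )
    fused = fuse(models, weights)

    # 4. cardiac function -------------------------------------------------------
    lv = generate_lv_sequence(syn.edv_ml, syn.esv_ml, n_phases=syn.n_phases)
    v_lv = np.array([lv_volume(m) for m in lv])
    edv, esv, sv = stroke_volume(v_lv)
    z, a_field, root_info = generate_aortic_root_sequence(
        area_systole_mm2=syn.aortic_area_mm2,
        regurgitant_volume_ml=syn.regurgitant_volume_ml,
        n_phases=syn.n_phases,
    )
    rv = regurgitant_volume(z, a_field[:, root_info["i_dia"]], a_field[:, root_info["i_avc"]])
    rv = min(rv, sv)
    sv_eff, co_eff = effective_output(sv, rv, prof.hr_bpm)
    q_cor_l_min = coronary_allocation(co_eff, bc.f_coronary)
    a_root_t = a_field.mean(axis=0)
    pressures = bramwell_hill_pressures(a_root_t, bc.p0_mmhg, bc.beta_compliance)

    # 5. boundary conditions ----------------------------------------------------
    inlet = InletWaveform(co_eff_l_min=co_eff, T=params.T, mode=bc.inlet_mode)
    rd = scale_rd(co_eff, bc.Rd_ref, bc.CO_ref_l_min)
    wk3 = Windkessel3(Rp=bc.Rp, Rd=rd, C=bc.C)
    wk2 = windkessel2_from_geometry(
        r_eff_mm=float(fused.r_eff[-1]),
        l_eff_mm=float(fused.s[-1]),
        alpha_res=bc.alpha_res,
        e_pa=bc.wall_modulus_pa,
        h_mm=bc.wall_thickness_mm,
        fluid=fluid,
    )
    export_boundary_config(
        outdir / "boundary.yaml",
        inlet,
        {"aorta": wk3, "coronary_outlet": wk2},
        fluid=fluid,
    )

    # 6. reduced-order FFR ------------------------------------------------------
    # hyperemic coronary flow through the vessel, shaped by the biphasic profile
    q_mean_m3_s = q_cor_l_min * bc.hyperemic_flow_factor * 1e-3 / 60.0
    n_t = 81
    t = np.linspace(0.0, params.T, n_t)
    shape = velocity(t, params)
    q_t = q_mean_m3_s * shape / np.trapezoid(shape, t) * params.T

    branch = BranchGeometry(s_mm=fused.s, r_eff_mm=fused.r_eff)
    # microvascular outlet resistance calibrated so the healthy vessel at this
    # flow sees the estimated mean aortic pressure (autoregulation-style closure)
    p_a_target = 0.5 * (pressures.p_sys_mmhg + pressures.p_dia_mmhg) * PA_PER_MMHG
    p_back = bc.p_venous_mmhg * PA_PER_MMHG
    r_healthy = segment_resistance(fused.s, np.full_like(fused.s, fused.r_eff.max()), fluid)
    r_out = max((p_a_target - p_back) / q_mean_m3_s - r_healthy, 1e6)
    solution = solve_network(
        [branch], {0: ResistorOutlet(R=r_out, p_back_pa=p_back)}, t, q_t, fluid=fluid
    )
    ffr = ffr_from_solution(solution, branch=0)

    # reports -------------------------------------------------------------------
    pd.DataFrame(
        {
            "s": fused.s,
            "r_eff": fused.r_eff,
            "kappa_eff": fused.kappa_eff,
            "A_ref": fused.A_ref,
        }
    ).to_csv(outdir / "effective_parameters.csv", index=False, float_format=FLOAT_FMT, lineterminator="\n")
    wdf = pd.DataFrame(
        weights.w_norm.T, columns=[f"phase_{i}" for i in range(len(models))]
    )
    wdf.insert(0, "s", weights.s)
    wdf.to_csv(outdir / "fusion_weights.csv", index=False, float_format=FLOAT_FMT, lineterminator="\n")
    write_mesh(outdir / "fused_surface.stl", fused.mesh)

    p_bar = solution.p_bar(0)
    pd.DataFrame(
        {
            "s": branch.s_mm,
            "p_bar_mmhg": p_bar * MMHG_PER_PA,
            "ffr_running": p_bar / (time_average(solution.t, solution.p_inlet)),
        }
    ).to_csv(outdir / "pressure_profile.csv", index=False, float_format=FLOAT_FMT, lineterminator="\n")

    metrics = {
        "v_lv_ml": [float(v) for v in v_lv],
        "edv_ml": edv,
        "esv_ml": esv,
        "sv_ml": sv,
        "rv_ml": rv,
        "sv_eff_ml": sv_eff,
        "hr_bpm": prof.hr_bpm,
        "co_eff_l_min": co_eff,
        "f_coronary": bc.f_coronary,
        "q_coronary_l_min": q_cor_l_min,
        "p_sys_mmhg": pressures.p_sys_mmhg,
        "p_dia_mmhg": pressures.p_dia_mmhg,
    }
    write_json_report(outdir / "cardiac_metrics.json", metrics)

    summary = {
        "ffr": ffr.ffr,
        "ffr_location_s_mm": ffr.location_s_mm,
        "p_bar_d_mmhg": ffr.p_bar_d_mmhg,
        "p_bar_a_mmhg": ffr.p_bar_a_mmhg,
        "stenosis_severity": syn.stenosis_severity,
        "stenosis_throat_s_mm": s_throat,
        "outlet_resistance_pa_s_m3": r_out,
        "windkessel3": {"Rp": wk3.Rp, "Rd": wk3.Rd, "C": wk3.C},
        "windkessel2": {"R": wk2.R, "C": wk2.C},
    }
    write_json_report(outdir / "ffr_summary.json", summary)

    manifest = {
        "package": "corofuse",
        "version": __version__,
        "seed": seed,
        "config_hash": config_hash(cfg),
        "inlet_mode": bc.inlet_mode,
        "fusion_coefficients": {
            "alpha": fus_cfg.alpha,
            "beta": fus_cfg.beta,
            "gamma": fus_cfg.gamma,
            "weight_floor": fus_cfg.weight_floor,
            "eps_torsion": fus_cfg.eps_torsion,
        },
        "n_phases": syn.n_phases,
        "n_time_samples": n_t,
    }
    write_json_report(outdir / "manifest.json", manifest)
    dump_config(outdir / "config_used.yaml", cfg)
    return summary
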