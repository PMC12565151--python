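"""Patient-specific inlet waveforms and outlet Windkessel boundary conditions.

The aortic-root inlet carries a pulsatile flow Q(t) = CO_eff·f(t) with a
two-harmonic normalized waveform; its radial velocity distribution follows
Womersley pulsatile-flow theory. The aortic outlet uses a three-element
Windkessel (characteristic impedance Rp, distal resistance Rd scaled
inversely with effective cardiac output, compliance C); coronary branch
outlets use a two-element model whose R and C derive from the fused
effective radius and length via Poiseuille resistance and thin-wall
elasticity. A complete parameter bundle can be exported for an external 3D
CFD run (OpenFOAM-dialect snippet included).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import jv

from .fusion import FluidProperties

__all__ = [
    "InletWaveform",
    "Windkessel3",
    "Windkessel2",
    "inlet_flow",
    "womersley_number",
    "womersley_profile",
    "windkessel3_solve",
    "scale_rd",
    "windkessel2_from_geometry",
    "export_boundary_config",
    "read_boundary_config",
    "RD_REF",
    "CO_REF",
]

log = logging.getLogger(__name__)

#: Reference distal resistance (Pa·s/m³) at the reference cardiac output.
RD_REF = 3.35e8
#: Reference cardiac output, L/min.
CO_REF = 5.0

L_MIN_TO_M3_S = 1e-3 / 60.0


@dataclass
class InletWaveform:
    """Two-harmonic aortic inlet flow waveform Q(t) = CO_eff · f(t).

    f(t) = A1 sin(ωt + φ1) + A2 sin(2ωt + φ2) + A3, ω = 2π/T. Because the
    sine terms integrate to zero over a cycle, the raw f has cycle mean A3;
    in the default ``renormalized`` mode f is rescaled so the cycle-mean flow
    equals CO_eff (``raw`` keeps the printed form verbatim).
    """

    co_eff_l_min: float
    T: float = 1.0  # s
    A1: float = 0.8
    A2: float = 0.3
    A3: float = 0.1
    phi1: float = np.pi / 4.0
    phi2: float = np.pi / 6.0
    mode: str = "renormalized"

    def __post_init__(self) -> None:
        if self.T <= 0 or self.co_eff_l_min <= 0:
            raise ValueError("period and cardiac output must be positive")
        if self.mode not in ("raw", "renormalized"):
            raise ValueError("mode must be 'raw' or 'renormalized'")
        if self.mode == "renormalized" and self.A3 == 0:
            raise ValueError("renormalized mode needs a nonzero mean term A3")

    @property
    def omega(self) -> float:
        return 2.0 * np.pi / self.T

    def f(self, t):
        t = np.asarray(t, dtype=float)
        w = self.omega
        out = (
            self.A1 * np.sin(w * t + self.phi1)
            + self.A2 * np.sin(2.0 * w * t + self.phi2)
            + self.A3
        )
        return float(out) if out.ndim == 0 else out


def inlet_flow(t, waveform: InletWaveform):
    """Inlet flow Q(t) in m³/s.

    Raw mode: Q = CO_eff·f(t) as printed (cycle mean A3·CO_eff). Renormalized
    mode (default): f scaled by 1/A3 so the cycle-mean flow equals CO_eff.
    Negative excursions of the waveform are reported at DEBUG level.
    """
    co_si = waveform.co_eff_l_min * L_MIN_TO_M3_S
    f = waveform.f(t)
    scale = 1.0 if waveform.mode == "raw" else 1.0 / waveform.A3
    q = co_si * scale * np.asarray(f)
    if np.any(np.asarray(q) < 0):
        log.debug("inlet waveform has negative excursions (min %.3g m³/s)", np.min(q))
    return float(q) if np.ndim(q) == 0 else q


def womersley_number(radius_mm: float, omega: float, fluid: FluidProperties | None = None) -> float:
    """α = R √(ω ρ / μ), pulsatile-to-viscous scale ratio (R in mm → SI)."""
    fluid = fluid or FluidProperties()
    if radius_mm <= 0 or omega < 0:
        raise ValueError("radius must be positive and omega non-negative")
    return radius_mm * 1e-3 * np.sqrt(omega * fluid.rho / fluid.mu)


def _womersley_shape(r_over_R: np.ndarray, alpha: float) -> np.ndarray:
    """Flow-normalized oscillatory Womersley profile shape at zero phase.

    φ(x) = [1 − J0(βx)/J0(β)] / [1 − 2J1(β)/(β J0(β))] with β = i^{3/2}α has
    unit area-average by construction (numerator and denominator are both
    O(α²) as α → 0, avoiding cancellation); its real part tends exactly to
    the parabolic Poiseuille shape 2(1 − x²)... /2 normalization handled by
    the caller's numeric renormalization.
    """
    beta = 1j ** 1.5 * alpha
    num = 1.0 - jv(0, beta * r_over_R) / jv(0, beta)
    den = 1.0 - 2.0 * jv(1, beta) / (beta * jv(0, beta))
    return np.real(num / den)


def womersley_profile(
    r_mm,
    radius_mm: float,
    q_m3_s: float,
    omega: float = 2.0 * np.pi,
    fluid: FluidProperties | None = None,
    n_harmonics: int = 1,
    mode: str = "harmonic",
) -> np.ndarray:
    """Axial velocity u(r) (m/s) carrying exactly the instantaneous flow Q.

    ``harmonic`` mode uses the oscillatory Womersley shape at the fundamental
    frequency (higher harmonics of a periodic Q should be superposed by the
    caller per harmonic); ``simplified`` uses the flat printed shape
    Q/(πR²)·(1 − J0(α r/R)/J0(α)). Either way the radial shape is
    renormalized so that 2π ∫ u r dr = Q, and the no-slip condition
    u(R) = 0 holds exactly.
    """
    fluid = fluid or FluidProperties()
    r = np.atleast_1d(np.asarray(r_mm, dtype=float))
    if np.any(r < 0) or np.any(r > radius_mm * (1 + 1e-12)):
        raise ValueError("radial positions must lie in [0, R]")
    x = np.clip(r / radius_mm, 0.0, 1.0)
    alpha = womersley_number(radius_mm, omega, fluid)
    if mode == "simplified":
        shape = 1.0 - jv(0, alpha * x) / jv(0, alpha)
    elif mode == "harmonic":
        if alpha < 1e-6:
            shape = 1.0 - x**2
        else:
            shape = _womersley_shape(x, alpha)
    else:
        raise ValueError("mode must be 'harmonic' or 'simplified'")
    shape = np.where(x >= 1.0, 0.0, shape)  # exact no-slip at the wall
    # renormalize: 2π ∫ shape(r) r dr on a fine grid
    xf = np.linspace(0.0, 1.0, 20001)
    if mode == "simplified":
        sf = 1.0 - jv(0, alpha * xf) / jv(0, alpha)
    elif alpha < 1e-6:
        sf = 1.0 - xf**2
    else:
        sf = _womersley_shape(xf, alpha)
    integral = 2.0 * np.pi * np.trapezoid(sf * xf, xf) * (radius_mm * 1e-3) ** 2
    if abs(integral) < 1e-30:
        raise ValueError("degenerate Womersley shape: cannot carry the requested flow")
    u = shape * (q_m3_s / integral)
    return u


@dataclass
class Windkessel3:
    """Three-element Windkessel for the aortic outlet.

    P(t) = Rp·Q(t) + Pd(t),  dPd/dt = (Q(t) − Pd/Rd)/C.
    """

    Rp: float = 3.31e7  # Pa·s/m³, characteristic impedance
    Rd: float = RD_REF  # Pa·s/m³, distal resistance
    C: float = 1.0e-9  # m³/Pa, arterial compliance

    def __post_init__(self) -> None:
        if min(self.Rp, self.Rd, self.C) <= 0:
            raise ValueError("Windkessel parameters must be positive")


@dataclass
class Windkessel2:
    """Two-element Windkessel for coronary branch outlets, geometry-derived."""

    R: float  # Pa·s/m³
    C: float  # m³/Pa
    r_eff_mm: float = 0.0
    L_eff_mm: float = 0.0
    alpha_res: float = 1.0
    E_pa: float = 1.0e6
    h_mm: float = 0.5

    def __post_init__(self) -> None:
        if self.R <= 0 or self.C <= 0 or self.alpha_res <= 0:
            raise ValueError("R, C and alpha_res must be positive")


def scale_rd(co_eff_l_min: float, rd_ref: float = RD_REF, co_ref_l_min: float = CO_REF) -> float:
    """Distal resistance scaled inversely with cardiac output: Rd = Rd_ref·CO_ref/CO_eff."""
    if co_eff_l_min <= 0:
        raise ValueError("effective cardiac output must be positive")
    return rd_ref * co_ref_l_min / co_eff_l_min


def windkessel2_from_geometry(
    r_eff_mm: float,
    l_eff_mm: float,
    alpha_res: float = 1.0,
    e_pa: float = 1.0e6,
    h_mm: float = 0.5,
    fluid: FluidProperties | None = None,
) -> Windkessel2:
    """Branch-outlet R and C from fused effective geometry.

    R = 8 μ L_eff / (π r_eff⁴) · α_res  (Poiseuille, scaled by the perfusion
    territory ratio α_res); C = 3 π r_eff³ L_eff / (2 E h) (thin-wall
    elasticity with modulus E and wall thickness h). Inputs in mm, outputs SI.
    """
    fluid = fluid or FluidProperties()
    if r_eff_mm <= 0 or l_eff_mm <= 0 or h_mm <= 0 or e_pa <= 0:
        raise ValueError("geometric and elastic parameters must be positive")
    r = r_eff_mm * 1e-3
    L = l_eff_mm * 1e-3
    h = h_mm * 1e-3
    R = 8.0 * fluid.mu * L / (np.pi * r**4) * alpha_res
    C = 3.0 * np.pi * r**3 * L / (2.0 * e_pa * h)
    return Windkessel2(
        R=R, C=C, r_eff_mm=r_eff_mm, L_eff_mm=l_eff_mm, alpha_res=alpha_res, E_pa=e_pa, h_mm=h_mm
    )


def windkessel3_solve(
    t_s: np.ndarray,
    q_m3_s: np.ndarray,
    wk: Windkessel3,
    cycles: int = 20,
    pd0_pa: float = 0.0,
    rtol_cycle: float = 1e-3,
) -> np.ndarray:
    """Periodic-steady-state outlet pressure P(t) for a periodic inflow.

    Integrates dPd/dt = (Q − Pd/Rd)/C with an implicit trapezoid scheme
    (unconditionally stable for this linear ODE) at Δt ≤ T/1000, repeating
    cycles until the cycle-to-cycle max |ΔP| falls below ``rtol_cycle``
    relative to the pressure scale; returns the last-cycle P(t) on ``t_s``.
    """
    t = np.asarray(t_s, dtype=float)
    q = np.asarray(q_m3_s, dtype=float)
    if t.ndim != 1 or t.shape != q.shape or len(t) < 3:
        raise ValueError("t and q must be matching 1-D arrays with >= 3 samples")
    T = t[-1] - t[0]
    n = max(len(t), 1001)
    tf = np.linspace(t[0], t[-1], n)
    qf = np.interp(tf, t, q)
    dt = tf[1] - tf[0]
    a = 1.0 / (wk.Rd * wk.C)

    pd = np.empty(n)
    pd_start = pd0_pa
    prev = None
    for _ in range(cycles):
        pd[0] = pd_start
        for k in range(n - 1):
            # implicit trapezoid: pd' = q/C - a*pd
            rhs = pd[k] + 0.5 * dt * (qf[k] / wk.C - a * pd[k] + qf[k + 1] / wk.C)
            pd[k + 1] = rhs / (1.0 + 0.5 * dt * a)
        p = wk.Rp * qf + pd
        if cycles == 1:  # open-loop transient: return the single integrated cycle
            return np.interp(t, tf, p)
        if prev is not None:
            scale = max(np.abs(p).max(), 1.0)
            if np.abs(p - prev).max() / scale < rtol_cycle:
                return np.interp(t, tf, p)
        prev = p.copy()
        pd_start = pd[-1]
    resid = np.abs(p - prev).max() / max(np.abs(p).max(), 1.0) if prev is not None else np.inf
    raise RuntimeError(
        f"Windkessel did not reach periodic steady state in {cycles} cycles "
        f"(last cycle-to-cycle residual {resid:.3g}, tolerance {rtol_cycle}); "
        f"time constant Rd*C = {wk.Rd * wk.C:.3g} s vs period {T:.3g} s"
    )


def export_boundary_config(
    path,
    inlet: InletWaveform,
    outlets: dict[str, Windkessel3 | Windkessel2],
    fluid: FluidProperties | None = None,
    outlet_names: list[str] | None = None,
    n_samples: int = 101,
) -> dict:
    """Write a solver-ready boundary-condition bundle (YAML) plus an
    OpenFOAM-dialect snippet next to it.

    ``outlet_names``, when given, is the full set of outlets the solver mesh
    expects; any name missing from ``outlets`` raises with the unmatched list.
    Returns the bundle dict (the same structure :func:`read_boundary_config`
    reloads losslessly).
    """
    import yaml

    fluid = fluid or FluidProperties()
    if outlet_names is not None:
        missing = sorted(set(outlet_names) - set(outlets))
        if missing:
            raise ValueError(f"missing outlet mapping for: {', '.join(missing)}")
    t = np.linspace(0.0, inlet.T, n_samples)
    q = inlet_flow(t, inlet)
    bundle = {
        "schema": "corofuse-boundary/1",
        "fluid": {"rho": fluid.rho, "mu": fluid.mu},
        "inlet": {
            **{k: float(v) for k, v in asdict(inlet).items() if k != "mode"},
            "mode": inlet.mode,
            "samples": {"t": t.tolist(), "Q": np.asarray(q).tolist()},
        },
        "outlets": {},
    }
    for name, wk in outlets.items():
        kind = "windkessel3" if isinstance(wk, Windkessel3) else "windkessel2"
        bundle["outlets"][name] = {"kind": kind, **{k: float(v) for k, v in asdict(wk).items()}}

    path = str(path)
    with open(path, "w") as fh:
        yaml.safe_dump(bundle, fh, sort_keys=True)
    with open(path + ".foam", "w") as fh:
        fh.write(_openfoam_snippet(bundle))
    return bundle


def read_boundary_config(path) -> dict:
    """Reload a boundary bundle written by :func:`export_boundary_config`."""
    import yaml

    with open(path) as fh:
        bundle = yaml.safe_load(fh)
    if bundle.get("schema") != "corofuse-boundary/1":
        raise ValueError(f"unrecognized boundary bundle schema: {bundle.get('schema')!r}")
    return bundle


def _openfoam_snippet(bundle: dict) -> str:
    lines = [
        "// boundary-condition snippet (OpenFOAM dialect) generated by corofuse",
        "boundaryField",
        "{",
        "    inlet",
        "    {",
        "        type            flowRateInletVelocity;",
        "        volumetricFlowRate table",
        "        (",
    ]
    samples = bundle["inlet"]["samples"]
    for ti, qi in zip(samples["t"], samples["Q"]):
        lines.append(f"            ({ti:.6g} {qi:.6g})")
    lines += ["        );", "    }"]
    for name, wk in bundle["outlets"].items():
        lines += [f"    {name}", "    {"]
        if wk["kind"] == "windkessel3":
            lines += [
                "        type            windkesselOutlet;",
                f"        Rp              {wk['Rp']:.6g};",
                f"        Rd              {wk['Rd']:.6g};",
                f"        C               {wk['C']:.6g};",
            ]
        else:
            lines += [
                "        type            windkesselOutlet;",
                f"        R               {wk['R']:.6g};",
                f"        C               {wk['C']:.6g};",
            ]
        lines.append("    }")
    lines += ["}", ""]
    return "\n".join(lines)
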