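"""Reduced-order pressure solver over the fused coronary geometry.

A quasi-static distributed-resistance network stands in for a full 3D CFD
run: each branch carries a Poiseuille resistance integrated from the fused
effective radius, R = ∫ 8μ/(π r_eff⁴) ds, augmented by a Borda–Carnot-type
expansion loss at stenoses, ΔP = Kt·(ρ/2)·(Q/A_min − Q/A_ref)². At every
time sample the branch flows satisfy junction conservation and the outlet
pressure–flow relations; time-averaging the resulting pressure field over
the cycle gives FFR = P̄_d / P̄_a at a distal evaluation point.

Inertia (Womersley effects) is neglected: FFR uses time-averaged pressures,
which at coronary scale are dominated by resistive losses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import root

from .fusion import FluidProperties

__all__ = [
    "BranchGeometry",
    "ResistorOutlet",
    "Windkessel3Outlet",
    "PressureSolution",
    "FFRResult",
    "segment_resistance",
    "stenosis_extra_loss",
    "solve_network",
    "time_average",
    "compute_ffr",
    "ffr_from_solution",
]

MMHG_PER_PA = 1.0 / 133.322
KT_DEFAULT = 1.52  # empirical expansion-loss coefficient


@dataclass
class BranchGeometry:
    """One unbranched vessel segment of the network.

    ``s_mm``/``r_eff_mm`` sample the fused effective radius along the branch;
    ``parent`` is the index of the upstream branch (−1 for the root).
    """

    s_mm: np.ndarray
    r_eff_mm: np.ndarray
    parent: int = -1

    def __post_init__(self) -> None:
        self.s_mm = np.asarray(self.s_mm, dtype=float)
        self.r_eff_mm = np.asarray(self.r_eff_mm, dtype=float)
        if np.any(self.r_eff_mm <= 0):
            raise ValueError("effective radius must be positive along the branch")
        if len(self.s_mm) < 2 or np.any(np.diff(self.s_mm) <= 0):
            raise ValueError("s must be strictly increasing with >= 2 samples")

    @property
    def area_mm2(self) -> np.ndarray:
        return np.pi * self.r_eff_mm**2


@dataclass
class ResistorOutlet:
    """Outlet closed by a lumped resistance to a back pressure (2-element
    Windkessel in the quasi-static limit, where compliance carries no mean flow)."""

    R: float  # Pa·s/m³
    p_back_pa: float = 0.0


@dataclass
class Windkessel3Outlet:
    """Aortic-type outlet: P = Rp·Q + Pd with dPd/dt = (Q − Pd/Rd)/C."""

    Rp: float
    Rd: float
    C: float
    p_back_pa: float = 0.0
    pd_state: float = field(default=0.0, repr=False)


@dataclass
class PressureSolution:
    """Pressure and flow fields of a network solve."""

    t: np.ndarray  # s, final cycle
    branches: list[BranchGeometry]
    P: list[np.ndarray]  # per branch: (n_s, n_t) Pa
    Q: np.ndarray  # (n_branch, n_t) m³/s
    p_inlet: np.ndarray  # (n_t,) Pa

    def p_bar(self, branch: int) -> np.ndarray:
        """Time-averaged pressure along one branch, Pa."""
        return time_average(self.t, self.P[branch])


@dataclass
class FFRResult:
    """Fractional flow reserve at a distal evaluation point."""

    ffr: float
    location_s_mm: float
    p_bar_d_mmhg: float
    p_bar_a_mmhg: float

    def __post_init__(self) -> None:
        if not (0.0 < self.ffr <= 1.0 + 1e-6):
            raise ValueError(f"FFR {self.ffr:.4f} outside the physiological (0, 1] band")


def segment_resistance(
    s_mm: np.ndarray, r_eff_mm: np.ndarray, fluid: FluidProperties | None = None
) -> float:
    """Poiseuille resistance R = ∫ 8μ/(π r_eff(s)⁴) ds (SI, inputs in mm).

    Composite trapezoid on the given s-grid.
    """
    fluid = fluid or FluidProperties()
    s = np.asarray(s_mm, dtype=float) * 1e-3
    r = np.asarray(r_eff_mm, dtype=float) * 1e-3
    if np.any(r <= 0):
        raise ValueError("radius must be positive over the interval")
    return float(np.trapezoid(8.0 * fluid.mu / (np.pi * r**4), s))


def _cumulative_resistance(branch: BranchGeometry, fluid: FluidProperties) -> np.ndarray:
    s = branch.s_mm * 1e-3
    r = branch.r_eff_mm * 1e-3
    integrand = 8.0 * fluid.mu / (np.pi * r**4)
    out = np.concatenate([[0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * np.diff(s))])
    return out


def stenosis_extra_loss(
    a_min_mm2: float,
    a_ref_mm2: float,
    q_m3_s: float,
    fluid: FluidProperties | None = None,
    kt: float = KT_DEFAULT,
) -> float:
    """Expansion pressure loss ΔP = Kt·(ρ/2)·(Q/A_min − Q/A_ref)² in Pa.

    Zero when A_min = A_ref or Q = 0. Signed with the flow direction.
    """
    fluid = fluid or FluidProperties()
    if not (0.0 < a_min_mm2 <= a_ref_mm2):
        raise ValueError("need 0 < A_min <= A_ref")
    dv = abs(q_m3_s) * (1.0 / (a_min_mm2 * 1e-6) - 1.0 / (a_ref_mm2 * 1e-6))
    return kt * 0.5 * fluid.rho * dv**2


@dataclass
class _BranchLoss:
    R: float
    cum_R: np.ndarray
    i_throat: int | None
    a_min: float
    a_ref: float

    def dp(self, q: float, fluid: FluidProperties, kt: float) -> float:
        dp = self.R * q
        if self.i_throat is not None:
            dp += np.sign(q) * stenosis_extra_loss(self.a_min, self.a_ref, q, fluid, kt)
        return dp


def _prepare_losses(
    branches: list[BranchGeometry], fluid: FluidProperties, stenosis_threshold: float = 0.95
) -> list[_BranchLoss]:
    losses = []
    for b in branches:
        area = b.area_mm2
        i_min = int(np.argmin(area))
        a_min = float(area[i_min])
        a_ref = float(area[: i_min + 1].max())
        throat = i_min if a_min < stenosis_threshold * a_ref else None
        losses.append(
            _BranchLoss(
                R=segment_resistance(b.s_mm, b.r_eff_mm, fluid),
                cum_R=_cumulative_resistance(b, fluid),
                i_throat=throat,
                a_min=a_min,
                a_ref=a_ref,
            )
        )
    return losses


def solve_network(
    branches: list[BranchGeometry],
    outlets: dict[int, ResistorOutlet | Windkessel3Outlet],
    t_s: np.ndarray,
    q_inlet_m3_s: np.ndarray,
    fluid: FluidProperties | None = None,
    kt: float = KT_DEFAULT,
    cycles: int = 10,
    rtol_cycle: float = 1e-3,
) -> PressureSolution:
    """Quasi-static network solve for a branching tree with prescribed inflow.

    At each time sample the leaf flows (and the inlet pressure) solve the
    nonlinear system: flow conservation at every junction plus
    pressure-consistency along every root-to-leaf path, with branch losses
    from Poiseuille resistance and stenotic expansion and outlet pressures
    from the attached lumped models. Windkessel states are advanced with an
    implicit step between samples; cycles repeat until the inlet pressure is
    cycle-periodic to ``rtol_cycle``.
    """
    fluid = fluid or FluidProperties()
    t = np.asarray(t_s, dtype=float)
    q_in = np.asarray(q_inlet_m3_s, dtype=float)
    if t.shape != q_in.shape or t.ndim != 1 or len(t) < 2:
        raise ValueError("t and inlet flow must be matching 1-D arrays")
    n_b = len(branches)
    leaves = [i for i in range(n_b) if not any(b.parent == i for b in branches)]
    missing = sorted(set(leaves) - set(outlets))
    if missing:
        raise ValueError(f"every leaf needs an outlet model; missing: {missing}")
    parent = [b.parent for b in branches]
    root_ids = [i for i, p in enumerate(parent) if p == -1]
    if len(root_ids) != 1:
        raise ValueError("network must have exactly one root branch")
    root_branch = root_ids[0]
    losses = _prepare_losses(branches, fluid)

    # leaves under each branch, and root-to-leaf branch paths
    def leaves_under(i: int) -> list[int]:
        kids = [j for j, p in enumerate(parent) if p == i]
        if not kids:
            return [i]
        out = []
        for k in kids:
            out.extend(leaves_under(k))
        return out

    under = {i: leaves_under(i) for i in range(n_b)}
    paths = {}
    for leaf in leaves:
        path, j = [], leaf
        while j != -1:
            path.append(j)
            j = parent[j]
        paths[leaf] = path[::-1]

    n_t = len(t)
    n_l = len(leaves)
    leaf_pos = {leaf: k for k, leaf in enumerate(leaves)}

    def branch_flows(q_leaf: np.ndarray) -> np.ndarray:
        qb = np.zeros(n_b)
        for i in range(n_b):
            qb[i] = sum(q_leaf[leaf_pos[l]] for l in under[i])
        return qb

    def outlet_pressure(leaf: int, q: float) -> float:
        om = outlets[leaf]
        if isinstance(om, Windkessel3Outlet):
            return om.Rp * q + om.pd_state + om.p_back_pa
        return om.R * q + om.p_back_pa

    q_store = np.zeros((n_b, n_t))
    p_in_store = np.zeros(n_t)
    prev_p_in = None
    q_leaf_guess = None

    for _cycle in range(cycles):
        for k in range(n_t):
            qk = q_in[k]
            if q_leaf_guess is None:
                q_leaf_guess = np.full(n_l, qk / max(n_l, 1))

            def residual(x):
                q_leaf, p_in = x[:n_l], x[n_l]
                qb = branch_flows(q_leaf)
                res = np.empty(n_l + 1)
                for idx, leaf in enumerate(leaves):
                    drop = sum(losses[j].dp(qb[j], fluid, kt) for j in paths[leaf])
                    res[idx] = p_in - drop - outlet_pressure(leaf, q_leaf[idx])
                res[n_l] = q_leaf.sum() - qk
                return res

            p_in_guess = outlet_pressure(leaves[0], q_leaf_guess[0]) + sum(
                losses[j].R * qk for j in paths[leaves[0]]
            )
            sol = root(residual, np.concatenate([q_leaf_guess, [p_in_guess]]), method="hybr")
            if not sol.success or np.abs(sol.fun).max() > 1e-6 * max(abs(p_in_guess), 1.0):
                raise RuntimeError(
                    f"network solve failed at t={t[k]:.4g}s: {sol.message}; "
                    f"residual max {np.abs(sol.fun).max():.3g}"
                )
            q_leaf = sol.x[:n_l]
            q_leaf_guess = q_leaf.copy()
            p_in_store[k] = sol.x[n_l]
            q_store[:, k] = branch_flows(q_leaf)

            # advance Windkessel states (implicit Euler over the sample interval)
            if k < n_t - 1:
                dt = t[k + 1] - t[k]
                for leaf in leaves:
                    om = outlets[leaf]
                    if isinstance(om, Windkessel3Outlet):
                        q = q_leaf[leaf_pos[leaf]]
                        om.pd_state = (om.pd_state + dt * q / om.C) / (1.0 + dt / (om.Rd * om.C))

        has_state = any(isinstance(o, Windkessel3Outlet) for o in outlets.values())
        if prev_p_in is not None or not has_state:
            if prev_p_in is not None:
                scale = max(np.abs(p_in_store).max(), 1.0)
                if np.abs(p_in_store - prev_p_in).max() / scale < rtol_cycle:
                    break
            if not has_state:
                break
        prev_p_in = p_in_store.copy()
    else:
        raise RuntimeError(
            f"network solve not cycle-periodic after {cycles} cycles "
            f"(residual {np.abs(p_in_store - prev_p_in).max():.3g} Pa)"
        )

    # assemble P(s, t) per branch
    P = []
    for i, b in enumerate(branches):
        p_field = np.zeros((len(b.s_mm), n_t))
        P.append(p_field)
    for k in range(n_t):
        # branch inlet pressures top-down
        p_entry = {root_branch: p_in_store[k]}
        done = [root_branch]  # fill branch entry pressures top-down from the root
        while len(done) < n_b:
            for i in range(n_b):
                if i not in done and parent[i] in done:
                    qp = q_store[parent[i], k]
                    p_entry[i] = p_entry[parent[i]] - losses[parent[i]].dp(qp, fluid, kt)
                    done.append(i)
        for i, b in enumerate(branches):
            q = q_store[i, k]
            p_field = p_entry[i] - losses[i].cum_R * q
            if losses[i].i_throat is not None:
                step = np.sign(q) * stenosis_extra_loss(
                    losses[i].a_min, losses[i].a_ref, q, fluid, kt
                )
                p_field = p_field - step * (np.arange(len(b.s_mm)) >= losses[i].i_throat)
            P[i][:, k] = p_field
    return PressureSolution(t=t, branches=list(branches), P=P, Q=q_store, p_inlet=p_in_store)


def time_average(t_s: np.ndarray, p: np.ndarray) -> np.ndarray | float:
    """Cycle-averaged value P̄ = (1/T) ∫ P dt (trapezoid; last axis is time)."""
    t = np.asarray(t_s, dtype=float)
    T = t[-1] - t[0]
    if T <= 0:
        raise ValueError("time grid must span a positive interval")
    out = np.trapezoid(np.asarray(p, dtype=float), t, axis=-1) / T
    return float(out) if np.ndim(out) == 0 else out


def compute_ffr(p_bar_d_mmhg: float, p_bar_a_mmhg: float, location_s_mm: float = np.nan) -> FFRResult:
    """FFR = P̄_d / P̄_a from time-averaged distal and aortic pressures (mmHg)."""
    if p_bar_d_mmhg <= 0 or p_bar_a_mmhg <= 0:
        raise ValueError("time-averaged pressures must be positive")
    return FFRResult(
        ffr=p_bar_d_mmhg / p_bar_a_mmhg,
        location_s_mm=location_s_mm,
        p_bar_d_mmhg=p_bar_d_mmhg,
        p_bar_a_mmhg=p_bar_a_mmhg,
    )


def ffr_from_solution(
    solution: PressureSolution, branch: int = 0, location_s_mm: float | None = None
) -> FFRResult:
    """FFR along one branch of a solved network.

    P̄_a is the time-averaged inlet (aortic-side) pressure; P̄_d is sampled at
    ``location_s_mm``, defaulting to one local diameter beyond the
    minimal-area point of the branch.
    """
    b = solution.branches[branch]
    if location_s_mm is None:
        i_min = int(np.argmin(b.r_eff_mm))
        location_s_mm = float(
            min(b.s_mm[i_min] + 2.0 * b.r_eff_mm[i_min], b.s_mm[-1])
        )
    p_bar = solution.p_bar(branch)
    p_d = float(np.interp(location_s_mm, b.s_mm, p_bar))
    p_a = float(time_average(solution.t, solution.p_inlet))
    return compute_ffr(p_d * MMHG_PER_PA, p_a * MMHG_PER_PA, location_s_mm)
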