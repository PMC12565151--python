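"""Synthetic multi-phase coronary and cardiac geometry.

Emulates the inputs a dynamic (ECG-gated, 11-frame) coronary CTA study would
provide, so that every downstream stage — temporal fusion, cardiac metrics,
boundary conditions, the reduced pressure solver — is testable end to end:

* tubular vessel meshes with elliptical cross-sections deforming periodically
  under a prescribed radial strain ε_r(t), |ε_r| ≤ 5 %, with exact sectional
  volume conservation π a(t) b(t) = A0 (1 + ε_r(t));
* optional Gaussian stenosis of stated fractional area severity;
* bounded biharmonic skinning weights and linear blend skinning (LBS) for
  mesh deformation driven by rigid per-segment transforms;
* left-ventricular surface sequences with known EDV/ESV and aortic-root area
  sequences with known regurgitant volume.

All phases of one sequence share vertex count and face connectivity, and all
randomness flows through one explicit seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import trimesh

from .geometry import MAX_RADIAL_STRAIN, Centerline, CrossSection, arc_length_parametrize, frenet_curvature_torsion

__all__ = [
    "TubeParams",
    "MotionParams",
    "PhaseModel",
    "SkinningWeights",
    "solve_skinning_weights",
    "anchors_from_segment_midpoints",
    "lbs_deform",
    "generate_phase_sequence",
    "generate_stenosed_vessel",
    "generate_lv_sequence",
    "generate_aortic_root_sequence",
]

N_PHASES_DEFAULT = 11  # frames at 0, 10, ..., 100 % of the R-R interval


@dataclass
class TubeParams:
    """Static geometry of a synthetic vessel.

    radius may be modulated along the axis by ``radius_profile`` (callable of
    arc fraction in [0, 1] returning a multiplicative factor).
    """

    length: float = 60.0  # mm
    radius: float = 2.0  # mm
    n_axial: int = 61
    n_theta: int = 24
    bend_amplitude: float = 0.0  # mm, lateral sinusoidal bow of the centerline
    radius_profile: object | None = None
    noise_amplitude: float = 0.0  # mm, smooth random radius modulation (seeded)


@dataclass
class MotionParams:
    """Periodic deformation over the cardiac cycle.

    ``radial_strain_amplitude`` is the peak |ε_r(t)| (≤ 0.05);
    ``ellipticity_amplitude`` modulates the a/b aspect without changing area;
    ``bend_motion_amplitude`` adds a periodic lateral translation of the
    centerline (rigid-like bulk motion).
    """

    radial_strain_amplitude: float = 0.04
    ellipticity_amplitude: float = 0.05
    bend_motion_amplitude: float = 0.5  # mm


@dataclass
class PhaseModel:
    """One cardiac phase: wall mesh + centerline + per-point cross-sections."""

    phase_index: int
    phase_fraction: float
    mesh: trimesh.Trimesh
    centerline: Centerline
    cross_sections: list[CrossSection]


@dataclass
class SkinningWeights:
    """Vertex × segment bounded biharmonic weight matrix.

    Rows sum to 1 (partition of unity) and all entries are non-negative, so
    LBS blending is convex and reproduces any single global rigid motion.
    """

    W: np.ndarray
    segments: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if np.any(self.W < -1e-12):
            raise ValueError("weights must be non-negative")
        row = self.W.sum(axis=1)
        if np.any(np.abs(row - 1.0) > 1e-9):
            raise ValueError("each row must sum to 1")


# ---------------------------------------------------------------------------
# tube construction


def _parallel_transport_frames(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-minimizing normal/binormal frames along a polyline."""
    tangents = np.gradient(points, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    e1 = np.zeros_like(points)
    e2 = np.zeros_like(points)
    # initial normal: any vector not parallel to t0
    t0 = tangents[0]
    ref = np.array([1.0, 0.0, 0.0]) if abs(t0[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1[0] = np.cross(t0, ref)
    e1[0] /= np.linalg.norm(e1[0])
    e2[0] = np.cross(t0, e1[0])
    for i in range(1, len(points)):
        t_prev, t_cur = tangents[i - 1], tangents[i]
        axis = np.cross(t_prev, t_cur)
        n = np.linalg.norm(axis)
        if n < 1e-12:
            e1[i] = e1[i - 1]
        else:
            axis /= n
            ang = np.arctan2(n, np.dot(t_prev, t_cur))
            e1[i] = _rotate(e1[i - 1], axis, ang)
        e1[i] -= np.dot(e1[i], t_cur) * t_cur
        e1[i] /= np.linalg.norm(e1[i])
        e2[i] = np.cross(t_cur, e1[i])
    return e1, e2


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


def _tube_faces(n_axial: int, n_theta: int) -> np.ndarray:
    faces = []
    for i in range(n_axial - 1):
        for k in range(n_theta):
            a = i * n_theta + k
            b = i * n_theta + (k + 1) % n_theta
            c = (i + 1) * n_theta + k
            d = (i + 1) * n_theta + (k + 1) % n_theta
            faces.append([a, b, d])
            faces.append([a, d, c])
    return np.asarray(faces, dtype=np.int64)


def _base_radius_profile(params: TubeParams, frac: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    r = np.full_like(frac, params.radius)
    if params.radius_profile is not None:
        r = r * np.asarray([params.radius_profile(f) for f in frac], dtype=float)
    if params.noise_amplitude > 0:
        # smooth random modulation: low-order Fourier series with seeded coefficients
        coeffs = rng.normal(0.0, 1.0, size=3)
        wave = sum(c * np.sin((k + 1) * np.pi * frac) for k, c in enumerate(coeffs))
        wave /= max(np.abs(wave).max(), 1e-12)
        r = r + params.noise_amplitude * wave
    if np.any(r <= 0):
        raise ValueError("radius profile produced non-positive radii")
    return r


def _build_phase(
    params: TubeParams,
    base_radius: np.ndarray,
    frac: np.ndarray,
    eps_r: float,
    ellipticity: float,
    lateral_shift: float,
) -> PhaseModel:
    n_ax, n_th = params.n_axial, params.n_theta
    z = frac * params.length
    x = params.bend_amplitude * np.sin(np.pi * frac) + lateral_shift * np.sin(np.pi * frac)
    pts = np.column_stack([x, np.zeros_like(z), z])
    e1, e2 = _parallel_transport_frames(pts)

    scale = np.sqrt(1.0 + eps_r)
    ell = np.sqrt(1.0 + ellipticity)
    theta = np.linspace(0.0, 2.0 * np.pi, n_th, endpoint=False)
    sections, verts = [], np.empty((n_ax * n_th, 3))
    radii = np.empty(n_ax)
    areas = np.empty(n_ax)
    for i in range(n_ax):
        a = base_radius[i] * scale * ell
        b = base_radius[i] * scale / ell
        A0 = np.pi * base_radius[i] ** 2
        sections.append(CrossSection(a=a, b=b, A0=A0, eps_r=eps_r))
        ring = (
            pts[i]
            + np.outer(a * np.cos(theta), e1[i])
            + np.outer(b * np.sin(theta), e2[i])
        )
        verts[i * n_th : (i + 1) * n_th] = ring
        radii[i] = np.sqrt(a * b)  # circular-equivalent radius
        areas[i] = np.pi * a * b

    mesh = trimesh.Trimesh(vertices=verts, faces=_tube_faces(n_ax, n_th), process=False)
    cl = arc_length_parametrize(pts)
    cl.radius, cl.area = radii, areas
    frenet_curvature_torsion(cl)
    return PhaseModel(
        phase_index=0, phase_fraction=0.0, mesh=mesh, centerline=cl, cross_sections=sections
    )


def generate_phase_sequence(
    tube: TubeParams | None = None,
    motion: MotionParams | None = None,
    n_phases: int = N_PHASES_DEFAULT,
    seed: int = 0,
) -> list[PhaseModel]:
    """Generate an ``n_phases``-frame periodic vessel sequence.

    Phases sit at fractions 0, 1/(n-1), ..., 1 of the cardiac cycle; the
    deformation is sinusoidal in the phase fraction, so the last frame
    reproduces the first (periodicity) while both are retained because the
    fusion sums run over all frames. Deterministic given ``seed``.
    """
    tube = tube or TubeParams()
    motion = motion or MotionParams()
    if motion.radial_strain_amplitude > MAX_RADIAL_STRAIN + 1e-12:
        raise ValueError(
            f"radial strain amplitude {motion.radial_strain_amplitude} exceeds "
            f"physiological bound {MAX_RADIAL_STRAIN}"
        )
    rng = np.random.default_rng(seed)
    frac_axial = np.linspace(0.0, 1.0, tube.n_axial)
    base_radius = _base_radius_profile(tube, frac_axial, rng)

    models = []
    for i in range(n_phases):
        tf = i / (n_phases - 1)
        eps_r = motion.radial_strain_amplitude * np.sin(2.0 * np.pi * tf)
        ellip = motion.ellipticity_amplitude * np.sin(2.0 * np.pi * tf)
        shift = motion.bend_motion_amplitude * (1.0 - np.cos(2.0 * np.pi * tf)) / 2.0
        pm = _build_phase(tube, base_radius, frac_axial, eps_r, ellip, shift)
        pm.phase_index, pm.phase_fraction = i, tf
        models.append(pm)
    return models


def generate_stenosed_vessel(
    severity: float,
    tube: TubeParams | None = None,
    motion: MotionParams | None = None,
    stenosis_center: float = 0.5,
    stenosis_width: float = 0.08,
    n_phases: int = N_PHASES_DEFAULT,
    seed: int = 0,
) -> tuple[list[PhaseModel], float]:
    """Vessel sequence with a Gaussian narrowing of stated area severity.

    ``severity`` is the fractional area reduction at the throat: the minimum
    cross-sectional area equals ``(1 - severity)`` times the reference area.
    Returns ``(models, s_min)`` where ``s_min`` is the arc position (mm) of
    the minimal-area section at phase 0.
    """
    if not (0.0 <= severity <= 0.95):
        raise ValueError("severity must lie in [0, 0.95]")
    tube = tube or TubeParams()

    def profile(f: float) -> float:
        g = np.exp(-((f - stenosis_center) ** 2) / (2.0 * stenosis_width**2))
        return float(np.sqrt(1.0 - severity * g))

    tube = TubeParams(
        length=tube.length,
        radius=tube.radius,
        n_axial=tube.n_axial,
        n_theta=tube.n_theta,
        bend_amplitude=tube.bend_amplitude,
        radius_profile=profile,
        noise_amplitude=tube.noise_amplitude,
    )
    models = generate_phase_sequence(tube, motion, n_phases=n_phases, seed=seed)
    areas = models[0].centerline.area
    s_min = float(models[0].centerline.s[int(np.argmin(areas))])
    return models, s_min


# ---------------------------------------------------------------------------
# biharmonic skinning


def _cotangent_laplacian(mesh: trimesh.Trimesh) -> tuple[sp.csr_matrix, sp.dia_matrix]:
    """Symmetric cotangent stiffness L and lumped barycentric mass M."""
    v, f = mesh.vertices, mesh.faces
    n = len(v)
    rows, cols, vals = [], [], []
    for c in range(3):
        i, j, k = f[:, c], f[:, (c + 1) % 3], f[:, (c + 2) % 3]
        e1 = v[j] - v[i]
        e2 = v[k] - v[i]
        # cot of angle at i contributes to edge (j, k)
        cross = np.linalg.norm(np.cross(e1, e2), axis=1)
        cot = np.einsum("ij,ij->i", e1, e2) / np.maximum(cross, 1e-300)
        rows.extend([j, k])
        cols.extend([k, j])
        vals.extend([0.5 * cot, 0.5 * cot])
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    W = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    L = sp.diags(np.asarray(W.sum(axis=1)).ravel()) - W

    face_area = mesh.area_faces
    mass = np.zeros(n)
    np.add.at(mass, f.ravel(), np.repeat(face_area / 3.0, 3))
    M = sp.diags(np.maximum(mass, 1e-12))
    return L.tocsr(), M


def solve_skinning_weights(
    mesh: trimesh.Trimesh,
    segments: list[tuple[int, int]],
    anchors: dict[int, int] | None = None,
) -> SkinningWeights:
    """Bounded biharmonic skinning weights for centerline segments.

    Minimizes the biharmonic energy tr(WᵀKW), K = L M⁻¹ L with L the
    area-normalized cotangent Laplacian of the wall mesh, subject to anchor
    constraints fixing each anchored vertex to weight 1 for its own segment
    and 0 for all others. Negative intermediate values are clamped to 0 and
    rows renormalized to sum to 1, keeping the LBS blend convex.

    Parameters
    ----------
    segments : list of (start, end) centerline-point index ranges; one weight
        column per segment.
    anchors : vertex index → segment index. When omitted, the ring of mesh
        vertices nearest each segment midpoint is anchored to that segment.
    """
    if len(segments) == 0:
        raise ValueError("need at least one segment")
    n_seg = len(segments)
    n_v = len(mesh.vertices)

    if anchors is None:
        raise ValueError("anchor constraints are required (vertex index -> segment)")
    seg_of = dict(anchors)
    anchored_segments = set(seg_of.values())
    missing = [j for j in range(n_seg) if j not in anchored_segments]
    if missing:
        raise ValueError(
            f"singular constraint system: segment(s) {missing} have no anchor vertices"
        )

    if n_seg == 1:
        return SkinningWeights(W=np.ones((n_v, 1)), segments=list(segments))

    L, M = _cotangent_laplacian(mesh)
    Minv = sp.diags(1.0 / M.diagonal())
    K = (L @ Minv @ L).tocsc()

    fixed = np.array(sorted(seg_of), dtype=int)
    free = np.setdiff1d(np.arange(n_v), fixed)
    W = np.zeros((n_v, n_seg))
    D = np.zeros((len(fixed), n_seg))
    for row, vi in enumerate(fixed):
        D[row, seg_of[vi]] = 1.0
    W[fixed] = D

    K_ff = K[np.ix_(free, free)]
    K_fc = K[np.ix_(free, fixed)]
    rhs = -np.asarray(K_fc @ D)
    lu = spla.splu(K_ff.tocsc())
    W[free] = lu.solve(rhs)

    W = np.clip(W, 0.0, None)
    row_sum = W.sum(axis=1)
    if np.any(row_sum <= 0):
        raise ValueError("some vertices received no positive weight")
    W /= row_sum[:, None]
    return SkinningWeights(W=W, segments=list(segments))


def anchors_from_segment_midpoints(
    mesh: trimesh.Trimesh, centerline: Centerline, segments: list[tuple[int, int]]
) -> dict[int, int]:
    """Default anchor rule: vertices nearest each segment's midpoint.

    For each segment the 5 % of mesh vertices closest to the segment midpoint
    (at least one ring's worth) are constrained to that segment.
    """
    n_anchor = max(8, len(mesh.vertices) // (20 * len(segments)))
    anchors: dict[int, int] = {}
    for j, (i0, i1) in enumerate(segments):
        mid = centerline.points[(i0 + i1) // 2]
        d = np.linalg.norm(mesh.vertices - mid, axis=1)
        for vi in np.argsort(d)[:n_anchor]:
            anchors[int(vi)] = j
    return anchors


def lbs_deform(
    mesh: trimesh.Trimesh, weights: SkinningWeights, transforms: np.ndarray
) -> trimesh.Trimesh:
    """Linear blend skinning: v'_i = Σ_j w_ij (R_j v_i + t_j).

    ``transforms`` is an (n_segments, 4, 4) array of rigid homogeneous
    transforms; non-rigid rotation blocks (|det R − 1| > 1e−6 or RᵀR ≠ I)
    are rejected. Connectivity is unchanged.
    """
    T = np.asarray(transforms, dtype=float)
    if T.shape != (weights.W.shape[1], 4, 4):
        raise ValueError("need one 4x4 transform per segment")
    for j, t in enumerate(T):
        R = t[:3, :3]
        if abs(np.linalg.det(R) - 1.0) > 1e-6 or np.max(np.abs(R.T @ R - np.eye(3))) > 1e-6:
            raise ValueError(f"transform {j} is not rigid (rotation block fails orthonormality)")
    v = np.asarray(mesh.vertices)
    # displacement form: v' = v + Σ_j w_j ((R_j − I) v + t_j); identical to the
    # direct blend under partition of unity, and exactly the identity map for
    # identity transforms (no float round-trip through the rotation)
    out = v.copy()
    for j in range(len(T)):
        disp = v @ (T[j, :3, :3] - np.eye(3)).T + T[j, :3, 3]
        out += weights.W[:, j : j + 1] * disp
    return trimesh.Trimesh(vertices=out, faces=mesh.faces.copy(), process=False)


# ---------------------------------------------------------------------------
# cardiac phantoms


def generate_lv_sequence(
    edv_ml: float,
    esv_ml: float,
    n_phases: int = N_PHASES_DEFAULT,
    subdivisions: int = 4,
) -> list[trimesh.Trimesh]:
    """Left-ventricular surface sequence with prescribed EDV and ESV.

    Phase volumes follow the smooth periodic curve
    V(t) = ESV + (EDV − ESV)(1 + cos 2πt)/2, maximal (EDV) at end diastole
    t = 0 and minimal (ESV) at end systole t = 0.5. Each phase is an icosphere
    (≥ 5000 faces at the default subdivision) scaled so its *discrete* volume
    matches the target, so EDV/ESV recovery is limited only by float round-off.
    """
    if not (edv_ml > esv_ml > 0):
        raise ValueError("need EDV > ESV > 0")
    unit = trimesh.creation.icosphere(subdivisions=subdivisions)
    unit_vol = unit.volume
    meshes = []
    for i in range(n_phases):
        tf = i / (n_phases - 1)
        v_ml = esv_ml + (edv_ml - esv_ml) * (1.0 + np.cos(2.0 * np.pi * tf)) / 2.0
        scale = (v_ml * 1e3 / unit_vol) ** (1.0 / 3.0)  # mL → mm³
        meshes.append(
            trimesh.Trimesh(vertices=unit.vertices * scale, faces=unit.faces.copy(), process=False)
        )
    return meshes


def generate_aortic_root_sequence(
    area_systole_mm2: float = 700.0,
    regurgitant_volume_ml: float = 0.0,
    root_length_mm: float = 20.0,
    n_z: int = 21,
    n_phases: int = N_PHASES_DEFAULT,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Aortic-root area field A(z, t) with a known regurgitant volume.

    During diastole the root cross-sectional area exceeds its valve-closure
    value by a hump whose z-integral equals the stated regurgitant volume.
    Returns ``(z_mm, A[z, phase] mm², info)`` where ``info`` holds the phase
    indices of mid-diastole and valve closure and the diastolic area baseline.
    """
    z = np.linspace(0.0, root_length_mm, n_z)
    tf = np.linspace(0.0, 1.0, n_phases)
    # systolic expansion: area swells around t = 0.25
    pulsation = 0.10 * np.exp(-((tf - 0.25) ** 2) / (2 * 0.1**2))
    A = np.empty((n_z, n_phases))
    base = area_systole_mm2 * (0.9 + 0.05 * np.cos(np.pi * z / root_length_mm))
    for j in range(n_phases):
        A[:, j] = base * (1.0 + pulsation[j])
    i_avc = int(np.argmin(np.abs(tf - 0.45)))  # valve closure
    i_dia = int(np.argmin(np.abs(tf - 0.75)))  # mid-diastole
    if regurgitant_volume_ml > 0:
        # uniform diastolic excess whose integral over z equals RV
        dA = regurgitant_volume_ml * 1e3 / root_length_mm  # mm²
        A[:, i_dia] = A[:, i_avc] + dA
    else:
        A[:, i_dia] = A[:, i_avc]
    info = {"i_dia": i_dia, "i_avc": i_avc, "t_dia": float(tf[i_dia]), "t_avc": float(tf[i_avc])}
    return z, A, info
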