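"""Differential geometry of coronary centerlines and cross-sections.

A vessel is represented by an ordered polyline (the centerline) carrying an
arc-length parameter ``s``, a local lumen radius/area, and the Frenet
curvature and torsion. These quantities feed the temporal-fusion weights
(curvature/torsion drive secondary Dean-flow terms) and the reduced-order
resistance model (area drives Poiseuille losses).

Lengths are millimetres throughout; conversion to SI happens only inside the
Reynolds-number and resistance computations that need it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Centerline",
    "CrossSection",
    "VesselTree",
    "MURRAY_EXPONENT",
    "arc_length_parametrize",
    "frenet_curvature_torsion",
    "hydraulic_diameter",
    "murray_parent_radius",
    "murray_flow_split",
]

#: Exponent of the modified Murray law for coronary bifurcations,
#: r_p^2.6 = r_d1^2.6 + r_d2^2.6.
MURRAY_EXPONENT = 2.6

#: Radial strain of coronary cross-sections stays within this physiological band.
MAX_RADIAL_STRAIN = 0.05


@dataclass
class Centerline:
    """Ordered centerline with arc-length parametrization and local lumen data.

    Attributes
    ----------
    points : (N, 3) float array, mm
    s : (N,) arc length, mm; ``s[0] == 0``, strictly increasing.
    radius : (N,) local lumen radius, mm (optional until assigned).
    area : (N,) local cross-sectional area, mm² (optional).
    curvature : (N,) Frenet curvature κ(s), 1/mm (optional).
    torsion : (N,) Frenet torsion τ(s), 1/mm (optional).
    """

    points: np.ndarray
    s: np.ndarray
    radius: np.ndarray | None = None
    area: np.ndarray | None = None
    curvature: np.ndarray | None = None
    torsion: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (N, 3) array")
        if self.s.shape != (len(self.points),):
            raise ValueError("s must have one entry per point")
        if self.s[0] != 0.0 or np.any(np.diff(self.s) <= 0):
            raise ValueError("s must start at 0 and be strictly increasing")
        for name in ("radius", "area"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val, dtype=float)
                if np.any(val <= 0):
                    raise ValueError(f"{name} must be strictly positive")
                setattr(self, name, val)

    @property
    def length(self) -> float:
        """Total arc length in mm."""
        return float(self.s[-1])

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class CrossSection:
    """Elliptical lumen cross-section obeying volume conservation.

    The semi-axes satisfy ``π a b = A0 (1 + eps_r)`` where ``A0`` is the
    reference area and ``eps_r`` the radial strain, bounded to ±5 %.
    """

    a: float
    b: float
    A0: float
    eps_r: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.A0) <= 0:
            raise ValueError("semi-axes and reference area must be positive")
        if abs(self.eps_r) > MAX_RADIAL_STRAIN + 1e-12:
            raise ValueError(
                f"radial strain {self.eps_r:+.4f} outside physiological ±{MAX_RADIAL_STRAIN}"
            )
        expected = self.A0 * (1.0 + self.eps_r)
        actual = np.pi * self.a * self.b
        if abs(actual - expected) > 1e-9 * expected:
            raise ValueError(
                "volume conservation violated: "
                f"pi*a*b = {actual:.12g} != A0*(1+eps_r) = {expected:.12g}"
            )

    @property
    def area(self) -> float:
        return np.pi * self.a * self.b


@dataclass
class VesselTree:
    """Branching vessel topology: centerline segments plus parent links.

    ``parent[i]`` is the index of branch *i*'s parent, or ``-1`` for the root.
    ``bifurcations`` lists (parent radius, daughter radius 1, daughter radius 2)
    tuples at each branch node for Murray-law consistency checks.
    """

    branches: list[Centerline]
    parent: list[int] = field(default_factory=list)
    bifurcations: list[tuple[float, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.branches)
        if not self.parent:
            self.parent = [-1] + [0] * (n - 1) if n else []
        roots = [i for i, p in enumerate(self.parent) if p == -1]
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root branch")
        # acyclicity / connectivity: walking parents from every node reaches the root
        for i in range(n):
            seen, j = set(), i
            while self.parent[j] != -1:
                if j in seen:
                    raise ValueError("parent links contain a cycle")
                seen.add(j)
                j = self.parent[j]

    def children(self, i: int) -> list[int]:
        return [j for j, p in enumerate(self.parent) if p == i]

    @property
    def leaves(self) -> list[int]:
        has_child = set(p for p in self.parent if p != -1)
        return [i for i in range(len(self.branches)) if i not in has_child]

    @property
    def root(self) -> int:
        return self.parent.index(-1)


def arc_length_parametrize(points: np.ndarray) -> Centerline:
    """Build a :class:`Centerline` with the cumulative arc-length parameter.

    Parameters
    ----------
    points : (N, 3) ordered coordinates in mm, N ≥ 2, no duplicate
        consecutive points.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("need at least 2 ordered 3D points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0):
        raise ValueError("duplicate consecutive points")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return Centerline(points=pts, s=s)


def frenet_curvature_torsion(c: Centerline) -> tuple[np.ndarray, np.ndarray]:
    """Frenet curvature κ(s) = |dT/ds| and torsion τ(s) along a centerline.

    Derivatives use central finite differences on the (possibly non-uniform)
    arc-length grid, one-sided at the endpoints. Where the curve is locally
    straight (κ ≈ 0) the Frenet frame is undefined and torsion is set to 0,
    the planar-curve limit.

    Returns ``(kappa, tau)`` in 1/mm; also stored on ``c``.
    """
    if len(c) < 5:
        raise ValueError("need at least 5 points for curvature/torsion")
    s, p = c.s, c.points
    d1 = np.gradient(p, s, axis=0, edge_order=2)
    d2 = np.gradient(d1, s, axis=0, edge_order=2)
    d3 = np.gradient(d2, s, axis=0, edge_order=2)

    cross = np.cross(d1, d2)
    cross_norm = np.linalg.norm(cross, axis=1)
    speed = np.linalg.norm(d1, axis=1)
    kappa = cross_norm / np.maximum(speed, 1e-300) ** 3

    # tau = (d1 x d2) . d3 / |d1 x d2|^2 ; 0 where the frame degenerates
    tau = np.zeros_like(kappa)
    ok = cross_norm > 1e-10
    tau[ok] = np.einsum("ij,ij->i", cross[ok], d3[ok]) / cross_norm[ok] ** 2
    kappa[~np.isfinite(kappa)] = 0.0
    tau[~np.isfinite(tau)] = 0.0
    c.curvature, c.torsion = kappa, tau
    return kappa, tau


def hydraulic_diameter(area: float | np.ndarray) -> float | np.ndarray:
    """Circular-equivalent diameter D_h = 2 sqrt(A/π) of a lumen area (mm² → mm)."""
    area = np.asarray(area, dtype=float)
    if np.any(area <= 0):
        raise ValueError("area must be strictly positive")
    out = 2.0 * np.sqrt(area / np.pi)
    return float(out) if out.ndim == 0 else out


def murray_parent_radius(r_d1: float, r_d2: float) -> float:
    """Parent radius from the modified Murray law r_p^2.6 = r_d1^2.6 + r_d2^2.6."""
    if r_d1 < 0 or r_d2 < 0:
        raise ValueError("radii must be non-negative")
    if r_d1 == 0 and r_d2 == 0:
        raise ValueError("at least one daughter radius must be positive")
    m = MURRAY_EXPONENT
    return float((r_d1**m + r_d2**m) ** (1.0 / m))


def murray_flow_split(r_d1: float, r_d2: float, q_parent: float) -> tuple[float, float]:
    """Partition parent flow between daughters in proportion to r^2.6.

    Conserves flow exactly: ``Q1 + Q2 == q_parent``.
    """
    if r_d1 <= 0 or r_d2 <= 0:
        raise ValueError("daughter radii must be positive")
    if q_parent < 0:
        raise ValueError("parent flow must be non-negative")
    m = MURRAY_EXPONENT
    w1 = r_d1**m / (r_d1**m + r_d2**m)
    q1 = q_parent * w1
    return q1, q_parent - q1
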