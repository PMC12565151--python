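"""File formats: meshes (STL/OBJ/VTK polydata), centerline tables, manifests.

STL and OBJ go through trimesh; legacy-VTK ASCII POLYDATA is handled by a
small built-in reader/writer (triangle meshes only). CSV output uses 17
significant digits so round trips are bit-faithful for doubles.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .geometry import Centerline, arc_length_parametrize

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_centerline_csv",
    "write_centerline_csv",
    "write_json_report",
    "FLOAT_FMT",
]

FLOAT_FMT = "%.17g"


def read_mesh(path) -> trimesh.Trimesh:
    """Load a surface mesh from STL, OBJ or legacy-VTK polydata."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".vtk":
        return _read_vtk_polydata(path)
    if ext in (".stl", ".obj", ".ply", ".off"):
        mesh = trimesh.load(str(path), file_type=ext[1:], process=False, force="mesh")
        if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
            raise ValueError(f"{path}: no triangular surface found")
        return mesh
    raise ValueError(f"{path}: unknown mesh extension {ext!r} (use .stl/.obj/.vtk)")


def write_mesh(path, mesh: trimesh.Trimesh) -> None:
    """Write a surface mesh; format chosen by extension (STL is float32 per spec)."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".vtk":
        _write_vtk_polydata(path, mesh)
    elif ext in (".stl", ".obj", ".ply", ".off"):
        mesh.export(str(path))
    else:
        raise ValueError(f"{path}: unknown mesh extension {ext!r} (use .stl/.obj/.vtk)")


def _read_vtk_polydata(path: Path) -> trimesh.Trimesh:
    tokens: list[str] = []
    lines = path.read_text().splitlines()
    if len(lines) < 4 or not lines[0].startswith("# vtk DataFile"):
        raise ValueError(f"{path}: corrupt or missing legacy-VTK header")
    if lines[2].strip().upper() != "ASCII":
        raise ValueError(f"{path}: only ASCII legacy VTK is supported")
    if "POLYDATA" not in lines[3].upper():
        raise ValueError(f"{path}: expected DATASET POLYDATA")
    for line in lines[4:]:
        tokens.extend(line.split())
    i = 0

    def expect(word: str) -> None:
        nonlocal i
        if i >= len(tokens) or tokens[i].upper() != word:
            raise ValueError(f"{path}: expected {word} at token {i}")
        i += 1

    expect("POINTS")
    n_pts = int(tokens[i]); i += 2  # count + dtype
    pts = np.array(tokens[i : i + 3 * n_pts], dtype=float).reshape(n_pts, 3)
    i += 3 * n_pts
    expect("POLYGONS")
    n_poly = int(tokens[i]); i += 2  # count + total ints
    faces = []
    for _ in range(n_poly):
        k = int(tokens[i]); i += 1
        if k != 3:
            raise ValueError(f"{path}: only triangle polygons supported, got {k}-gon")
        faces.append([int(tokens[i]), int(tokens[i + 1]), int(tokens[i + 2])])
        i += 3
    return trimesh.Trimesh(vertices=pts, faces=np.asarray(faces), process=False)


def _write_vtk_polydata(path: Path, mesh: trimesh.Trimesh) -> None:
    v, f = mesh.vertices, mesh.faces
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\ncorofuse surface\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {len(v)} double\n")
        for p in v:
            fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
        fh.write(f"POLYGONS {len(f)} {4 * len(f)}\n")
        for tri in f:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")


def read_centerline_csv(path) -> Centerline:
    """Centerline from CSV with columns x, y, z, radius (mm; optional area)."""
    df = pd.read_csv(path)
    required = {"x", "y", "z", "radius"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: centerline CSV needs columns {sorted(required)}")
    cl = arc_length_parametrize(df[["x", "y", "z"]].to_numpy())
    cl.radius = df["radius"].to_numpy(dtype=float)
    cl.area = (
        df["area"].to_numpy(dtype=float)
        if "area" in df.columns
        else np.pi * cl.radius**2
    )
    return cl


def write_centerline_csv(path, cl: Centerline) -> None:
    cols = {
        "x": cl.points[:, 0],
        "y": cl.points[:, 1],
        "z": cl.points[:, 2],
        "s": cl.s,
        "radius": cl.radius,
        "area": cl.area,
    }
    if cl.curvature is not None:
        cols["curvature"] = cl.curvature
    if cl.torsion is not None:
        cols["torsion"] = cl.torsion
    pd.DataFrame(cols).to_csv(path, index=False, float_format=FLOAT_FMT, lineterminator="\n")


def write_json_report(path, payload: dict) -> None:
    """Deterministic JSON: sorted keys, fixed separators, LF newline."""
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
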