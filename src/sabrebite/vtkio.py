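"""File I/O: triangle surfaces (STL/OFF/PLY), legacy-VTK unstructured grids
with the integer ``region`` cell field, landmark CSV, and reaction CSV.

The legacy-VTK (ASCII) reader/writer covers exactly what the pipeline emits:
tet-only unstructured grids, integer cell data (region: 0=bone, 1=dentine,
2=enamel), and optional point/cell fields from solves.  Files missing the
region field read back as all-bone with a warning; non-tet cells are rejected
with the offending cell index.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import numpy as np

from sabrebite.mesh import REGION_BONE, TetMesh

_SURFACE_SUFFIXES = {".stl", ".off", ".ply"}


class ParseError(ValueError):
    """Malformed input file; message carries the file position."""


# ---------------------------------------------------------------------------
# triangle surfaces
# ---------------------------------------------------------------------------

def read_surface(path):
    """Read an STL (ascii or binary), OFF or PLY triangle surface; normals
    are recomputed from geometry on load."""
    import trimesh

    path = Path(path)
    if path.suffix.lower() not in _SURFACE_SUFFIXES:
        raise ParseError(f"{path}: unsupported surface format "
                         f"'{path.suffix}' (want STL/OFF/PLY)")
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        mesh = trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if not hasattr(mesh, "faces") or len(mesh.faces) == 0:
        raise ParseError(f"{path}: no triangles found")
    mesh._cache.delete("face_normals")      # recompute from geometry
    return mesh


def write_surface(surface, path) -> None:
    """Write a trimesh or (vertices, faces) pair; format from the suffix."""
    import trimesh

    path = Path(path)
    if path.suffix.lower() not in _SURFACE_SUFFIXES:
        raise ValueError(f"unsupported surface format '{path.suffix}'")
    if not hasattr(surface, "export"):
        surface = trimesh.Trimesh(vertices=np.asarray(surface[0]),
                                  faces=np.asarray(surface[1]),
                                  process=False)
    surface.export(str(path))


# ---------------------------------------------------------------------------
# legacy VTK unstructured grids
# ---------------------------------------------------------------------------

def write_volume(mesh: TetMesh, path, point_data: dict | None = None,
                 cell_data: dict | None = None) -> None:
    """Write a tet mesh as an ASCII legacy-VTK unstructured grid.

    The region labels go out as integer cell data named ``region``; extra
    ``point_data``/``cell_data`` arrays (e.g. displacement, von Mises) are
    appended as FIELD/SCALARS entries.
    """
    path = Path(path)
    n, m = mesh.n_nodes, mesh.n_tets
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write("sabrebite unstructured grid (mm)\n")
        f.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {n} double\n")
        for p in mesh.nodes:
            f.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        f.write(f"CELLS {m} {5 * m}\n")
        for t in mesh.tets:
            f.write(f"4 {t[0]} {t[1]} {t[2]} {t[3]}\n")
        f.write(f"CELL_TYPES {m}\n")
        f.write("\n".join(["10"] * m) + "\n")

        f.write(f"CELL_DATA {m}\n")
        f.write("SCALARS region int 1\nLOOKUP_TABLE default\n")
        f.write("\n".join(str(int(r)) for r in mesh.regions) + "\n")
        for name, arr in (cell_data or {}).items():
            arr = np.asarray(arr)
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            f.write("\n".join(f"{v:.9g}" for v in arr) + "\n")
        if point_data:
            f.write(f"POINT_DATA {n}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 2 and arr.shape[1] == 3:
                    f.write(f"VECTORS {name} double\n")
                    for v in arr:
                        f.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
                else:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    f.write("\n".join(f"{v:.9g}" for v in arr) + "\n")


def read_volume(path) -> TetMesh:
    """Read an ASCII legacy-VTK unstructured grid of tet cells.

    Non-tet cells are rejected (with the offending cell index); a missing
    ``region`` field defaults every cell to cortical bone with a warning.
    """
    path = Path(path)
    tokens = []
    line_of = []
    with open(path) as f:
        for ln, line in enumerate(f, 1):
            for tok in line.split():
                tokens.append(tok)
                line_of.append(ln)
    pos = 0

    def expect(word):
        nonlocal pos
        if pos >= len(tokens) or tokens[pos].upper() != word:
            got = tokens[pos] if pos < len(tokens) else "<eof>"
            line = line_of[min(pos, len(line_of) - 1)] if line_of else 0
            raise ParseError(f"{path}:{line}: expected {word}, got {got!r}")
        pos += 1

    def find(word):
        nonlocal pos
        while pos < len(tokens) and tokens[pos].upper() != word:
            pos += 1
        if pos >= len(tokens):
            raise ParseError(f"{path}: missing {word} section")
        pos += 1

    def take(n, conv):
        nonlocal pos
        if pos + n > len(tokens):
            raise ParseError(f"{path}: truncated file at line "
                             f"{line_of[-1] if line_of else 0}")
        out = [conv(t) for t in tokens[pos:pos + n]]
        pos += n
        return out

    find("DATASET")
    expect("UNSTRUCTURED_GRID")
    find("POINTS")
    npts = take(1, int)[0]
    take(1, str)                          # dtype
    pts = np.array(take(3 * npts, float)).reshape(npts, 3)

    find("CELLS")
    ncell = take(1, int)[0]
    total = take(1, int)[0]
    raw = take(total, int)
    cells = []
    i = 0
    for ci in range(ncell):
        k = raw[i]
        if k != 4:
            raise ParseError(f"{path}: cell {ci} has {k} vertices; only "
                             "4-noded tets are supported")
        cells.append(raw[i + 1:i + 5])
        i += k + 1
    find("CELL_TYPES")
    ntypes = take(1, int)[0]
    types = take(ntypes, int)
    for ci, t in enumerate(types):
        if t != 10:
            raise ParseError(f"{path}: cell {ci} has VTK type {t}; only "
                             "tetrahedra (type 10) are supported")

    regions = None
    save = pos
    try:
        find("CELL_DATA")
        take(1, int)
        while pos < len(tokens):
            if tokens[pos].upper() == "SCALARS" and pos + 1 < len(tokens) \
                    and tokens[pos + 1] == "region":
                pos += 3                          # SCALARS region <type>
                if pos < len(tokens) and tokens[pos] == "1":
                    pos += 1
                find("LOOKUP_TABLE")
                take(1, str)
                regions = np.array(take(ncell, int))
                break
            pos += 1
    except ParseError:
        pos = save
    if regions is None:
        warnings.warn(f"{path}: no 'region' cell data; defaulting all cells "
                      "to cortical bone", RuntimeWarning, stacklevel=2)
        regions = np.full(ncell, REGION_BONE)

    mesh = TetMesh(pts, np.array(cells), regions)
    mesh.orient_positive()
    return mesh


# ---------------------------------------------------------------------------
# CSV helpers
# ---------------------------------------------------------------------------

def write_landmarks(landmarks: dict, path) -> None:
    """Landmark CSV: name, x, y, z (mm)."""
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["name", "x_mm", "y_mm", "z_mm"])
        for name in sorted(landmarks):
            p = landmarks[name]
            w.writerow([name, f"{p[0]:.9g}", f"{p[1]:.9g}", f"{p[2]:.9g}"])


def read_landmarks(path) -> dict:
    out = {}
    with open(path, newline="") as f:
        r = csv.reader(f)
        header = next(r)
        if header[:1] != ["name"]:
            raise ParseError(f"{path}:1: expected landmark CSV header")
        for row in r:
            out[row[0]] = np.array([float(row[1]), float(row[2]),
                                    float(row[3])])
    return out


def write_reactions(reactions: dict, coords, path) -> None:
    """Support reactions CSV: node, position (mm), force (N), moment (N*mm)."""
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["node", "x_mm", "y_mm", "z_mm",
                    "fx_n", "fy_n", "fz_n", "mx_nmm", "my_nmm", "mz_nmm"])
        for node in sorted(reactions):
            p = coords[node]
            r = reactions[node]
            w.writerow([node] + [f"{v:.9g}" for v in (*p, *r)])
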