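"""Reading and writing atrial surface meshes and fibre fields.

Two dialects are supported:

* **carp** — the CARP/openCARP plain-text triplet: ``.pts`` (vertex count,
  then ``x y z`` per line), ``.elem`` (element count, then ``Tr i j k region``)
  and optional ``.lon`` (``fx fy fz`` per element). Indices are written
  0-based by default; a flag handles the 1-based dialect. A ``scale`` flag
  converts micrometre files to the package's internal millimetres, since
  deposited meshes do not state their unit convention.
* **vtk** — legacy ASCII VTK polydata with triangle polygons, optional
  ``CELL_DATA`` fibre ``VECTORS`` and optional per-vertex scalar fields
  (used for the coordinate fields ``alpha``/``beta``).

Round trips are bit-exact for carp (``repr``-precision floats) and good to
1e-6 for vtk.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .mesh import FibreField, SurfaceMesh

__all__ = ["FormatError", "read_mesh", "write_mesh", "read_lon", "write_lon"]


class FormatError(ValueError):
    """Malformed mesh file; the message names the offending file and line."""


def _err(path, lineno, msg):
    raise FormatError(f"{path}:{lineno}: {msg}")


# ----------------------------------------------------------------------
# CARP triplet
# ----------------------------------------------------------------------

def _read_pts(path: Path, scale: float) -> np.ndarray:
    lines = path.read_text().splitlines()
    if not lines:
        _err(path, 1, "empty .pts file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        _err(path, 1, f"expected vertex count, got {lines[0]!r}")
    if len(lines) < n + 1:
        _err(path, len(lines), f"expected {n} vertex lines")
    try:
        pts = np.loadtxt(lines[1 : n + 1], dtype=float, ndmin=2)
    except ValueError as e:
        _err(path, 2, f"bad vertex line: {e}")
    if pts.shape[1] != 3:
        _err(path, 2, f"expected 3 coordinates per vertex, got {pts.shape[1]}")
    return pts * scale


def _read_elem(path: Path, n_vertices: int, one_based: bool) -> np.ndarray:
    lines = path.read_text().splitlines()
    if not lines:
        _err(path, 1, "empty .elem file")
    try:
        m = int(lines[0].split()[0])
    except (ValueError, IndexError):
        _err(path, 1, f"expected element count, got {lines[0]!r}")
    tris = np.empty((m, 3), dtype=np.int64)
    for i in range(m):
        lineno = i + 2
        if i + 1 >= len(lines):
            _err(path, lineno, "unexpected end of file")
        parts = lines[i + 1].split()
        if not parts:
            _err(path, lineno, "empty element line")
        if parts[0] != "Tr":
            _err(path, lineno, f"unsupported cell type {parts[0]!r} (only 'Tr')")
        if len(parts) < 4:
            _err(path, lineno, "triangle needs three vertex indices")
        try:
            tris[i] = [int(parts[1]), int(parts[2]), int(parts[3])]
        except ValueError:
            _err(path, lineno, f"non-integer vertex index in {lines[i + 1]!r}")
    if one_based:
        tris -= 1
    if tris.size and (tris.min() < 0 or tris.max() >= n_vertices):
        bad = int(np.argmax((tris < 0) | (tris >= n_vertices)).item() // 3)
        _err(path, bad + 2, "vertex index out of range")
    return tris


def read_lon(path, n_elements: int | None = None) -> FibreField:
    """Read a CARP ``.lon`` fibre file (one ``fx fy fz`` per element)."""
    path = Path(path)
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    # tolerate the openCARP header line holding the number of fibre columns
    if lines and len(lines[0].split()) == 1:
        lines = lines[1:]
    try:
        vec = np.loadtxt(lines, dtype=float, ndmin=2)
    except ValueError as e:
        _err(path, 1, f"bad fibre line: {e}")
    if vec.shape[1] != 3:
        _err(path, 1, f"expected 3 components per fibre, got {vec.shape[1]}")
    if n_elements is not None and len(vec) != n_elements:
        _err(path, 1, f"expected {n_elements} fibres, got {len(vec)}")
    return FibreField(vec)


def write_lon(fibres: FibreField, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for v in fibres.vectors:
            fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")


def _write_carp(mesh, prefix: Path, fibres, scale, one_based) -> None:
    pts = prefix.with_suffix(".pts")
    with pts.open("w") as fh:
        fh.write(f"{mesh.n_vertices}\n")
        for v in mesh.vertices / scale:
            fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
    offset = 1 if one_based else 0
    with prefix.with_suffix(".elem").open("w") as fh:
        fh.write(f"{mesh.n_triangles}\n")
        for t in mesh.triangles + offset:
            fh.write(f"Tr {t[0]} {t[1]} {t[2]} 1\n")
    if fibres is not None:
        write_lon(fibres, prefix.with_suffix(".lon"))


# ----------------------------------------------------------------------
# legacy ASCII VTK polydata
# ----------------------------------------------------------------------

def _read_vtk(path: Path):
    tokens: list[str] = []
    lineno_of: list[int] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        for tok in line.split():
            tokens.append(tok)
            lineno_of.append(lineno)
    pos = 0

    def take(n):
        nonlocal pos
        if pos + n > len(tokens):
            _err(path, lineno_of[-1] if lineno_of else 1, "unexpected end of file")
        out = tokens[pos : pos + n]
        pos += n
        return out

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    vertices = triangles = None
    fibres = None
    point_data: dict[str, np.ndarray] = {}
    n_points = n_cells = 0
    while pos < len(tokens):
        tok = take(1)[0].upper()
        if tok == "POINTS":
            n_points = int(take(1)[0])
            take(1)  # dtype
            vals = np.asarray(take(3 * n_points), dtype=float)
            vertices = vals.reshape(n_points, 3)
        elif tok == "POLYGONS":
            n_cells = int(take(1)[0])
            total = int(take(1)[0])
            # modern legacy writers may emit OFFSETS/CONNECTIVITY instead
            if peek() and peek().upper() == "OFFSETS":
                _err(path, lineno_of[pos], "OFFSETS-style POLYGONS not supported")
            vals = np.asarray(take(total), dtype=np.int64)
            tris = []
            i = 0
            while i < len(vals):
                sz = int(vals[i])
                if sz != 3:
                    _err(path, lineno_of[pos - total + i], f"non-triangle cell of size {sz}")
                tris.append(vals[i + 1 : i + 4])
                i += sz + 1
            if len(tris) != n_cells:
                _err(path, lineno_of[pos - 1], "POLYGONS count mismatch")
            triangles = np.asarray(tris, dtype=np.int64)
        elif tok == "CELL_DATA":
            n = int(take(1)[0])
            while peek() and peek().upper() in ("VECTORS", "SCALARS", "NORMALS"):
                kind = take(1)[0].upper()
                name = take(1)[0]
                take(1)  # dtype
                if kind == "SCALARS":
                    if peek() and peek().isdigit():
                        take(1)  # optional numComponents
                    take(2)  # LOOKUP_TABLE default
                    take(n)
                else:
                    vals = np.asarray(take(3 * n), dtype=float).reshape(n, 3)
                    if name == "fibres":
                        fibres = vals
        elif tok == "POINT_DATA":
            n = int(take(1)[0])
            while peek() and peek().upper() in ("SCALARS", "VECTORS"):
                kind = take(1)[0].upper()
                name = take(1)[0]
                take(1)
                if kind == "SCALARS":
                    if peek() and peek().isdigit():
                        take(1)  # optional numComponents
                    take(2)
                    point_data[name] = np.asarray(take(n), dtype=float)
                else:
                    take(3 * n)
        # all other header tokens (versions, DATASET, comments) are skipped
    if vertices is None or triangles is None:
        _err(path, 1, "file lacks POINTS or POLYGONS section")
    if triangles.size and (triangles.min() < 0 or triangles.max() >= n_points):
        _err(path, 1, "vertex index out of range in POLYGONS")
    return vertices, triangles, fibres, point_data


def _write_vtk(mesh, path: Path, fibres, point_data=None) -> None:
    with path.open("w") as fh:
        fh.write("# vtk DataFile Version 3.0\natriafib surface\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_vertices} double\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        fh.write(f"POLYGONS {mesh.n_triangles} {4 * mesh.n_triangles}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        if fibres is not None:
            fh.write(f"CELL_DATA {mesh.n_triangles}\n")
            fh.write("VECTORS fibres double\n")
            for v in fibres.vectors:
                fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_vertices}\n")
            for name, vals in point_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for x in vals:
                    fh.write(f"{x:.9g}\n")


# ----------------------------------------------------------------------
# public front end
# ----------------------------------------------------------------------

def read_mesh(
    path,
    fmt: str = "carp",
    scale: float = 1.0,
    one_based: bool = False,
    with_fibres: bool = False,
):
    """Read a surface mesh (and optionally its fibre field).

    Parameters
    ----------
    path : str or Path
        For carp: the triplet prefix (``.pts``/``.elem``/``.lon`` appended).
        For vtk: the ``.vtk`` file.
    fmt : {"carp", "vtk"}
    scale : float
        Multiplier applied to input coordinates (e.g. ``1e-3`` for files in
        micrometres) so that internal units are mm.
    one_based : bool
        carp dialect flag for 1-based element indices.
    with_fibres : bool
        Also return the fibre field (``.lon`` / CELL_DATA ``fibres``).

    Returns
    -------
    SurfaceMesh, or (SurfaceMesh, FibreField | None) if ``with_fibres``.
    """
    path = Path(path)
    if fmt == "carp":
        prefix = path.with_suffix("") if path.suffix in (".pts", ".elem", ".lon") else path
        vertices = _read_pts(prefix.with_suffix(".pts"), scale)
        triangles = _read_elem(prefix.with_suffix(".elem"), len(vertices), one_based)
        mesh = SurfaceMesh(vertices, triangles)
        fib = None
        lon = prefix.with_suffix(".lon")
        if with_fibres and lon.exists():
            fib = read_lon(lon, mesh.n_triangles)
    elif fmt == "vtk":
        vertices, triangles, fvec, _pd = _read_vtk(path)
        mesh = SurfaceMesh(vertices * scale, triangles)
        fib = FibreField(fvec) if fvec is not None else None
    else:
        raise ValueError(f"unknown format {fmt!r} (use 'carp' or 'vtk')")
    return (mesh, fib) if with_fibres else mesh


def write_mesh(
    mesh: SurfaceMesh,
    path,
    fmt: str = "carp",
    fibres: FibreField | None = None,
    scale: float = 1.0,
    one_based: bool = False,
    point_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write a surface mesh, optional fibres, and optional per-vertex scalars."""
    path = Path(path)
    if fmt == "carp":
        prefix = path.with_suffix("") if path.suffix in (".pts", ".elem", ".lon") else path
        _write_carp(mesh, prefix, fibres, scale, one_based)
    elif fmt == "vtk":
        _write_vtk(mesh, path, fibres, point_data)
    else:
        raise ValueError(f"unknown format {fmt!r} (use 'carp' or 'vtk')")
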