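"""Mesh file I/O: ASCII VTU, STL and a documented INP subset.

VTU (VTK XML unstructured grid, ascii) is the round-trip format for volume
meshes and result fields: node coordinates are written with 17 significant
digits so that write∘read reproduces them to 1e-12 relative, and the cavity
facets, orifice ring and trabecula cables are preserved as FieldData arrays.
STL carries surfaces only (via :mod:`trimesh`).  The INP subset understands
``*NODE``, ``*ELEMENT, TYPE=C3D4`` (any 4-node tet type string) and
``*NSET``; it is 1-based on disk, 0-based in memory, and a node set named
``ORIFICE`` populates the orifice ring on read.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET

import numpy as np
import trimesh

from .geometry import SurfaceMesh, VolumeMesh

__all__ = ["read_mesh", "write_mesh", "read_vtu", "write_vtu",
           "read_stl", "write_stl", "read_inp", "write_inp"]

_FMT = "%.17g"


class MeshParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# VTU


def write_vtu(mesh: VolumeMesh, path, cell_data: dict | None = None,
              point_data: dict | None = None) -> None:
    """Write a volume mesh (plus optional per-element / per-node fields)."""
    n, e = mesh.n_nodes, mesh.n_elements
    lines = []
    w = lines.append
    w('<?xml version="1.0"?>')
    w('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">')
    w('<UnstructuredGrid>')
    # field data: tags that a plain tet mesh cannot carry
    w('<FieldData>')
    _field_array(w, "inner_facets", mesh.inner_facets.ravel(), "Int64")
    _field_array(w, "orifice_ring", mesh.orifice_ring, "Int64")
    if mesh.trabecula_cables:
        cab = np.asarray([[a, b] for a, b, _ in mesh.trabecula_cables],
                         dtype=np.int64)
        dia = np.asarray([d for _, _, d in mesh.trabecula_cables])
        _field_array(w, "cable_nodes", cab.ravel(), "Int64")
        _field_array(w, "cable_diameters", dia, "Float64")
    w('</FieldData>')
    w(f'<Piece NumberOfPoints="{n}" NumberOfCells="{e}">')
    w('<Points>')
    w('<DataArray type="Float64" NumberOfComponents="3" format="ascii">')
    w("\n".join(" ".join(_FMT % x for x in row) for row in mesh.nodes))
    w('</DataArray>')
    w('</Points>')
    w('<Cells>')
    w('<DataArray type="Int64" Name="connectivity" format="ascii">')
    w("\n".join(" ".join(str(i) for i in row) for row in mesh.tets))
    w('</DataArray>')
    w('<DataArray type="Int64" Name="offsets" format="ascii">')
    w(" ".join(str(4 * (i + 1)) for i in range(e)))
    w('</DataArray>')
    w('<DataArray type="UInt8" Name="types" format="ascii">')
    w(" ".join("10" for _ in range(e)))
    w('</DataArray>')
    w('</Cells>')
    w('<CellData>')
    for name, arr in (cell_data or {}).items():
        _field_array(w, name, np.asarray(arr), "Float64")
    w('</CellData>')
    w('<PointData>')
    for name, arr in (point_data or {}).items():
        a = np.asarray(arr)
        ncomp = a.shape[1] if a.ndim == 2 else 1
        w(f'<DataArray type="Float64" Name="{name}" '
          f'NumberOfComponents="{ncomp}" format="ascii">')
        w("\n".join(" ".join(_FMT % x for x in np.atleast_1d(row))
                    for row in a))
        w('</DataArray>')
    w('</PointData>')
    w('</Piece>')
    w('</UnstructuredGrid>')
    w('</VTKFile>')
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _field_array(w, name: str, arr: np.ndarray, vtk_type: str) -> None:
    fmt = _FMT if vtk_type.startswith("Float") else "%d"
    w(f'<DataArray type="{vtk_type}" Name="{name}" '
      f'NumberOfTuples="{len(arr)}" format="ascii">')
    w(" ".join(fmt % x for x in np.asarray(arr).ravel()))
    w('</DataArray>')


def read_vtu(path) -> VolumeMesh:
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise MeshParseError(f"{path}: not well-formed XML ({exc})") from exc
    root = tree.getroot()
    piece = root.find(".//Piece")
    if piece is None:
        raise MeshParseError(f"{path}: no <Piece> element")

    def arr(parent, name=None, tag="DataArray"):
        for da in parent.iter(tag):
            if name is None or da.get("Name") == name:
                txt = (da.text or "").split()
                typ = da.get("type", "Float64")
                dtype = np.int64 if typ.startswith(("Int", "UInt")) else float
                return np.asarray(txt, dtype=dtype)
        return None

    pts_el = piece.find("Points")
    conn_parent = piece.find("Cells")
    if pts_el is None or conn_parent is None:
        raise MeshParseError(f"{path}: missing Points/Cells")
    pts = arr(pts_el).reshape(-1, 3)
    conn = arr(conn_parent, "connectivity")
    offsets = arr(conn_parent, "offsets")
    if np.any(np.diff(np.concatenate([[0], offsets])) != 4):
        raise MeshParseError(f"{path}: only 4-node tetrahedra supported")
    tets = conn.reshape(-1, 4)

    fd = root.find(".//FieldData")
    inner = np.empty((0, 3), np.int64)
    ring = np.empty(0, np.int64)
    cables: list[tuple[int, int, float]] = []
    if fd is not None:
        a = arr(fd, "inner_facets")
        if a is not None and a.size:
            inner = a.reshape(-1, 3)
        a = arr(fd, "orifice_ring")
        if a is not None:
            ring = a
        cn = arr(fd, "cable_nodes")
        cd = arr(fd, "cable_diameters")
        if cn is not None and cd is not None and cn.size:
            pairs = cn.reshape(-1, 2)
            cables = [(int(p[0]), int(p[1]), float(d))
                      for p, d in zip(pairs, cd)]
    return VolumeMesh(nodes=pts, tets=tets, inner_facets=inner,
                      orifice_ring=ring, trabecula_cables=cables,
                      node_sets={"ORIFICE": ring} if ring.size else {})


# ---------------------------------------------------------------------------
# STL (surfaces)


def write_stl(surf: SurfaceMesh, path) -> None:
    trimesh.Trimesh(vertices=surf.vertices, faces=surf.triangles,
                    process=False).export(path)


def read_stl(path) -> SurfaceMesh:
    tm = trimesh.load(path, force="mesh", process=True)
    return SurfaceMesh(np.asarray(tm.vertices, float),
                       np.asarray(tm.faces, np.int64))


# ---------------------------------------------------------------------------
# INP subset


def write_inp(mesh: VolumeMesh, path) -> None:
    with open(path, "w") as fh:
        fh.write("*NODE\n")
        for i, (x, y, z) in enumerate(mesh.nodes, start=1):
            fh.write(f"{i}, {_FMT % x}, {_FMT % y}, {_FMT % z}\n")
        fh.write("*ELEMENT, TYPE=C3D4\n")
        for i, t in enumerate(mesh.tets, start=1):
            fh.write(f"{i}, {t[0] + 1}, {t[1] + 1}, {t[2] + 1}, {t[3] + 1}\n")
        sets = dict(mesh.node_sets)
        if mesh.orifice_ring.size and "ORIFICE" not in sets:
            sets["ORIFICE"] = mesh.orifice_ring
        for name, ids in sets.items():
            fh.write(f"*NSET, NSET={name}\n")
            ids1 = np.asarray(ids) + 1
            for k in range(0, len(ids1), 8):
                fh.write(", ".join(str(int(i)) for i in ids1[k:k + 8]) + "\n")


def read_inp(path) -> VolumeMesh:
    nodes: dict[int, tuple[float, float, float]] = {}
    tets: list[tuple[int, int, int, int]] = []
    nsets: dict[str, list[int]] = {}
    section = None
    current_set = None
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("**"):
                continue
            if line.startswith("*"):
                kw = line.split(",")[0].strip().upper()
                if kw == "*NODE":
                    section = "node"
                elif kw == "*ELEMENT":
                    opts = dict(
                        p.partition("=")[::2] for p in
                        (s.strip().upper() for s in line.split(",")[1:]))
                    et = opts.get("TYPE", "C3D4")
                    if "3D4" not in et and "TET" not in et:
                        raise MeshParseError(
                            f"{path}:{ln}: unsupported element type {et}")
                    section = "element"
                elif kw == "*NSET":
                    opts = dict(
                        p.partition("=")[::2] for p in
                        (s.strip() for s in line.split(",")[1:]))
                    name = {k.upper(): v for k, v in opts.items()}.get("NSET")
                    if not name:
                        raise MeshParseError(f"{path}:{ln}: *NSET without "
                                             f"NSET= name")
                    current_set = name
                    nsets[name] = []
                    section = "nset"
                else:
                    section = None
                continue
            try:
                if section == "node":
                    parts = line.split(",")
                    nodes[int(parts[0])] = (float(parts[1]), float(parts[2]),
                                            float(parts[3]))
                elif section == "element":
                    parts = [int(p) for p in line.split(",")]
                    tets.append(tuple(parts[1:5]))
                elif section == "nset":
                    nsets[current_set] += [int(p) for p in line.split(",")
                                           if p.strip()]
            except (ValueError, IndexError) as exc:
                raise MeshParseError(
                    f"{path}:{ln}: malformed record {line!r}") from exc
    if not nodes or not tets:
        raise MeshParseError(f"{path}: no nodes or elements found")
    ids = sorted(nodes)
    remap = {nid: k for k, nid in enumerate(ids)}
    coords = np.asarray([nodes[i] for i in ids])
    tets_arr = np.asarray([[remap[i] for i in t] for t in tets], np.int64)
    node_sets = {name: np.asarray(sorted(remap[i] for i in lst), np.int64)
                 for name, lst in nsets.items()}
    ring = node_sets.get("ORIFICE", np.empty(0, np.int64))
    return VolumeMesh(nodes=coords, tets=tets_arr,
                      inner_facets=np.empty((0, 3), np.int64),
                      orifice_ring=ring, node_sets=node_sets)


# ---------------------------------------------------------------------------
# dispatch


def _infer_format(path, fmt: str | None) -> str:
    if fmt:
        return fmt.lower()
    s = str(path).lower()
    for ext in ("vtu", "stl", "inp"):
        if s.endswith("." + ext):
            return ext
    raise ValueError(f"cannot infer mesh format from {path!r}")


def read_mesh(path, fmt: str | None = None):
    fmt = _infer_format(path, fmt)
    if fmt == "vtu":
        return read_vtu(path)
    if fmt == "stl":
        return read_stl(path)
    if fmt == "inp":
        return read_inp(path)
    raise ValueError(f"unknown mesh format {fmt!r}")


def write_mesh(mesh, path, fmt: str | None = None, **kw) -> None:
    fmt = _infer_format(path, fmt)
    if fmt == "vtu":
        write_vtu(mesh, path, **kw)
    elif fmt == "stl":
        write_stl(mesh, path)
    elif fmt == "inp":
        write_inp(mesh, path)
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")
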