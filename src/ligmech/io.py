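"""Mesh and table I/O: ASCII VTK unstructured grids and Abaqus-dialect meshes.

Writes `.vtu` (XML, ASCII) files with the named point fields
``displacement`` and ``pressure`` and cell fields ``fiber`` and
``material_id``, readable by ParaView; reads them back for round-trip use.
Also reads the NODE/ELEMENT blocks of Abaqus ``.inp`` files with C3D4 or
C3D4P tetrahedra so third-party meshes can be imported.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .poro_fem import PoroMesh

__all__ = ["write_vtu", "read_vtu", "read_abaqus_inp"]


def _fmt(arr: np.ndarray) -> str:
    return "\n".join(" ".join(f"{v:.10g}" for v in np.atleast_1d(row)) for row in arr)


def write_vtu(
    path,
    mesh: PoroMesh,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write mesh (+ named fields) as an ASCII .vtu unstructured grid."""
    point_data = dict(point_data or {})
    cell_data = dict(cell_data or {})
    cell_data.setdefault("fiber", mesh.fiber)
    cell_data.setdefault("material_id", mesh.material_id)

    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1", byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")
    piece = ET.SubElement(
        grid, "Piece", NumberOfPoints=str(mesh.n_nodes), NumberOfCells=str(mesh.n_elements)
    )

    pts = ET.SubElement(piece, "Points")
    da = ET.SubElement(pts, "DataArray", type="Float64", NumberOfComponents="3", format="ascii")
    da.text = _fmt(mesh.nodes)

    cells = ET.SubElement(piece, "Cells")
    conn = ET.SubElement(cells, "DataArray", type="Int64", Name="connectivity", format="ascii")
    conn.text = _fmt(mesh.tets)
    offs = ET.SubElement(cells, "DataArray", type="Int64", Name="offsets", format="ascii")
    offs.text = _fmt(4 * np.arange(1, mesh.n_elements + 1))
    typ = ET.SubElement(cells, "DataArray", type="UInt8", Name="types", format="ascii")
    typ.text = _fmt(np.full(mesh.n_elements, 10))  # VTK_TETRA

    def add_fields(parent_name: str, data: dict):
        parent = ET.SubElement(piece, parent_name)
        for name, arr in data.items():
            arr = np.asarray(arr)
            ncomp = 1 if arr.ndim == 1 else arr.shape[1]
            d = ET.SubElement(
                parent,
                "DataArray",
                type="Float64",
                Name=name,
                NumberOfComponents=str(ncomp),
                format="ascii",
            )
            d.text = _fmt(arr)

    add_fields("PointData", point_data)
    add_fields("CellData", cell_data)
    ET.ElementTree(root).write(str(path), xml_declaration=True, encoding="ascii")


def read_vtu(path) -> tuple[PoroMesh, dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Read an ASCII .vtu written by :func:`write_vtu`.

    Returns ``(mesh, point_data, cell_data)``; ``fiber``/``material_id``
    cell fields are folded back into the mesh.
    """
    root = ET.parse(str(path)).getroot()
    piece = root.find(".//Piece")
    nodes = np.fromstring(piece.find("Points/DataArray").text, sep=" ").reshape(-1, 3)
    conn = None
    for da in piece.find("Cells"):
        if da.get("Name") == "connectivity":
            conn = np.fromstring(da.text, sep=" ", dtype=int).reshape(-1, 4)

    def read_fields(tag):
        out = {}
        el = piece.find(tag)
        if el is None:
            return out
        for da in el:
            ncomp = int(da.get("NumberOfComponents", "1"))
            arr = np.fromstring(da.text, sep=" ")
            out[da.get("Name")] = arr.reshape(-1, ncomp) if ncomp > 1 else arr
        return out

    point_data = read_fields("PointData")
    cell_data = read_fields("CellData")
    fiber = cell_data.pop("fiber", None)
    mat = cell_data.pop("material_id", None)
    mesh = PoroMesh(nodes, conn, fiber, None if mat is None else mat.astype(int))
    return mesh, point_data, cell_data


def read_abaqus_inp(path) -> PoroMesh:
    """Minimal Abaqus .inp reader: *NODE and *ELEMENT (C3D4 / C3D4P) blocks.

    Node ids may be arbitrary; they are remapped to a contiguous range.
    """
    nodes: dict[int, list[float]] = {}
    elems: list[list[int]] = []
    mode = None
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("**"):
            continue
        if line.startswith("*"):
            kw = line.split(",")[0].strip().upper()
            if kw == "*NODE":
                mode = "node"
            elif kw == "*ELEMENT":
                etype = ""
                for part in line.split(",")[1:]:
                    k, _, v = part.partition("=")
                    if k.strip().upper() == "TYPE":
                        etype = v.strip().upper()
                if etype not in ("C3D4", "C3D4P"):
                    raise ValueError(f"unsupported element type {etype!r} (need C3D4/C3D4P)")
                mode = "element"
            else:
                mode = None
            continue
        vals = [v.strip() for v in line.split(",") if v.strip()]
        if mode == "node":
            nodes[int(vals[0])] = [float(v) for v in vals[1:4]]
        elif mode == "element":
            elems.append([int(v) for v in vals[1:5]])
    if not nodes or not elems:
        raise ValueError("no NODE/ELEMENT data found")
    ids = sorted(nodes)
    remap = {nid: i for i, nid in enumerate(ids)}
    coords = np.array([nodes[nid] for nid in ids])
    tets = np.array([[remap[n] for n in e] for e in elems])
    mesh = PoroMesh(coords, tets)
    mesh.fix_orientation()
    mesh.validate()
    return mesh
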