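"""Minimal ASCII VTU (VTK UnstructuredGrid XML) writer/reader for tet meshes.

Cell labels and any per-cell scalar/vector fields are written as CellData so
solutions open directly in standard VTK viewers.  Patch definitions are
carried in a FieldData byte array (JSON) that other tools simply ignore.
"""

from __future__ import annotations

import json
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np

from ..mesh import TetMesh

__all__ = ["write_vtu", "read_vtu"]


def _array_el(parent, name: str, data: np.ndarray, vtk_type: str) -> None:
    ncomp = 1 if data.ndim == 1 else data.shape[1]
    el = ET.SubElement(
        parent,
        "DataArray",
        type=vtk_type,
        Name=name,
        NumberOfComponents=str(ncomp),
        format="ascii",
    )
    flat = np.asarray(data).reshape(-1)
    if vtk_type.startswith("Float"):
        el.text = " ".join(f"{x:.17g}" for x in flat)
    else:
        el.text = " ".join(str(int(x)) for x in flat)


def write_vtu(
    mesh: TetMesh, path: str | Path, cell_fields: dict[str, np.ndarray] | None = None
) -> None:
    """Write mesh (+ per-cell fields, scalar or 3-vector) as ASCII .vtu."""
    root = ET.Element("VTKFile", type="UnstructuredGrid", version="0.1", byte_order="LittleEndian")
    grid = ET.SubElement(root, "UnstructuredGrid")

    fd = ET.SubElement(grid, "FieldData")
    patch_json = json.dumps({k: v.tolist() for k, v in mesh.patches.items()})
    patch_bytes = np.frombuffer(patch_json.encode(), dtype=np.uint8)
    _array_el(fd, "tesfv_patches", patch_bytes, "UInt8")

    piece = ET.SubElement(
        grid, "Piece", NumberOfPoints=str(mesh.n_points), NumberOfCells=str(mesh.n_cells)
    )
    pts = ET.SubElement(piece, "Points")
    _array_el(pts, "Points", mesh.points, "Float64")
    cells = ET.SubElement(piece, "Cells")
    _array_el(cells, "connectivity", mesh.cells.reshape(-1), "Int64")
    _array_el(cells, "offsets", 4 * np.arange(1, mesh.n_cells + 1), "Int64")
    _array_el(cells, "types", np.full(mesh.n_cells, 10), "UInt8")
    cd = ET.SubElement(piece, "CellData")
    _array_el(cd, "label", mesh.cell_labels, "Int64")
    for name, data in (cell_fields or {}).items():
        _array_el(cd, name, np.asarray(data, dtype=float), "Float64")
    ET.indent(root)
    ET.ElementTree(root).write(str(path), xml_declaration=True)


def read_vtu(path: str | Path) -> tuple[TetMesh, dict[str, np.ndarray]]:
    """Read a .vtu written by :func:`write_vtu`; returns (mesh, cell_fields)."""
    root = ET.parse(str(path)).getroot()
    piece = root.find(".//Piece")
    if piece is None:
        raise ValueError(f"{path}: no UnstructuredGrid Piece found")

    def arr(parent, name, dtype):
        el = parent.find(f"./DataArray[@Name='{name}']")
        if el is None:
            raise ValueError(f"{path}: missing DataArray {name}")
        return np.fromstring(el.text or "", sep=" ").astype(dtype)

    points = arr(piece.find("Points"), "Points", float).reshape(-1, 3)
    conn = arr(piece.find("Cells"), "connectivity", np.int64).reshape(-1, 4)
    types = arr(piece.find("Cells"), "types", np.int64)
    if not np.all(types == 10):
        raise ValueError(f"{path}: only tetrahedral (type 10) cells supported")
    cd = piece.find("CellData")
    labels = arr(cd, "label", np.int64)
    fields = {}
    for el in cd.findall("DataArray"):
        name = el.get("Name")
        if name == "label":
            continue
        ncomp = int(el.get("NumberOfComponents", "1"))
        data = np.fromstring(el.text or "", sep=" ")
        fields[name] = data.reshape(-1, ncomp) if ncomp > 1 else data

    patches = {}
    fd = root.find(".//FieldData/DataArray[@Name='tesfv_patches']")
    if fd is not None and fd.text:
        raw = bytes(int(x) for x in fd.text.split())
        patches = {k: np.array(v, dtype=np.int64) for k, v in json.loads(raw).items()}
    return TetMesh(points, conn, labels, patches), fields
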