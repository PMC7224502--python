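"""GMSH file format version 2.2 (ASCII) reader and writer.

Dialect: physical volume tag = compartment label, physical surface tag =
patch id, with patch names recorded in ``$PhysicalNames``.  Triangular patch
elements are written after the tetrahedra.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from ..mesh import TetMesh

__all__ = ["read_gmsh", "write_gmsh", "GmshParseError"]


class GmshParseError(ValueError):
    def __init__(self, path, line_no: int, msg: str):
        super().__init__(f"{path}:{line_no}: {msg}")
        self.line_no = line_no


def write_gmsh(mesh: TetMesh, path: str | Path) -> None:
    path = Path(path)
    patch_names = sorted(mesh.patches)
    patch_ids = {name: i + 1 for i, name in enumerate(patch_names)}
    lines = ["$MeshFormat", "2.2 0 8", "$EndMeshFormat"]
    lines.append("$PhysicalNames")
    lines.append(str(len(patch_names)))
    for name in patch_names:
        lines.append(f'2 {patch_ids[name]} "{name}"')
    lines.append("$EndPhysicalNames")
    lines.append("$Nodes")
    lines.append(str(mesh.n_points))
    for i, p in enumerate(mesh.points, start=1):
        lines.append(f"{i} {p[0]:.17g} {p[1]:.17g} {p[2]:.17g}")
    lines.append("$EndNodes")
    n_tri = sum(len(t) for t in mesh.patches.values())
    lines.append("$Elements")
    lines.append(str(mesh.n_cells + n_tri))
    eid = 1
    for c, lab in zip(mesh.cells + 1, mesh.cell_labels):
        lines.append(f"{eid} 4 2 {lab} {lab} {c[0]} {c[1]} {c[2]} {c[3]}")
        eid += 1
    for name in patch_names:
        pid = patch_ids[name]
        for t in mesh.patches[name] + 1:
            lines.append(f"{eid} 2 2 {pid} {pid} {t[0]} {t[1]} {t[2]}")
            eid += 1
    lines.append("$EndElements")
    path.write_text("\n".join(lines) + "\n")


def read_gmsh(path: str | Path) -> TetMesh:
    path = Path(path)
    lines = path.read_text().splitlines()
    i = 0

    def expect(section: str) -> None:
        nonlocal i
        while i < len(lines) and not lines[i].strip():
            i += 1
        if i >= len(lines) or lines[i].strip() != section:
            raise GmshParseError(path, i + 1, f"expected {section}")
        i += 1

    expect("$MeshFormat")
    fmt = lines[i].split()
    if not fmt or not fmt[0].startswith("2"):
        raise GmshParseError(path, i + 1, f"unsupported GMSH format version {fmt[0] if fmt else '?'} (only 2.x)")
    i += 1
    expect("$EndMeshFormat")

    patch_names: dict[int, str] = {}
    # optional $PhysicalNames
    j = i
    while j < len(lines) and not lines[j].strip():
        j += 1
    if j < len(lines) and lines[j].strip() == "$PhysicalNames":
        i = j + 1
        n = int(lines[i]); i += 1
        for _ in range(n):
            parts = lines[i].split(maxsplit=2)
            if len(parts) != 3:
                raise GmshParseError(path, i + 1, "malformed physical name")
            dim, tag, name = int(parts[0]), int(parts[1]), parts[2].strip().strip('"')
            if dim == 2:
                patch_names[tag] = name
            i += 1
        expect("$EndPhysicalNames")

    expect("$Nodes")
    try:
        n_nodes = int(lines[i])
    except ValueError:
        raise GmshParseError(path, i + 1, "bad node count") from None
    i += 1
    node_lines = lines[i : i + n_nodes]
    i += n_nodes
    expect("$EndNodes")
    data = np.loadtxt(node_lines, dtype=float).reshape(n_nodes, 4)
    ids = data[:, 0].astype(np.int64)
    id_map = np.full(ids.max() + 1, -1, dtype=np.int64)
    id_map[ids] = np.arange(n_nodes)
    points = data[:, 1:]

    expect("$Elements")
    n_elem = int(lines[i]); i += 1
    cells, cell_labels = [], []
    tris: dict[int, list] = {}
    for k in range(n_elem):
        parts = lines[i + k].split()
        try:
            etype = int(parts[1]); ntags = int(parts[2])
            tags = [int(x) for x in parts[3 : 3 + ntags]]
            nodes = [int(x) for x in parts[3 + ntags :]]
        except (IndexError, ValueError):
            raise GmshParseError(path, i + k + 1, "malformed element line") from None
        phys = tags[0] if tags else 0
        if etype == 4:
            cells.append(nodes)
            cell_labels.append(phys)
        elif etype == 2:
            tris.setdefault(phys, []).append(nodes)
        # other element types ignored
    i += n_elem
    expect("$EndElements")

    patches = {}
    for pid, t in tris.items():
        name = patch_names.get(pid, f"patch_{pid}")
        patches[name] = id_map[np.array(t, dtype=np.int64)]
    return TetMesh(
        points,
        id_map[np.array(cells, dtype=np.int64)],
        np.array(cell_labels, dtype=np.int64),
        patches,
    )
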