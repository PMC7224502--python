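"""Mesh, image and surface file I/O (GMSH v2.2, VTU, NIfTI/ANALYZE, STL/OFF)."""

from __future__ import annotations

from pathlib import Path

from ..image import read_label_image, write_label_image
from ..mesh import TetMesh
from ..surface import read_surface, write_surface
from .gmsh import GmshParseError, read_gmsh, write_gmsh
from .vtu import read_vtu, write_vtu

__all__ = [
    "read_mesh",
    "write_mesh",
    "read_gmsh",
    "write_gmsh",
    "read_vtu",
    "write_vtu",
    "read_label_image",
    "write_label_image",
    "read_surface",
    "write_surface",
    "GmshParseError",
]


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = path.suffix.lower()
    if ext == ".msh":
        return "gmsh2"
    if ext == ".vtu":
        return "vtu"
    raise ValueError(f"cannot infer mesh format from {path.name!r}; pass format=")


def read_mesh(path: str | Path, format: str | None = None) -> TetMesh:
    """Read a tetrahedral mesh from GMSH v2.2 (.msh) or VTU (.vtu)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "gmsh2":
        return read_gmsh(path)
    if fmt == "vtu":
        return read_vtu(path)[0]
    raise ValueError(f"unknown mesh format {fmt!r}")


def write_mesh(mesh: TetMesh, path: str | Path, format: str | None = None) -> None:
    """Write a tetrahedral mesh as GMSH v2.2 (.msh) or VTU (.vtu)."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "gmsh2":
        write_gmsh(mesh, path)
    elif fmt == "vtu":
        write_vtu(mesh, path)
    else:
        raise ValueError(f"unknown mesh format {fmt!r}")
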