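"""Triangulated surfaces: isosurface extraction, smoothing, and STL/OFF I/O.

Surfaces delimit the polyhedral subdomains of the hybrid meshing domain and
carry electrode geometry.  Closed (watertight) surfaces are required wherever
inside/outside queries are made.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from skimage.measure import marching_cubes

from .image import LabeledImage

__all__ = [
    "TriSurface",
    "extract_isosurface",
    "taubin_smooth",
    "laplacian_smooth",
    "read_surface",
    "write_surface",
]


@dataclass
class TriSurface:
    """A triangle mesh in mm coordinates.

    ``vertices`` is ``(nv, 3)`` float, ``triangles`` ``(nt, 3)`` int.  Use
    :meth:`is_watertight` before treating the surface as a closed domain
    boundary.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    name: str = "surface"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        if self.triangles.size and self.triangles.max() >= len(self.vertices):
            raise ValueError("triangle index out of range")
        if self.triangles.size and self.triangles.min() < 0:
            raise ValueError("negative triangle index")

    # -- basic geometry -------------------------------------------------
    def triangle_normals(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        return np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])

    def triangle_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(self.triangle_normals(), axis=1)

    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def enclosed_volume(self) -> float:
        """Signed enclosed volume via the divergence theorem (closed surface)."""
        v = self.vertices
        t = self.triangles
        return float(np.einsum("ij,ij->i", v[t[:, 0]], np.cross(v[t[:, 1]], v[t[:, 2]])).sum() / 6.0)

    def edges(self) -> np.ndarray:
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
        return np.sort(e, axis=1)

    def is_watertight(self) -> bool:
        """True iff every edge is shared by exactly two triangles."""
        if len(self.triangles) == 0:
            return False
        _, counts = np.unique(self.edges(), axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def boundary_edges(self) -> np.ndarray:
        """Edges used by exactly one triangle (open boundary loops)."""
        e, counts = np.unique(self.edges(), axis=0, return_counts=True)
        return e[counts == 1]

    def cleaned(self, merge_tol: float = 1e-9) -> "TriSurface":
        """Merge duplicate vertices and drop degenerate (zero-area) triangles."""
        tm = self.to_trimesh()
        tm.merge_vertices(merge_tex=True, merge_norm=True, digits_vertex=9)
        areas = tm.area_faces if len(tm.faces) else np.zeros(0)
        tm.update_faces(areas > merge_tol**2)
        tm.remove_unreferenced_vertices()
        return TriSurface(np.asarray(tm.vertices), np.asarray(tm.faces), self.name)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.triangles.copy(), process=False)

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, name: str = "surface") -> "TriSurface":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), name)


def extract_isosurface(image: LabeledImage, label: int) -> TriSurface:
    """Marching-cubes boundary of one label, as a closed surface in mm.

    The indicator volume of ``label`` is contoured at iso-level 0.5.  The
    volume is padded by one background voxel so surfaces touching the grid
    edge still close.
    """
    mask = image.labels == label
    if not mask.any():
        raise ValueError(f"label {label} not present in image")
    padded = np.pad(mask.astype(np.float32), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5)
    verts = (verts - 1.0) * image.spacing + image.origin
    return TriSurface(verts, faces, name=f"label_{label}")


def _umbrella_step(vertices: np.ndarray, triangles: np.ndarray, factor: float) -> np.ndarray:
    """One Laplacian step with uniform (umbrella) weights; isolated vertices fixed."""
    e = np.concatenate([triangles[:, [0, 1]], triangles[:, [1, 2]], triangles[:, [2, 0]]])
    e = np.unique(np.sort(e, axis=1), axis=0)
    n = len(vertices)
    acc = np.zeros_like(vertices)
    deg = np.zeros(n)
    np.add.at(acc, e[:, 0], vertices[e[:, 1]])
    np.add.at(acc, e[:, 1], vertices[e[:, 0]])
    np.add.at(deg, e[:, 0], 1)
    np.add.at(deg, e[:, 1], 1)
    moved = vertices.copy()
    has = deg > 0
    mean = acc[has] / deg[has, None]
    moved[has] += factor * (mean - vertices[has])
    return moved


def taubin_smooth(
    surface: TriSurface, lam: float = 0.5, mu: float = -0.53, steps: int = 50
) -> TriSurface:
    """Taubin shrink-compensating smoothing (alternating lambda/mu passes).

    Defaults (0.5, -0.53, 50) are the values used for smoothing
    marching-cubes tissue surfaces before surface-based meshing.  Uniform
    umbrella weights; mesh connectivity is unchanged.
    """
    v = surface.vertices.copy()
    for _ in range(steps):
        v = _umbrella_step(v, surface.triangles, lam)
        v = _umbrella_step(v, surface.triangles, mu)
    return TriSurface(v, surface.triangles.copy(), surface.name)


def laplacian_smooth(surface: TriSurface, lam: float = 0.5, steps: int = 50) -> TriSurface:
    """Plain (shrinking) Laplacian smoothing, mostly for contrast with Taubin."""
    v = surface.vertices.copy()
    for _ in range(steps):
        v = _umbrella_step(v, surface.triangles, lam)
    return TriSurface(v, surface.triangles.copy(), surface.name)


def write_surface(surface: TriSurface, path: str | Path) -> None:
    """Write STL (ASCII for ``.stl``) or OFF, chosen by extension."""
    path = Path(path)
    tm = surface.to_trimesh()
    ext = path.suffix.lower()
    if ext == ".off":
        path.write_bytes(trimesh.exchange.off.export_off(tm).encode())
    elif ext == ".stl":
        path.write_bytes(trimesh.exchange.stl.export_stl_ascii(tm).encode())
    else:
        raise ValueError(f"unsupported surface format: {ext}")


def read_surface(path: str | Path, name: str | None = None) -> TriSurface:
    """Read STL (binary or ASCII) or OFF.

    STL files store one vertex triple per facet; coincident vertices are
    merged on load so the shared topology is recovered.
    """
    path = Path(path)
    ext = path.suffix.lower()
    if ext not in {".off", ".stl"}:
        raise ValueError(f"unsupported surface format: {ext}")
    tm = trimesh.load(str(path), process=False, force="mesh")
    if ext == ".stl":
        tm.merge_vertices()
    return TriSurface(np.asarray(tm.vertices), np.asarray(tm.faces), name or path.stem)
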