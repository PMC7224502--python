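"""Tetrahedral volume meshes: the computational domain of the solver.

A :class:`TetMesh` is a flat array-of-cells representation with one integer
compartment label per cell and named *patches*: sets of triangular faces on
the outer boundary (e.g. ``scalp``, ``anode_outer``) or on internal
compartment interfaces (e.g. ``anode_contact``).

:class:`MeshGeometry` derives the finite-volume connectivity — cell
centroids/volumes, internal owner/neighbour face pairs and oriented boundary
faces — once, so assembly, gradients, quality metrics and current
integration all share it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = ["TetMesh", "MeshGeometry", "build_interface_patches"]

# local vertex triples of the 4 faces of tet (v0,v1,v2,v3), outward for a
# positively oriented cell (det[v1-v0, v2-v0, v3-v0] > 0)
_TET_FACES = np.array([[1, 2, 3], [0, 3, 2], [0, 1, 3], [0, 2, 1]])


def _face_keys(tris: np.ndarray) -> np.ndarray:
    """Orientation-independent sortable keys for vertex triples."""
    s = np.sort(tris, axis=1)
    return s[:, 0].astype(np.int64) * (1 << 42) + s[:, 1].astype(np.int64) * (1 << 21) + s[:, 2]


@dataclass
class TetMesh:
    """Tetrahedral mesh with per-cell compartment labels and named face patches."""

    points: np.ndarray
    cells: np.ndarray
    cell_labels: np.ndarray
    patches: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.cells = np.asarray(self.cells, dtype=np.int64).reshape(-1, 4)
        self.cell_labels = np.asarray(self.cell_labels, dtype=np.int64).reshape(-1)
        if len(self.cell_labels) != len(self.cells):
            raise ValueError("cell_labels length must match cells")
        self.patches = {k: np.asarray(v, dtype=np.int64).reshape(-1, 3) for k, v in self.patches.items()}

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def signed_volumes(self) -> np.ndarray:
        p = self.points
        c = self.cells
        a = p[c[:, 1]] - p[c[:, 0]]
        b = p[c[:, 2]] - p[c[:, 0]]
        d = p[c[:, 3]] - p[c[:, 0]]
        return np.einsum("ij,ij->i", a, np.cross(b, d)) / 6.0

    def oriented(self) -> "TetMesh":
        """Copy with every cell positively oriented (signed volume > 0)."""
        vol = self.signed_volumes()
        cells = self.cells.copy()
        flip = vol < 0
        cells[flip] = cells[flip][:, [0, 1, 3, 2]]
        return TetMesh(self.points, cells, self.cell_labels, self.patches)

    def cell_centroids(self) -> np.ndarray:
        return self.points[self.cells].mean(axis=1)

    @cached_property
    def geometry(self) -> "MeshGeometry":
        return MeshGeometry(self)

    def with_labels(self, labels: np.ndarray) -> "TetMesh":
        return TetMesh(self.points, self.cells, labels, dict(self.patches))


class MeshGeometry:
    """Face connectivity and metric quantities of a :class:`TetMesh`.

    Internal face area vectors point owner -> neighbour, boundary face area
    vectors point outward.  Patch names resolve to face indices: boundary
    patches into the boundary-face arrays, interface patches into the
    internal-face arrays.
    """

    def __init__(self, mesh: TetMesh):
        vol = mesh.signed_volumes()
        if np.any(vol <= 0):
            raise ValueError(f"{int((vol <= 0).sum())} cells are not positively oriented")
        self.mesh = mesh
        p, c = mesh.points, mesh.cells
        self.cell_volumes = vol
        self.cell_centroids = p[c].mean(axis=1)

        tris = c[:, _TET_FACES].reshape(-1, 3)  # 4*nc faces, outward-ordered
        keys = _face_keys(tris)
        order = np.argsort(keys, kind="stable")
        sk = keys[order]
        # group identical keys: first/second occurrence in sorted order
        is_first = np.ones(len(sk), dtype=bool)
        is_first[1:] = sk[1:] != sk[:-1]
        group_start = np.flatnonzero(is_first)
        group_size = np.diff(np.append(group_start, len(sk)))
        if np.any(group_size > 2):
            raise ValueError("non-manifold mesh: a face is shared by more than 2 cells")

        first_idx = order[group_start]
        cell_of = first_idx // 4
        internal = group_size == 2
        second_idx = order[np.minimum(group_start + 1, len(sk) - 1)]

        self.int_owner = cell_of[internal]
        self.int_neighbour = second_idx[internal] // 4
        self.int_tris = tris[first_idx[internal]]  # oriented outward from owner
        self.bnd_owner = cell_of[~internal]
        self.bnd_tris = tris[first_idx[~internal]]  # outward from owner = outward of mesh

        self.int_area_vec = self._area_vec(self.int_tris)
        self.int_centroid = p[self.int_tris].mean(axis=1)
        self.bnd_area_vec = self._area_vec(self.bnd_tris)
        self.bnd_centroid = p[self.bnd_tris].mean(axis=1)

        self._int_keys = _face_keys(self.int_tris)
        self._int_sorter = np.argsort(self._int_keys)
        self._bnd_keys = _face_keys(self.bnd_tris)
        self._bnd_sorter = np.argsort(self._bnd_keys)

    def _area_vec(self, tris: np.ndarray) -> np.ndarray:
        p = self.mesh.points
        return 0.5 * np.cross(p[tris[:, 1]] - p[tris[:, 0]], p[tris[:, 2]] - p[tris[:, 0]])

    @property
    def n_internal_faces(self) -> int:
        return len(self.int_owner)

    @property
    def n_boundary_faces(self) -> int:
        return len(self.bnd_owner)

    def _lookup(self, tris: np.ndarray, keys: np.ndarray, sorter: np.ndarray, kind: str) -> np.ndarray:
        want = _face_keys(np.asarray(tris).reshape(-1, 3))
        pos = np.searchsorted(keys, want, sorter=sorter)
        pos = np.clip(pos, 0, len(keys) - 1)
        idx = sorter[pos]
        if np.any(keys[idx] != want):
            raise KeyError(f"patch face not found among {kind} faces")
        return idx

    def boundary_face_indices(self, patch: str) -> np.ndarray:
        """Boundary-face indices of a named boundary patch."""
        tris = self.mesh.patches[patch]
        return self._lookup(tris, self._bnd_keys, self._bnd_sorter, "boundary")

    def internal_face_indices(self, patch: str) -> np.ndarray:
        """Internal-face indices of a named interface patch."""
        tris = self.mesh.patches[patch]
        return self._lookup(tris, self._int_keys, self._int_sorter, "internal")

    def patch_is_boundary(self, patch: str) -> bool:
        tris = self.mesh.patches[patch]
        if len(tris) == 0:
            return True
        want = _face_keys(tris[:1])
        pos = np.searchsorted(self._bnd_keys, want, sorter=self._bnd_sorter)
        pos = np.clip(pos, 0, len(self._bnd_keys) - 1)
        return bool(self._bnd_keys[self._bnd_sorter[pos]] == want)


def build_interface_patches(mesh: TetMesh, boundary_name: str = "boundary") -> TetMesh:
    """Recompute patches from cell labels.

    The exterior surface becomes one patch (``boundary_name``); every internal
    face separating two different labels joins a patch named
    ``interface_<a>_<b>`` with a < b.
    """
    geo = MeshGeometry(mesh)
    patches: dict[str, np.ndarray] = {boundary_name: geo.bnd_tris.copy()}
    lo = mesh.cell_labels[geo.int_owner]
    ln = mesh.cell_labels[geo.int_neighbour]
    diff = lo != ln
    if diff.any():
        a = np.minimum(lo[diff], ln[diff])
        b = np.maximum(lo[diff], ln[diff])
        tris = geo.int_tris[diff]
        pair_key = a * (b.max() + 1) + b
        for key in np.unique(pair_key):
            sel = pair_key == key
            patches[f"interface_{a[sel][0]}_{b[sel][0]}"] = tris[sel]
    return TetMesh(mesh.points, mesh.cells, mesh.cell_labels, patches)
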