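"""Synthetic phantoms: layered spheres and slabs, as images and as meshes.

These generators stand in for the MRI segmentation and Delaunay meshing
stages of a full head-modelling pipeline, providing analytically known
geometry for verification.  The canonical phantom is the 3-layered spherical
head model (scalp/skull/brain) used for the analytic validation of the
solver.

Meshing here is deliberately structured rather than Delaunay-based:

* layered spheres are meshed body-fitted by radially extruding an icosphere,
  so compartment interfaces lie *exactly* at the model radii;
* labeled images are meshed by splitting each voxel into six Kuhn simplices,
  whose face diagonals agree between neighbouring voxels, so the mesh is
  conforming by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Callable, Iterable, Sequence

import numpy as np
import trimesh

from .image import LabeledImage
from .mesh import MeshGeometry, TetMesh

__all__ = [
    "LayeredSphereModel",
    "three_layer_head_model",
    "generate_layered_sphere_image",
    "generate_layered_sphere_mesh",
    "tetrahedralize_labeled_image",
    "slab_mesh",
    "tag_boundary_patch",
]


@dataclass
class LayeredSphereModel:
    """Concentric spherical shells: radii strictly decreasing outer -> inner."""

    radii: np.ndarray
    conductivities: np.ndarray
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        self.conductivities = np.asarray(self.conductivities, dtype=float).reshape(-1)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if len(self.radii) != len(self.conductivities):
            raise ValueError("radii and conductivities must have equal length")
        if np.any(np.diff(self.radii) >= 0):
            raise ValueError("radii must be strictly decreasing outer -> inner")
        if np.any(self.conductivities <= 0):
            raise ValueError("conductivities must be positive")

    @property
    def n_layers(self) -> int:
        return len(self.radii)

    def shrunk(self, margin: float) -> "LayeredSphereModel":
        """Model with the outer radius reduced by ``margin`` mm (other shells kept)."""
        radii = self.radii.copy()
        radii[0] -= margin
        return LayeredSphereModel(radii, self.conductivities.copy(), self.center.copy())


def three_layer_head_model(numerical_outer: bool = False) -> LayeredSphereModel:
    """The standard 3-layered spherical head phantom.

    Scalp 92 mm / 0.465 S/m, skull 85 mm / 0.01 S/m, brain 80 mm / 0.33 S/m.
    With ``numerical_outer=True`` the outer radius is 90 mm, the 2 mm smaller
    sphere actually meshed for the numerical verification (the analytic
    point-electrode solution lives on the 92 mm sphere and supplies boundary
    data on the 90 mm one).
    """
    outer = 90.0 if numerical_outer else 92.0
    return LayeredSphereModel(
        radii=np.array([outer, 85.0, 80.0]),
        conductivities=np.array([0.465, 0.01, 0.33]),
    )


def generate_layered_sphere_image(model: LayeredSphereModel, spacing: float) -> LabeledImage:
    """Voxelize a layered sphere: label = 1-based index of the innermost layer
    whose radius still covers the voxel center; 0 outside the outermost radius."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    r_out = model.radii[0]
    n = int(np.ceil(2 * (r_out + spacing) / spacing)) + 1
    origin = model.center - (n - 1) / 2 * spacing
    idx = np.indices((n, n, n))
    d = np.sqrt(
        ((idx[0] * spacing + origin[0] - model.center[0]) ** 2)
        + ((idx[1] * spacing + origin[1] - model.center[1]) ** 2)
        + ((idx[2] * spacing + origin[2] - model.center[2]) ** 2)
    )
    labels = (d[None, :, :, :] <= model.radii[:, None, None, None]).sum(axis=0)
    return LabeledImage(labels.astype(np.int16), np.full(3, float(spacing)), origin)


# ---------------------------------------------------------------------------
# body-fitted layered sphere mesh
# ---------------------------------------------------------------------------

# prism symmetries used to rotate the globally smallest vertex to slot 0
_PRISM_ROTATIONS = np.array(
    [
        [0, 1, 2, 3, 4, 5],
        [1, 2, 0, 4, 5, 3],
        [2, 0, 1, 5, 3, 4],
        [3, 5, 4, 0, 2, 1],
        [4, 3, 5, 1, 0, 2],
        [5, 4, 3, 2, 1, 0],
    ]
)


def _split_prisms(prisms: np.ndarray) -> np.ndarray:
    """Split triangular prisms into 3 tets each with conforming quad diagonals.

    Quad-face diagonals are chosen by the smallest-global-vertex rule, so two
    prisms sharing a quad face pick the same diagonal and the resulting tet
    mesh is conforming.
    """
    n = len(prisms)
    rot = _PRISM_ROTATIONS[np.argmin(prisms, axis=1)]
    v = prisms[np.arange(n)[:, None], rot]
    case_a = np.minimum(v[:, 1], v[:, 5]) < np.minimum(v[:, 2], v[:, 4])
    tets = np.empty((n, 3, 4), dtype=np.int64)
    a = v[case_a]
    tets[case_a] = np.stack(
        [a[:, [0, 1, 2, 5]], a[:, [0, 1, 5, 4]], a[:, [0, 4, 5, 3]]], axis=1
    )
    b = v[~case_a]
    tets[~case_a] = np.stack(
        [b[:, [0, 1, 2, 4]], b[:, [0, 4, 2, 5]], b[:, [0, 4, 5, 3]]], axis=1
    )
    return tets.reshape(-1, 4)


def _radial_ladder(
    model: LayeredSphereModel, radial_layers: Sequence[int], grading: float
) -> tuple[np.ndarray, np.ndarray]:
    """Radii of all spherical node shells (descending) and per-gap region index."""
    radii = list(model.radii)
    shells: list[float] = []
    region_of_gap: list[int] = []
    for i, k in enumerate(radial_layers):
        outer = radii[i]
        inner = radii[i + 1] if i + 1 < len(radii) else 0.0
        if k < 1:
            raise ValueError("each shell needs at least one radial layer")
        if outer - inner <= 0:
            raise ValueError("zero-thickness shell in radial layering")
        if i + 1 < len(radii):
            sub = outer + (inner - outer) * np.arange(k) / k
        else:
            # innermost region: graded toward the center, last gap is the apex cap
            frac = (np.arange(k, 0, -1) / k) ** grading
            sub = outer * frac
        shells.extend(sub.tolist())
        region_of_gap.extend([i] * k)
    return np.array(shells), np.array(region_of_gap)


def generate_layered_sphere_mesh(
    model: LayeredSphereModel,
    subdivisions: int = 3,
    radial_layers: Sequence[int] | None = None,
    grading: float = 1.0,
) -> TetMesh:
    """Body-fitted tetrahedral mesh of a layered sphere.

    An icosphere (``subdivisions`` levels) provides the angular triangulation;
    node shells are placed at every model radius plus ``radial_layers[i]``
    subdivisions inside shell ``i`` (the last entry covers the innermost
    region down to the center, graded by ``radius ~ (j/k)**grading``).  Every
    compartment interface is an exact sphere at its model radius.  Cell labels
    are 1-based from the outside in; the outer boundary is patch ``"outer"``.
    """
    if subdivisions < 2:
        raise ValueError("subdivisions must be >= 2")
    if radial_layers is None:
        h = model.radii[0] * 1.05 / 2**subdivisions
        radial_layers = []
        radii = list(model.radii) + [0.0]
        for i in range(model.n_layers):
            thick = radii[i] - radii[i + 1]
            radial_layers.append(max(1, int(np.ceil(thick / h))))
    if len(radial_layers) != model.n_layers:
        raise ValueError("radial_layers needs one entry per model layer")

    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    unit = np.asarray(ico.vertices)
    unit /= np.linalg.norm(unit, axis=1, keepdims=True)
    faces = np.asarray(ico.faces)
    nv = len(unit)

    shells, region_of_gap = _radial_ladder(model, radial_layers, grading)
    ns = len(shells)
    points = np.concatenate([(shells[:, None, None] * unit[None]).reshape(-1, 3),
                             np.zeros((1, 3))]) + model.center
    center_id = ns * nv

    cells = []
    labels = []
    for g in range(ns - 1):
        top = g * nv + faces  # outer shell of the gap
        bot = (g + 1) * nv + faces
        prisms = np.concatenate([bot, top], axis=1)  # bottom=inner, top=outer
        tets = _split_prisms(prisms)
        cells.append(tets)
        labels.append(np.full(len(tets), region_of_gap[g] + 1))
    # apex cap: innermost shell to the center point
    cap = np.concatenate(
        [np.full((len(faces), 1), center_id), (ns - 1) * nv + faces], axis=1
    )
    cells.append(cap)
    labels.append(np.full(len(cap), region_of_gap[-1] + 1))

    mesh = TetMesh(
        points,
        np.concatenate(cells),
        np.concatenate(labels),
        patches={"outer": faces.copy()},
    ).oriented()
    return mesh


# ---------------------------------------------------------------------------
# labeled-image meshing (Kuhn simplices)
# ---------------------------------------------------------------------------

_KUHN_PERMS = list(permutations(range(3)))


def _kuhn_corner_indices() -> np.ndarray:
    """Local corner index (0..7, bit i = axis i) of the 6 Kuhn tets."""
    tets = []
    for perm in _KUHN_PERMS:
        c = np.zeros(3, dtype=int)
        verts = [0]
        for ax in perm:
            c = c.copy()
            c[ax] = 1
            verts.append(c[0] | (c[1] << 1) | (c[2] << 2))
        tets.append(verts)
    return np.array(tets)


_KUHN_TETS = _kuhn_corner_indices()


def tetrahedralize_labeled_image(
    image: LabeledImage, exclude_labels: Iterable[int] = (0,)
) -> TetMesh:
    """Mesh every retained voxel as six Kuhn tetrahedra (conforming by design).

    Cell label = voxel label; the exterior surface becomes the ``"boundary"``
    patch.  ``exclude_labels`` (default: background 0) are dropped.
    """
    exclude = set(int(x) for x in exclude_labels)
    keep = ~np.isin(image.labels, list(exclude)) if exclude else np.ones_like(image.labels, bool)
    vi, vj, vk = np.nonzero(keep)
    if len(vi) == 0:
        raise ValueError("no voxels retained after exclusion")
    nx, ny, nz = image.dims
    gx, gy, gz = nx + 1, ny + 1, nz + 1

    def gid(i, j, k):
        return (i * gy + j) * gz + k

    # 8 corner grid ids per voxel, bit order (x, y, z)
    corners = np.stack(
        [gid(vi + (b & 1), vj + ((b >> 1) & 1), vk + ((b >> 2) & 1)) for b in range(8)],
        axis=1,
    )
    cells = corners[:, _KUHN_TETS].reshape(-1, 4)
    labels = np.repeat(image.labels[vi, vj, vk], 6)

    used, cells = np.unique(cells, return_inverse=True)
    cells = cells.reshape(-1, 4)
    ui = used // (gy * gz)
    uj = (used // gz) % gy
    uk = used % gz
    half = image.spacing / 2.0
    points = image.origin - half + np.stack([ui, uj, uk], axis=1) * image.spacing

    mesh = TetMesh(points, cells, labels).oriented()
    geo = MeshGeometry(mesh)
    mesh.patches = {"boundary": geo.bnd_tris.copy()}
    return mesh


def ortho_box_mesh(
    shape: tuple[int, int, int],
    spacing: float = 1.0,
    label_of_k: Callable[[np.ndarray], np.ndarray] | None = None,
) -> TetMesh:
    """Fully *orthogonal* tetrahedral box: 24 tets per voxel.

    Each voxel is split barycentrically (corners + 6 face centers + its
    center): every internal face then separates two mirror-image tets, so the
    centroid line is exactly parallel to the face normal everywhere — the
    non-orthogonality of every face is 0 and the 2-point flux stencil is
    exact.  The ``zmin``/``zmax`` end patches are tagged.
    """
    nx, ny, nz = shape
    sp_ = float(spacing)
    # point blocks: corners, x-faces, y-faces, z-faces, centers
    cg = np.stack(np.meshgrid(*[np.arange(n + 1) for n in shape], indexing="ij"), -1).reshape(-1, 3)
    xf = np.stack(np.meshgrid(np.arange(nx + 1), np.arange(ny), np.arange(nz), indexing="ij"), -1).reshape(-1, 3)
    yf = np.stack(np.meshgrid(np.arange(nx), np.arange(ny + 1), np.arange(nz), indexing="ij"), -1).reshape(-1, 3)
    zf = np.stack(np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz + 1), indexing="ij"), -1).reshape(-1, 3)
    cc = np.stack(np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"), -1).reshape(-1, 3)
    pts = np.concatenate(
        [
            cg * sp_,
            (xf + [0.0, 0.5, 0.5]) * sp_,
            (yf + [0.5, 0.0, 0.5]) * sp_,
            (zf + [0.5, 0.5, 0.0]) * sp_,
            (cc + [0.5, 0.5, 0.5]) * sp_,
        ]
    ) - sp_ / 2.0  # voxel-center convention: voxel (0,0,0) center at origin

    n_c = len(cg)
    off_x, off_y, off_z = n_c, n_c + len(xf), n_c + len(xf) + len(yf)
    off_cc = off_z + len(zf)

    def corner(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    def xface(i, j, k):
        return off_x + (i * ny + j) * nz + k

    def yface(i, j, k):
        return off_y + (i * (ny + 1) + j) * nz + k

    def zface(i, j, k):
        return off_z + (i * ny + j) * (nz + 1) + k

    vi, vj, vk = [a.reshape(-1) for a in np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")]
    center = off_cc + (vi * ny + vj) * nz + vk
    cells = []
    # 6 faces of the voxel; each contributes 4 tets (edge, face center, cell center)
    faces6 = [
        (xface(vi, vj, vk), [corner(vi, vj, vk), corner(vi, vj + 1, vk), corner(vi, vj + 1, vk + 1), corner(vi, vj, vk + 1)]),
        (xface(vi + 1, vj, vk), [corner(vi + 1, vj, vk), corner(vi + 1, vj + 1, vk), corner(vi + 1, vj + 1, vk + 1), corner(vi + 1, vj, vk + 1)]),
        (yface(vi, vj, vk), [corner(vi, vj, vk), corner(vi + 1, vj, vk), corner(vi + 1, vj, vk + 1), corner(vi, vj, vk + 1)]),
        (yface(vi, vj + 1, vk), [corner(vi, vj + 1, vk), corner(vi + 1, vj + 1, vk), corner(vi + 1, vj + 1, vk + 1), corner(vi, vj + 1, vk + 1)]),
        (zface(vi, vj, vk), [corner(vi, vj, vk), corner(vi + 1, vj, vk), corner(vi + 1, vj + 1, vk), corner(vi, vj + 1, vk)]),
        (zface(vi, vj, vk + 1), [corner(vi, vj, vk + 1), corner(vi + 1, vj, vk + 1), corner(vi + 1, vj + 1, vk + 1), corner(vi, vj + 1, vk + 1)]),
    ]
    for fc, quad in faces6:
        for e in range(4):
            a, b = quad[e], quad[(e + 1) % 4]
            cells.append(np.stack([a, b, fc, center], axis=1))
    cells = np.concatenate(cells)
    vox_labels = np.ones(len(vi), dtype=np.int64)
    if label_of_k is not None:
        vox_labels = np.asarray(label_of_k(vk), dtype=np.int64)
    labels = np.tile(vox_labels, 24)

    mesh = TetMesh(pts, cells, labels).oriented()
    geo = MeshGeometry(mesh)
    mesh.patches = {"boundary": geo.bnd_tris.copy()}
    zmin, zmax = -sp_ / 2, (nz - 0.5) * sp_
    mesh = tag_boundary_patch(mesh, "zmin", lambda c, n: np.isclose(c[:, 2], zmin))
    mesh = tag_boundary_patch(mesh, "zmax", lambda c, n: np.isclose(c[:, 2], zmax))
    return mesh


def slab_mesh(
    shape: tuple[int, int, int] = (4, 4, 8),
    spacing: float = 1.0,
    label_of_k: Callable[[np.ndarray], np.ndarray] | None = None,
) -> TetMesh:
    """Rectangular slab of Kuhn-split voxels with ``zmin``/``zmax`` end patches.

    ``label_of_k`` maps the voxel k-index array to labels (default: all 1),
    e.g. a two-layer slab for the series-resistance solver check.
    """
    labels = np.ones(shape, dtype=np.int16)
    if label_of_k is not None:
        kk = np.broadcast_to(np.arange(shape[2]), shape).astype(np.int64)
        labels = label_of_k(kk).astype(np.int16)
    img = LabeledImage(labels, np.full(3, spacing), np.zeros(3))
    mesh = tetrahedralize_labeled_image(img, exclude_labels=())
    zmin = -spacing / 2
    zmax = (shape[2] - 0.5) * spacing
    mesh = tag_boundary_patch(mesh, "zmin", lambda c, n: np.isclose(c[:, 2], zmin))
    mesh = tag_boundary_patch(mesh, "zmax", lambda c, n: np.isclose(c[:, 2], zmax))
    return mesh


def tag_boundary_patch(
    mesh: TetMesh,
    name: str,
    selector: Callable[[np.ndarray, np.ndarray], np.ndarray],
) -> TetMesh:
    """Add a boundary patch of the faces where ``selector(centroids, normals)``.

    ``selector`` receives the boundary-face centroids and outward unit
    normals and returns a boolean mask.
    """
    geo = mesh.geometry
    normals = geo.bnd_area_vec / np.linalg.norm(geo.bnd_area_vec, axis=1, keepdims=True)
    sel = np.asarray(selector(geo.bnd_centroid, normals), dtype=bool)
    if not sel.any():
        raise ValueError(f"selector matched no boundary faces for patch {name!r}")
    patches = dict(mesh.patches)
    patches[name] = geo.bnd_tris[sel]
    return TetMesh(mesh.points, mesh.cells, mesh.cell_labels, patches)
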