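"""Electrode placement and modeling on a scalp surface.

The international 10-20 system is constructed from four fiducials (nasion,
inion, left/right tragus): the vertex Cz is the fixed point at which the
nasion-inion and tragus-tragus surface arcs have a common midpoint, and all
other positions sit at 10%/20% arc-length fractions of the sagittal,
coronal and circumferential curves.  Arcs are geodesic in the plane-section
sense: each curve is the intersection of the scalp surface with the plane
through its two endpoints and Cz (or the appropriate third anchor).

Electrode bodies are built from a planar footprint (rectangle, circle, or
polygon) swept along the outward surface normal at the target position:
the scalp patch inside the swept prism is clipped exactly, then extruded
outward in 1 mm steps to the requested thickness; the final offset layer is
the equipotential outer surface.  For volume meshes an electrode can instead
be stamped directly into the outermost cell layer
(:func:`tag_electrode_on_mesh`), producing the ``<name>_outer`` and
``<name>_contact`` patches the solver's boundary conditions refer to.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import shapely
import shapely.geometry as sg
import trimesh

from .mesh import TetMesh, build_interface_patches
from .surface import TriSurface

__all__ = [
    "FiducialSet",
    "ElectrodeSpec",
    "locate_1020",
    "clip_patch",
    "extrude_electrode",
    "tag_electrode_on_mesh",
]


@dataclass
class FiducialSet:
    """The four 10-20 anchor landmarks, on (or projected onto) the scalp."""

    nasion: np.ndarray
    inion: np.ndarray
    tragus_left: np.ndarray
    tragus_right: np.ndarray

    def __post_init__(self) -> None:
        for name in ("nasion", "inion", "tragus_left", "tragus_right"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float).reshape(3))
        pts = np.stack([self.nasion, self.inion, self.tragus_left, self.tragus_right])
        if len(np.unique(np.round(pts, 9), axis=0)) != 4:
            raise ValueError("fiducial points must be distinct")
        a = self.inion - self.nasion
        b = self.tragus_right - self.tragus_left
        if np.linalg.norm(np.cross(a, b)) < 1e-9 * np.linalg.norm(a) * np.linalg.norm(b):
            raise ValueError("nasion-inion and tragus-tragus chords are parallel")


@dataclass
class ElectrodeSpec:
    """Electrode geometry + role.  ``position`` is a 10-20 label or an
    explicit scalp point; footprints are given in the local tangent frame."""

    name: str
    shape: Literal["rect", "circle", "polygon"]
    dims: tuple | np.ndarray  # rect: (width, height) mm; circle: (radius,); polygon: (k,2) vertices
    thickness: float = 2.0
    position: str | np.ndarray = "Cz"
    role: Literal["anode", "cathode"] = "anode"

    def footprint_polygon(self, n_segments: int = 64) -> sg.Polygon:
        if self.shape == "rect":
            w, h = (float(x) for x in self.dims)
            poly = sg.box(-w / 2, -h / 2, w / 2, h / 2)
        elif self.shape == "circle":
            (r,) = (float(x) for x in np.atleast_1d(self.dims))
            ang = np.linspace(0, 2 * np.pi, n_segments, endpoint=False)
            poly = sg.Polygon(np.column_stack([r * np.cos(ang), r * np.sin(ang)]))
        elif self.shape == "polygon":
            poly = sg.Polygon(np.asarray(self.dims, dtype=float))
        else:
            raise ValueError(f"unknown electrode shape {self.shape!r}")
        if poly.area <= 0:
            raise ValueError("electrode footprint must have positive area")
        if self.thickness < 1.0:
            raise ValueError("electrode thickness must be at least 1 mm")
        return poly


# ---------------------------------------------------------------------------
# 10-20 positioning
# ---------------------------------------------------------------------------


def _plane_loop(surface: TriSurface, origin: np.ndarray, normal: np.ndarray, near: np.ndarray) -> np.ndarray:
    """Closed polyline of the surface/plane intersection loop nearest ``near``."""
    v = surface.vertices
    t = surface.triangles
    d = (v - origin) @ normal
    # symbolic perturbation: no vertex lies exactly on the plane, so every
    # crossing triangle yields exactly one clean segment
    scale = np.abs(d).max() or 1.0
    d = np.where(np.abs(d) < 1e-12 * scale, 1e-12 * scale, d)
    dt = d[t]
    crossing = ~(np.all(dt > 0, axis=1) | np.all(dt < 0, axis=1))
    segs = []
    for tri in t[crossing]:
        pts = []
        for i in range(3):
            a, b = tri[i], tri[(i + 1) % 3]
            da, db = d[a], d[b]
            if (da > 0) != (db > 0):
                w = da / (da - db)
                pts.append(v[a] + w * (v[b] - v[a]))
        if len(pts) == 2:
            segs.append((pts[0], pts[1]))
    if not segs:
        raise ValueError("plane does not intersect the surface")
    # chain segments into loops by matching rounded endpoints
    key = lambda p: tuple(np.round(p, 7))
    adj: dict[tuple, list[np.ndarray]] = {}
    for a, b in segs:
        adj.setdefault(key(a), []).append(b)
        adj.setdefault(key(b), []).append(a)
    loops = []
    visited: set[tuple] = set()
    for start in list(adj):
        if start in visited:
            continue
        # every intersection vertex has two neighbours on a closed surface:
        # walk forward until we return to the start
        loop = [np.array(start)]
        visited.add(start)
        prev = None
        cur = start
        while True:
            nxt = None
            for cand in adj[cur]:
                kc = key(cand)
                if kc != prev and kc != cur:
                    if kc == start:
                        nxt = None  # closed
                        break
                    if kc not in visited:
                        nxt = cand
                        break
            if nxt is None:
                break
            loop.append(np.asarray(nxt))
            visited.add(key(nxt))
            prev = cur
            cur = key(nxt)
        if len(loop) >= 3:
            loops.append(np.array(loop))
    if not loops:
        raise ValueError("plane/surface intersection produced no closed loop")
    dists = [np.linalg.norm(lp - near, axis=1).min() for lp in loops]
    return loops[int(np.argmin(dists))]


class _Loop:
    """Arc-length parametrization of a closed polyline."""

    def __init__(self, pts: np.ndarray):
        self.pts = pts
        seg = np.linalg.norm(np.diff(np.vstack([pts, pts[:1]]), axis=0), axis=1)
        self.cum = np.concatenate([[0.0], np.cumsum(seg)])
        self.total = self.cum[-1]

    def param_of(self, p: np.ndarray) -> float:
        """Arc parameter of the projection of p onto the loop."""
        a = self.pts
        b = np.vstack([self.pts[1:], self.pts[:1]])
        ab = b - a
        tt = np.clip(np.einsum("ij,ij->i", p - a, ab) / np.einsum("ij,ij->i", ab, ab), 0, 1)
        proj = a + tt[:, None] * ab
        i = int(np.argmin(np.linalg.norm(proj - p, axis=1)))
        return float(self.cum[i] + tt[i] * (self.cum[i + 1] - self.cum[i]))

    def point_at(self, s: float) -> np.ndarray:
        s = s % self.total
        i = int(np.searchsorted(self.cum, s, side="right")) - 1
        i = min(i, len(self.pts) - 1)
        seg_len = self.cum[i + 1] - self.cum[i]
        w = (s - self.cum[i]) / seg_len if seg_len > 0 else 0.0
        nxt = self.pts[(i + 1) % len(self.pts)]
        return self.pts[i] + w * (nxt - self.pts[i])

    def arc(self, s0: float, s1: float, s_via: float) -> tuple[float, float, int]:
        """(start, length, direction) of the s0->s1 arc passing through s_via."""
        fwd = (s1 - s0) % self.total
        via_fwd = (s_via - s0) % self.total
        if via_fwd <= fwd + 1e-12:
            return s0, fwd, +1
        return s0, self.total - fwd, -1

    def fraction(self, s0: float, s1: float, s_via: float, f: float) -> np.ndarray:
        start, length, sign = self.arc(s0, s1, s_via)
        return self.point_at(start + sign * f * length)


def _surface_arc_point(
    surface: TriSurface, p0: np.ndarray, p1: np.ndarray, via: np.ndarray, f: float
) -> np.ndarray:
    """Point at arc fraction ``f`` of the p0->p1 surface curve through ``via``."""
    n = np.cross(p1 - p0, via - p0)
    nn = np.linalg.norm(n)
    if nn < 1e-12:
        raise ValueError("arc endpoints and via point are collinear")
    loop = _Loop(_plane_loop(surface, p0, n / nn, via))
    return loop.fraction(loop.param_of(p0), loop.param_of(p1), loop.param_of(via), f)


def _project_to_surface(surface: TriSurface, p: np.ndarray) -> np.ndarray:
    q, _ = _closest_on_triangles(surface, np.asarray(p, dtype=float))
    return q


def locate_1020(
    scalp: TriSurface, fid: FiducialSet, cz_tol: float = 0.1, max_iter: int = 100
) -> dict[str, np.ndarray]:
    """Compute the 21 standard 10-20 positions on the scalp surface.

    Cz is found by fixed-point iteration: alternate taking the midpoint of
    the nasion->inion arc (through the current Cz) and of the tragus arc
    (through that midpoint) until both agree within ``cz_tol`` mm.
    """
    if not scalp.is_watertight():
        raise ValueError("scalp surface must be closed for 10-20 positioning")
    na = _project_to_surface(scalp, fid.nasion)
    ini = _project_to_surface(scalp, fid.inion)
    tl = _project_to_surface(scalp, fid.tragus_left)
    tr = _project_to_surface(scalp, fid.tragus_right)

    up = np.cross(ini - na, tr - tl)
    up /= np.linalg.norm(up)
    cz = scalp.vertices[int(np.argmax(scalp.vertices @ up))]
    for _ in range(max_iter):
        cz_s = _surface_arc_point(scalp, na, ini, cz, 0.5)
        cz_c = _surface_arc_point(scalp, tl, tr, cz_s, 0.5)
        if np.linalg.norm(cz_s - cz_c) < cz_tol:
            cz = cz_c
            break
        cz = cz_c
    else:
        raise RuntimeError(f"Cz fixed point did not converge within {max_iter} iterations")

    pos: dict[str, np.ndarray] = {"Cz": cz}
    sag = lambda f: _surface_arc_point(scalp, na, ini, cz, f)
    pos["Fpz"], pos["Fz"], pos["Pz"], pos["Oz"] = sag(0.1), sag(0.3), sag(0.7), sag(0.9)
    cor = lambda f: _surface_arc_point(scalp, tl, tr, cz, f)
    pos["T3"], pos["C3"], pos["C4"], pos["T4"] = cor(0.1), cor(0.3), cor(0.7), cor(0.9)

    # circumferential curve through Fpz, Oz and T3; fractions from Fpz toward T3
    n = np.cross(pos["Oz"] - pos["Fpz"], pos["T3"] - pos["Fpz"])
    loop = _Loop(_plane_loop(scalp, pos["Fpz"], n / np.linalg.norm(n), pos["T3"]))
    s_fpz, s_oz, s_t3 = (loop.param_of(pos[k]) for k in ("Fpz", "Oz", "T3"))
    start, length, sign = loop.arc(s_fpz, s_oz, s_t3)
    left = lambda f: loop.point_at(start + sign * f * length)
    # right-hand semicircle: the complementary arc, walked the other way
    rlength = loop.total - length
    right = lambda f: loop.point_at(start - sign * f * rlength)
    for name, f, side in [
        ("Fp1", 0.1, left), ("F7", 0.3, left), ("T5", 0.7, left), ("O1", 0.9, left),
        ("Fp2", 0.1, right), ("F8", 0.3, right), ("T6", 0.7, right), ("O2", 0.9, right),
    ]:
        pos[name] = side(f)

    # parasagittal positions at arc midpoints of the frontal/parietal curves
    pos["F3"] = _surface_arc_point(scalp, pos["F7"], pos["F8"], pos["Fz"], 0.25)
    pos["F4"] = _surface_arc_point(scalp, pos["F7"], pos["F8"], pos["Fz"], 0.75)
    pos["P3"] = _surface_arc_point(scalp, pos["T5"], pos["T6"], pos["Pz"], 0.25)
    pos["P4"] = _surface_arc_point(scalp, pos["T5"], pos["T6"], pos["Pz"], 0.75)
    return pos


# ---------------------------------------------------------------------------
# footprint clipping and extrusion
# ---------------------------------------------------------------------------


def _closest_on_triangles(surface: TriSurface, p: np.ndarray) -> tuple[np.ndarray, int]:
    """Closest point to ``p`` over all triangles, and the triangle index."""
    v = surface.vertices
    t = surface.triangles
    a, b, c = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = np.where(np.abs(va + vb + vc) < 1e-300, 1.0, va + vb + vc)
    u = vb / denom
    w = vc / denom
    # clamp barycentric candidates to the triangle (vertex/edge regions)
    u = np.clip(u, 0, 1)
    w = np.clip(w, 0, 1 - u)
    cand = a + u[:, None] * ab + w[:, None] * ac
    # also consider the three edges explicitly for robustness
    best = cand
    dist = np.linalg.norm(best - p, axis=1)
    for e0, e1 in ((a, b), (a, c), (b, c)):
        d = e1 - e0
        tt = np.clip(np.einsum("ij,ij->i", p - e0, d) / np.einsum("ij,ij->i", d, d), 0, 1)
        q = e0 + tt[:, None] * d
        dq = np.linalg.norm(q - p, axis=1)
        closer = dq < dist
        best = np.where(closer[:, None], q, best)
        dist = np.where(closer, dq, dist)
    i = int(np.argmin(dist))
    return best[i], i


def _surface_normal_at(surface: TriSurface, p: np.ndarray) -> np.ndarray:
    _, tid = _closest_on_triangles(surface, np.asarray(p, dtype=float))
    n = surface.triangle_normals()[tid]
    return n / np.linalg.norm(n)


def _tangent_frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0]) if abs(axis[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    t1 = np.cross(axis, ref)
    t1 /= np.linalg.norm(t1)
    return t1, np.cross(axis, t1)


def _triangulate_convexish(poly: sg.Polygon) -> list[np.ndarray]:
    """Fan/Delaunay triangulation of a simple polygon, coords as (k,3,2)."""
    coords = np.asarray(poly.exterior.coords)[:-1]
    if len(coords) < 3:
        return []
    if sg.Polygon(coords).equals(sg.Polygon(coords).convex_hull):
        return [np.stack([coords[0], coords[i], coords[i + 1]]) for i in range(1, len(coords) - 1)]
    tris = []
    for tri in shapely.delaunay_triangles(sg.MultiPoint([sg.Point(c) for c in coords])).geoms:
        if tri.within(poly.buffer(1e-9)):
            tris.append(np.asarray(tri.exterior.coords)[:3])
    return tris


def clip_patch(
    scalp: TriSurface,
    spec: ElectrodeSpec,
    center: np.ndarray,
    n_segments: int = 64,
    min_edge: float = 1e-3,
) -> TriSurface:
    """Scalp patch inside the footprint prism swept along the normal at
    ``center``: exact polygon clipping per triangle, then duplicate-vertex
    merge and short-edge (< ``min_edge`` mm) collapse."""
    center = np.asarray(center, dtype=float)
    axis = _surface_normal_at(scalp, center)
    t1, t2 = _tangent_frame(axis)
    foot = spec.footprint_polygon(n_segments)

    v = scalp.vertices - center
    uv = np.column_stack([v @ t1, v @ t2])
    w = v @ axis
    out_tris = []
    tri_normals = scalp.triangle_normals()
    for tri, tn in zip(scalp.triangles, tri_normals):
        if tn @ axis <= 0:
            continue  # back-facing (e.g. the far side of a closed scalp)
        tri2d = uv[tri]
        e1, e2 = tri2d[1] - tri2d[0], tri2d[2] - tri2d[0]
        area2 = e1[0] * e2[1] - e1[1] * e2[0]
        if abs(area2) < 1e-12:
            continue  # triangle parallel to the prism axis
        tpoly = sg.Polygon(tri2d)
        inter = tpoly.intersection(foot)
        if inter.is_empty or inter.area <= 0:
            continue
        polys = inter.geoms if hasattr(inter, "geoms") else [inter]
        M = np.column_stack([tri2d[1] - tri2d[0], tri2d[2] - tri2d[0]])
        Minv = np.linalg.inv(M)
        for poly in polys:
            if not isinstance(poly, sg.Polygon):
                continue
            for t3 in _triangulate_convexish(poly):
                pts3d = []
                for p2 in t3:
                    lam = Minv @ (p2 - tri2d[0])
                    h = w[tri[0]] + lam[0] * (w[tri[1]] - w[tri[0]]) + lam[1] * (w[tri[2]] - w[tri[0]])
                    pts3d.append(center + p2[0] * t1 + p2[1] * t2 + h * axis)
                # orient consistently outward (along the prism axis)
                nrm = np.cross(pts3d[1] - pts3d[0], pts3d[2] - pts3d[0])
                if nrm @ axis < 0:
                    pts3d = [pts3d[0], pts3d[2], pts3d[1]]
                out_tris.append(pts3d)
    if not out_tris:
        raise ValueError("electrode footprint does not intersect the scalp surface")
    flat = np.asarray(out_tris).reshape(-1, 3)
    verts, inv = np.unique(np.round(flat / min_edge).astype(np.int64), axis=0, return_inverse=True)
    # representative coordinates: first occurrence of each merged vertex
    first = np.zeros(len(verts), dtype=np.int64)
    first[inv[::-1]] = np.arange(len(flat))[::-1]
    tris = inv.reshape(-1, 3)
    good = (tris[:, 0] != tris[:, 1]) & (tris[:, 1] != tris[:, 2]) & (tris[:, 0] != tris[:, 2])
    patch = TriSurface(flat[first], tris[good], name=f"{spec.name}_patch")
    return patch.cleaned()


def extrude_electrode(
    patch: TriSurface, thickness: float, step: float = 1.0
) -> tuple[TriSurface, np.ndarray]:
    """Extrude an open patch along per-vertex normals in 1 mm steps.

    Returns the closed solid and the triangle indices of its outer
    (equipotential) face set, i.e. the final offset copy of the patch.
    ``ceil(thickness)`` layers are used, the last one shortened so the total
    offset equals ``thickness`` exactly.
    """
    if thickness <= 0:
        raise ValueError("thickness must be positive")
    if len(patch.boundary_edges()) == 0:
        raise ValueError("patch must be open (have a boundary) for extrusion")
    n_layers = int(np.ceil(thickness / step - 1e-12))
    offsets = np.minimum(np.arange(1, n_layers + 1) * step, thickness)

    tm = patch.to_trimesh()
    vnorm = np.asarray(tm.vertex_normals, dtype=float)
    # consistent outward orientation: align with mean face normal
    mean_n = np.asarray(tm.face_normals, dtype=float).mean(axis=0)
    if vnorm.sum(axis=0) @ mean_n < 0:
        vnorm = -vnorm

    nv = len(patch.vertices)
    layers = [patch.vertices]
    for off in offsets:
        layers.append(patch.vertices + off * vnorm)
    verts = np.concatenate(layers)

    tris = [patch.triangles[:, ::-1]]  # bottom, flipped outward
    top = patch.triangles + n_layers * nv
    bed = patch.boundary_edges()
    # orient boundary edges consistently with triangle winding
    edge_set = {}
    for tri in patch.triangles:
        for i in range(3):
            edge_set[(tri[i], tri[(i + 1) % 3])] = True
    walls = []
    for a, b in bed:
        if (a, b) not in edge_set:
            a, b = b, a
        for k in range(n_layers):
            a0, b0 = a + k * nv, b + k * nv
            a1, b1 = a + (k + 1) * nv, b + (k + 1) * nv
            walls.append([a0, b0, b1])
            walls.append([a0, b1, a1])
    tris.append(np.asarray(walls, dtype=np.int64))
    tris.append(top)
    solid = TriSurface(verts, np.concatenate(tris), name=f"{patch.name}_solid")
    check = solid.cleaned()
    if not check.is_watertight():
        raise ValueError("extrusion produced a non-watertight solid (self-intersecting offset?)")
    n_bottom = len(patch.triangles)
    n_wall = len(walls)
    outer_idx = np.arange(n_bottom + n_wall, n_bottom + n_wall + len(top))
    return solid, outer_idx


def tag_electrode_on_mesh(
    mesh: TetMesh,
    spec: ElectrodeSpec,
    center: np.ndarray,
    electrode_label: int,
    n_segments: int = 64,
) -> TetMesh:
    """Stamp an electrode into the outer cell layer of a volume mesh.

    Cells whose centroid lies inside the footprint prism and within
    ``spec.thickness`` (measured inward along the outward normal at
    ``center``) of the boundary are relabeled ``electrode_label``.  Adds the
    boundary patch ``<name>_outer`` (exterior faces of the electrode) and the
    interface patch ``<name>_contact`` (electrode/tissue faces).
    """
    center = np.asarray(center, dtype=float)
    geo = mesh.geometry
    bn = geo.bnd_area_vec / np.linalg.norm(geo.bnd_area_vec, axis=1, keepdims=True)
    near = np.linalg.norm(geo.bnd_centroid - center, axis=1)
    axis = bn[int(np.argmin(near))]
    t1, t2 = _tangent_frame(axis)
    foot = spec.footprint_polygon(n_segments)

    rel = geo.bnd_centroid - center
    inside2d = shapely.contains_xy(foot, rel @ t1, rel @ t2)
    facing = np.einsum("ij,j->i", bn, axis) > 0.0
    # gate along the prism axis so the far side of a closed phantom (which
    # also projects into the footprint) is never captured
    circum = float(np.abs(np.asarray(foot.exterior.coords)).max())
    reach = circum + spec.thickness + 2.0 * np.sqrt(
        np.linalg.norm(geo.bnd_area_vec, axis=1).max()
    )
    near_axis = np.abs(rel @ axis) <= reach
    seed_faces = inside2d & facing & near_axis
    if not seed_faces.any():
        raise ValueError(f"electrode footprint covers no boundary faces for {spec.name!r}")

    relc = mesh.cell_centroids() - center
    in_prism = shapely.contains_xy(foot, relc @ t1, relc @ t2)
    depth = -(relc @ axis)  # positive going inward from the footprint center
    labels = mesh.cell_labels.copy()
    pick = in_prism & (depth >= -1e-9) & (depth <= spec.thickness)
    seed_cells = np.unique(geo.bnd_owner[seed_faces])
    pick[seed_cells] = True
    labels[pick] = electrode_label

    out = TetMesh(mesh.points, mesh.cells, labels, dict(mesh.patches))
    geo2 = out.geometry
    is_el_o = labels[geo2.int_owner] == electrode_label
    is_el_n = labels[geo2.int_neighbour] == electrode_label
    contact = is_el_o ^ is_el_n
    outer = labels[geo2.bnd_owner] == electrode_label
    # restrict to faces of *this* electrode's cells
    mine = np.zeros(out.n_cells, dtype=bool)
    mine[pick] = True
    contact &= mine[geo2.int_owner] | mine[geo2.int_neighbour]
    outer &= mine[geo2.bnd_owner]
    if not contact.any():
        raise ValueError(f"electrode {spec.name!r} has no contact interface")
    out.patches[f"{spec.name}_outer"] = geo2.bnd_tris[outer]
    # store contact triangles oriented electrode -> tissue (int_tris are
    # oriented outward from the owner cell), so current integration over the
    # patch has a well-defined sign
    ct = geo2.int_tris[contact].copy()
    flip = labels[geo2.int_owner[contact]] != electrode_label
    ct[flip] = ct[flip][:, ::-1]
    out.patches[f"{spec.name}_contact"] = ct
    return out
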