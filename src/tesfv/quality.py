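"""Finite-volume mesh quality metrics: non-orthogonality and skewness.

Non-orthogonality of an internal face is the angle between its area vector
and the owner->neighbour centroid vector; the 2-point flux approximation is
exact only at 0 deg and faces beyond 70 deg conventionally require explicit
correction.  Skewness measures how far the centroid line misses the face
centroid, normalized by the centroid distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TetMesh

__all__ = ["QualityReport", "mesh_quality", "face_nonorthogonality", "face_skewness"]

NONORTHO_THRESHOLD_DEG = 70.0


@dataclass
class QualityReport:
    n_cells: int
    n_nonorthogonal_faces: int
    max_nonorthogonality: float  # degrees
    max_skewness: float

    def as_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "n_nonorthogonal_faces": self.n_nonorthogonal_faces,
            "max_nonorthogonality_deg": self.max_nonorthogonality,
            "max_skewness": self.max_skewness,
        }


def face_nonorthogonality(mesh: TetMesh) -> np.ndarray:
    """Per internal face: angle (deg) between area vector and centroid line."""
    geo = mesh.geometry
    d = geo.cell_centroids[geo.int_neighbour] - geo.cell_centroids[geo.int_owner]
    a = geo.int_area_vec
    cosang = np.einsum("ij,ij->i", a, d) / (
        np.linalg.norm(a, axis=1) * np.linalg.norm(d, axis=1)
    )
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def face_skewness(mesh: TetMesh) -> np.ndarray:
    """Per internal face: |face centroid - centroid-line/face-plane intersection|
    normalized by the owner-neighbour centroid distance."""
    geo = mesh.geometry
    xo = geo.cell_centroids[geo.int_owner]
    xn = geo.cell_centroids[geo.int_neighbour]
    d = xn - xo
    n = geo.int_area_vec
    xf = geo.int_centroid
    denom = np.einsum("ij,ij->i", d, n)
    denom = np.where(np.abs(denom) < 1e-300, np.nan, denom)
    t = np.einsum("ij,ij->i", xf - xo, n) / denom
    hit = xo + t[:, None] * d
    return np.linalg.norm(xf - hit, axis=1) / np.linalg.norm(d, axis=1)


def mesh_quality(mesh: TetMesh, threshold_deg: float = NONORTHO_THRESHOLD_DEG) -> QualityReport:
    """Quality report over all internal faces of the mesh."""
    geo = mesh.geometry
    if geo.n_internal_faces == 0:
        raise ValueError("mesh has no internal faces")
    ang = face_nonorthogonality(mesh)
    skew = face_skewness(mesh)
    return QualityReport(
        n_cells=mesh.n_cells,
        n_nonorthogonal_faces=int((ang > threshold_deg).sum()),
        max_nonorthogonality=float(ang.max()),
        max_skewness=float(np.nanmax(skew)),
    )
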