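"""Post-processing statistics for simulated fields and pipeline comparisons.

These are the summaries used when contrasting two tES simulations: percentile
tables of |E| per tissue compartment, hotspot masks (above the 90th
percentile), per-cell relative magnitude difference and angle difference
maps, and sampling along a line between an electrode pair.

Conventions (fixed and reported): percentiles interpolate linearly between
closest ranks; statistics are unweighted per-cell unless ``volume_weighted``
is requested; the relative difference is normalized by the *reference* field
and is therefore not symmetric in its arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import TetMesh

__all__ = [
    "MagnitudeStats",
    "magnitude_stats",
    "hotspot_mask",
    "relative_difference_map",
    "angle_difference_map",
    "sample_line",
]


@dataclass
class MagnitudeStats:
    mean: float
    sd: float
    p90: float
    p95: float
    p99: float
    n_cells: int

    def as_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "p90": self.p90,
                "p95": self.p95, "p99": self.p99, "n_cells": self.n_cells}


def _magnitudes(E: np.ndarray) -> np.ndarray:
    E = np.asarray(E, dtype=float)
    return np.linalg.norm(E, axis=1) if E.ndim == 2 else np.abs(E)


def magnitude_stats(
    E: np.ndarray,
    mesh: TetMesh | None = None,
    compartment: int | None = None,
    volume_weighted: bool = False,
) -> MagnitudeStats:
    """Mean/SD and 90/95/99th percentiles of |E| over a compartment.

    Without ``mesh``/``compartment`` the statistics cover all cells.
    ``volume_weighted=True`` weights by cell volume (percentiles then use the
    weighted empirical CDF).
    """
    mag = _magnitudes(E)
    if compartment is not None:
        if mesh is None:
            raise ValueError("compartment selection requires the mesh")
        sel = mesh.cell_labels == compartment
        if not sel.any():
            raise ValueError(f"compartment {compartment} is empty")
        mag = mag[sel]
    else:
        sel = slice(None)
    if volume_weighted:
        if mesh is None:
            raise ValueError("volume weighting requires the mesh")
        w = mesh.geometry.cell_volumes[sel]
        order = np.argsort(mag)
        mag_s, w_s = mag[order], w[order]
        cdf = (np.cumsum(w_s) - 0.5 * w_s) / w_s.sum()
        pct = [float(np.interp(p / 100, cdf, mag_s)) for p in (90, 95, 99)]
        mean = float(np.average(mag, weights=w))
        sd = float(np.sqrt(np.average((mag - mean) ** 2, weights=w)))
    else:
        pct = [float(np.percentile(mag, p)) for p in (90, 95, 99)]
        mean = float(mag.mean())
        sd = float(mag.std())
    return MagnitudeStats(mean, sd, *pct, n_cells=int(mag.size))


def hotspot_mask(E: np.ndarray, percentile: float = 90.0) -> np.ndarray:
    """Cells with |E| strictly above the given percentile of |E| (hotspots)."""
    mag = _magnitudes(E)
    if np.ptp(mag) == 0:
        import warnings

        warnings.warn("constant field: hotspot mask is empty", stacklevel=2)
        return np.zeros(mag.shape, dtype=bool)
    return mag > np.percentile(mag, percentile)


def relative_difference_map(E_ref: np.ndarray, E_test: np.ndarray) -> np.ndarray:
    """Per-cell 100 * | |E_ref| - |E_test| | / |E_ref| (percent).

    Cells with |E_ref| = 0 are flagged NaN (undefined) rather than raising,
    and should be excluded from summaries.
    """
    mr = _magnitudes(E_ref)
    mt = _magnitudes(E_test)
    if mr.shape != mt.shape:
        raise ValueError("fields must be matched per cell")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 100.0 * np.abs(mr - mt) / mr
    out[mr == 0] = np.nan
    return out


def angle_difference_map(E_a: np.ndarray, E_b: np.ndarray) -> np.ndarray:
    """Per-cell angle between two vector fields in degrees [0, 180].

    ``arccos`` of the clamped normalized inner product; zero vectors on
    either side are flagged NaN.
    """
    E_a = np.asarray(E_a, dtype=float)
    E_b = np.asarray(E_b, dtype=float)
    na = np.linalg.norm(E_a, axis=1)
    nb = np.linalg.norm(E_b, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cosang = np.einsum("ij,ij->i", E_a, E_b) / (na * nb)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ang[(na == 0) | (nb == 0)] = np.nan
    return ang


def sample_line(
    mesh: TetMesh,
    field: np.ndarray,
    p0: np.ndarray,
    p1: np.ndarray,
    n_samples: int = 100,
) -> dict[str, np.ndarray]:
    """Sample a per-cell field at equidistant points of the segment p0 -> p1.

    Each sample takes the (piecewise-constant) value of its containing cell;
    points outside the mesh are flagged, not dropped.  Returns arrays
    ``t`` (mm along the line), ``points``, ``value``, ``label``, ``inside``.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    field = np.asarray(field, dtype=float)
    ts = np.linspace(0.0, 1.0, n_samples)
    pts = p0 + ts[:, None] * (p1 - p0)
    cell_idx = _containing_cells(mesh, pts)
    inside = cell_idx >= 0
    if not inside.any():
        raise ValueError("sampling segment lies entirely outside the mesh")
    shape = (n_samples,) if field.ndim == 1 else (n_samples, field.shape[1])
    value = np.full(shape, np.nan)
    value[inside] = field[cell_idx[inside]]
    label = np.full(n_samples, -1, dtype=np.int64)
    label[inside] = mesh.cell_labels[cell_idx[inside]]
    return {
        "t": ts * np.linalg.norm(p1 - p0),
        "points": pts,
        "value": value,
        "label": label,
        "inside": inside,
    }


def _containing_cells(mesh: TetMesh, pts: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Index of the tet containing each point (-1 if none), barycentric test."""
    p = mesh.points
    c = mesh.cells
    out = np.full(len(pts), -1, dtype=np.int64)
    # prefilter by bounding spheres of cells around each point
    centroids = mesh.cell_centroids()
    radius = np.max(np.linalg.norm(p[c] - centroids[:, None, :], axis=2), axis=1)
    a = p[c[:, 0]]
    T = np.stack([p[c[:, 1]] - a, p[c[:, 2]] - a, p[c[:, 3]] - a], axis=2)
    Tinv = np.linalg.inv(T)
    for i, q in enumerate(pts):
        cand = np.flatnonzero(np.linalg.norm(centroids - q, axis=1) <= radius)
        if len(cand) == 0:
            continue
        lam = np.einsum("nij,nj->ni", Tinv[cand], q - a[cand])
        ok = (lam >= -tol).all(axis=1) & (lam.sum(axis=1) <= 1 + tol)
        hits = cand[ok]
        if len(hits):
            out[i] = hits[0]
    return out
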