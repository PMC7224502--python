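"""Per-cell conductivity tensors: isotropic tables and white-matter anisotropy.

Isotropic compartments get ``sigma * I``.  White-matter anisotropy is derived
from diffusion tensors by the volume-constraint method: the conductivity
tensor shares the diffusion tensor's eigenvectors, its principal/auxiliary
eigenvalues have a fixed ratio (default 10), and their geometric mean is
pinned to the tissue's scalar conductivity:

    sigma_wm^2 = sigma_main * sigma_aux,   sigma_aux = sigma_main / ratio

so ``sigma_main = sigma_wm * sqrt(ratio)`` and
``sigma_T = S diag(sigma_main, sigma_aux, sigma_aux) S^T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .image import LabeledImage
from .mesh import TetMesh

__all__ = [
    "TissueTable",
    "DEFAULT_TISSUES",
    "AIR_SIGMA",
    "ConductivityField",
    "DiffusionTensorField",
    "isotropic_field",
    "volume_constraint_tensor",
    "spd_repair",
    "tensors_to_cells",
    "read_tensor_field",
    "write_tensor_field",
]

AIR_SIGMA = 1e-15  # insulator sentinel (S/m)

#: Scalar conductivities (S/m) commonly used for tDCS head models.
DEFAULT_TISSUES: dict[str, float] = {
    "skin": 0.465,
    "skull": 0.01,
    "csf": 1.654,
    "gray_matter": 0.275,
    "white_matter": 0.126,
    "electrode": 29.4,
    "air": AIR_SIGMA,
}


@dataclass
class TissueTable:
    """Map compartment label -> scalar conductivity sigma (S/m)."""

    sigma: dict[int, float]

    def __post_init__(self) -> None:
        for lab, s in self.sigma.items():
            if s <= 0:
                raise ValueError(f"conductivity for label {lab} must be > 0 (insulators use {AIR_SIGMA})")

    def __getitem__(self, label: int) -> float:
        return self.sigma[int(label)]


@dataclass
class ConductivityField:
    """One symmetric positive-definite 3x3 tensor (S/m) per cell."""

    tensors: np.ndarray  # (n_cells, 3, 3)
    anisotropic: np.ndarray = field(default=None)  # bool per cell

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float).reshape(-1, 3, 3)
        if self.anisotropic is None:
            self.anisotropic = np.zeros(len(self.tensors), dtype=bool)
        self.anisotropic = np.asarray(self.anisotropic, dtype=bool)

    @property
    def n_cells(self) -> int:
        return len(self.tensors)

    def validate(self, eig_tol: float = 0.0) -> None:
        asym = np.abs(self.tensors - np.swapaxes(self.tensors, 1, 2)).max()
        if asym > 1e-12:
            raise ValueError(f"tensors not symmetric (max asymmetry {asym:g})")
        mins = np.linalg.eigvalsh(self.tensors)[:, 0]
        if np.any(mins <= eig_tol):
            raise ValueError("non-positive-definite conductivity tensor present")


@dataclass
class DiffusionTensorField:
    """Per-voxel symmetric diffusion tensors on a regular grid.

    Units are arbitrary: only the eigenvectors are used by the
    volume-constraint mapping.
    """

    tensors: np.ndarray  # (nx, ny, nz, 3, 3)
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 5 or self.tensors.shape[3:] != (3, 3):
            raise ValueError("tensors must have shape (nx, ny, nz, 3, 3)")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    def grid(self) -> LabeledImage:
        return LabeledImage(
            np.zeros(self.tensors.shape[:3], dtype=np.int16), self.spacing, self.origin
        )


def isotropic_field(mesh: TetMesh, table: TissueTable) -> ConductivityField:
    """sigma_label * identity for every cell."""
    present = np.unique(mesh.cell_labels)
    missing = [int(l) for l in present if int(l) not in table.sigma]
    if missing:
        raise KeyError(f"labels missing from tissue table: {missing}")
    sig = np.array([table[l] for l in mesh.cell_labels])
    return ConductivityField(sig[:, None, None] * np.eye(3))


def spd_repair(D: np.ndarray, fallback_sigma: float = 1.0, eps: float = 1e-12) -> np.ndarray:
    """Total repair of a 3x3 tensor: NaNs -> isotropic fallback, eigenvalues
    clamped to ``eps`` so downstream eigenvector use is well-defined."""
    D = np.asarray(D, dtype=float)
    if np.isnan(D).any():
        return fallback_sigma * np.eye(3)
    Ds = 0.5 * (D + D.T)
    w, V = np.linalg.eigh(Ds)
    w = np.maximum(w, eps)
    return (V * w) @ V.T


def volume_constraint_tensor(
    D: np.ndarray, sigma_wm: float, ratio: float = 10.0
) -> np.ndarray:
    """Map a diffusion tensor to a conductivity tensor (volume constraint).

    The returned tensor keeps D's eigenvectors (eigenvalues sorted
    descending) with eigenvalues ``(sigma_main, sigma_aux, sigma_aux)``,
    ``sigma_main = sigma_wm*sqrt(ratio)``, ``sigma_aux = sigma_wm/sqrt(ratio)``
    — the unique solution of ``sigma_wm^2 = sigma_main*sigma_aux`` with
    ``sigma_aux = sigma_main/ratio``.

    Degenerate eigenvalues get a deterministic eigenvector tie-break (each
    eigenvector's lexicographically largest component made positive), so
    isotropic input yields a reproducible basis.
    """
    D = np.asarray(D, dtype=float)
    if sigma_wm <= 0:
        raise ValueError("sigma_wm must be positive")
    if ratio <= 1:
        raise ValueError("anisotropy ratio must exceed 1")
    if np.abs(D - D.T).max() > 1e-9:
        raise ValueError("diffusion tensor is not symmetric")
    D = spd_repair(D, fallback_sigma=1.0)
    w, V = np.linalg.eigh(D)  # ascending
    order = np.argsort(w)[::-1]
    V = V[:, order]
    # deterministic sign: largest-magnitude component positive (ties -> lexicographic)
    for k in range(3):
        col = V[:, k]
        j = int(np.argmax(np.abs(col)))
        if col[j] < 0:
            V[:, k] = -col
    s_main = sigma_wm * np.sqrt(ratio)
    s_aux = sigma_wm / np.sqrt(ratio)
    return (V * np.array([s_main, s_aux, s_aux])) @ V.T


def tensors_to_cells(
    field_: DiffusionTensorField,
    mesh: TetMesh,
    conductivity: ConductivityField,
    wm_label: int,
    sigma_wm: float | None = None,
    ratio: float = 10.0,
    table: TissueTable | None = None,
) -> tuple[ConductivityField, int]:
    """Overwrite white-matter cells with volume-constraint tensors.

    Each WM cell samples the voxel containing its centroid (nearest-voxel,
    no interpolation).  Cells whose centroid falls outside the tensor grid
    keep their isotropic value; the count of such fallbacks is returned.
    """
    if sigma_wm is None:
        if table is None:
            raise ValueError("provide sigma_wm or a tissue table")
        sigma_wm = table[wm_label]
    grid = field_.grid()
    wm = np.flatnonzero(mesh.cell_labels == wm_label)
    centroids = mesh.cell_centroids()[wm]
    idx = grid.world_to_index(centroids)
    inside = np.all((idx >= 0) & (idx < np.array(grid.dims)), axis=1)

    out = ConductivityField(conductivity.tensors.copy(), conductivity.anisotropic.copy())
    for cell, (i, j, k), ok in zip(wm, idx, inside):
        if not ok:
            continue
        D = field_.tensors[i, j, k]
        if np.isnan(D).any():
            D = spd_repair(D, fallback_sigma=1.0)
        out.tensors[cell] = volume_constraint_tensor(D, sigma_wm, ratio)
        out.anisotropic[cell] = True
    n_fallback = int((~inside).sum())
    return out, n_fallback


# -- tensor volume I/O (lower-triangular NIfTI convention) -------------------

_LT = [(0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2)]  # Dxx Dxy Dyy Dxz Dyz Dzz


def write_tensor_field(field_: DiffusionTensorField, path: str | Path) -> None:
    """Write as 4-D NIfTI with 6 lower-triangular components per voxel."""
    comp = np.stack([field_.tensors[..., i, j] for i, j in _LT], axis=-1)
    affine = np.diag([*field_.spacing, 1.0])
    affine[:3, 3] = field_.origin
    nib.save(nib.Nifti1Image(comp.astype(np.float64), affine), str(path))


def read_tensor_field(path: str | Path) -> DiffusionTensorField:
    img = nib.load(str(path))
    comp = np.asanyarray(img.dataobj)
    if comp.ndim != 4 or comp.shape[3] != 6:
        raise ValueError(f"{path}: expected a 6-component tensor volume")
    T = np.empty(comp.shape[:3] + (3, 3))
    for c, (i, j) in enumerate(_LT):
        T[..., i, j] = comp[..., c]
        T[..., j, i] = comp[..., c]
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return DiffusionTensorField(T, spacing, origin)
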