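"""Labeled voxel images: the image half of the hybrid meshing domain.

A :class:`LabeledImage` stores one integer tissue label per voxel on a regular
grid.  World coordinates follow the voxel-center convention with 0-based
indices and no rotation part::

    world = origin + index * spacing

which is the natural reading of an ANALYZE header (voxel sizes only).  Label 0
is background/air.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["LabeledImage", "read_label_image", "write_label_image"]


@dataclass
class LabeledImage:
    """Integer tissue labels on a regular voxel grid.

    Parameters
    ----------
    labels
        ``(nx, ny, nz)`` integer array, 0 = background.
    spacing
        Voxel edge lengths in mm per axis.
    origin
        World coordinate (mm) of the *center* of voxel ``(0, 0, 0)``.
    """

    labels: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError("spacing must be positive on every axis")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def label_set(self) -> np.ndarray:
        """Sorted array of labels present in the image."""
        return np.unique(self.labels)

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape ``(n_voxels, 3)``."""
        idx = np.indices(self.dims).reshape(3, -1).T
        return self.origin + idx * self.spacing

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Containing-voxel index for each world point (may be out of range)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        return np.rint((points - self.origin) / self.spacing).astype(int)

    def label_at(self, points: np.ndarray) -> np.ndarray:
        """Label of the voxel containing each point; 0 outside the grid."""
        idx = self.world_to_index(points)
        inside = np.all((idx >= 0) & (idx < np.array(self.dims)), axis=1)
        out = np.zeros(len(idx), dtype=self.labels.dtype)
        ii = idx[inside]
        out[inside] = self.labels[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out


def _is_analyze(path: Path) -> bool:
    return path.suffix.lower() in {".hdr", ".img"}


def write_label_image(image: LabeledImage, path: str | Path) -> None:
    """Write a label image as NIfTI (``.nii``/``.nii.gz``) or ANALYZE (``.hdr``).

    NIfTI stores the origin in the affine translation; ANALYZE carries voxel
    sizes only, so the origin is not preserved through an ANALYZE round trip.
    """
    path = Path(path)
    data = np.asarray(image.labels, dtype=np.int16 if image.labels.max() < 2**15 else np.int32)
    if _is_analyze(path):
        img = nib.AnalyzeImage(data, None)
        img.header.set_zooms(tuple(image.spacing))
        nib.save(img, str(path))
    else:
        affine = np.diag([*image.spacing, 1.0])
        affine[:3, 3] = image.origin
        img = nib.Nifti1Image(data, affine)
        img.header.set_zooms(tuple(image.spacing))
        nib.save(img, str(path))


def read_label_image(path: str | Path) -> LabeledImage:
    """Read a NIfTI or ANALYZE volume of integer labels."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=0):
            raise ValueError(f"{path}: voxel data is not integer-valued; not a label image")
        data = rounded.astype(np.int32)
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    if isinstance(img, nib.Nifti1Image):
        origin = np.asarray(img.affine[:3, 3], dtype=float)
    else:
        origin = np.zeros(3)
    return LabeledImage(labels=np.asarray(data), spacing=spacing, origin=origin)
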