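"""In-memory containers for 3D scalar volumes and ROI label masks.

The package works on axis-aligned regular grids.  An :class:`ImageVolume`
stores the voxel data as a ``(nx, ny, nz)`` array together with the voxel
spacing and the world coordinate of voxel ``(0, 0, 0)``.  World coordinates
follow the convention ``world = origin + index * spacing`` with 0-based
indices; axial slices are indexed along the last (z) axis.

Volumes and masks round-trip through NIfTI-1 via nibabel, with the spacing
carried in the affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume", "ROIMask"]


@dataclass
class ImageVolume:
    """A 3D scalar image on a regular grid.

    Parameters
    ----------
    data
        Voxel values, shape ``(nx, ny, nz)``.
    spacing
        Voxel size in mm per axis.
    origin
        World coordinate (mm) of the center of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def voxel_centers(self, axis: int) -> np.ndarray:
        """World coordinates (mm) of voxel centers along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def copy_with(self, data: np.ndarray) -> "ImageVolume":
        """A new volume with the same geometry and different data."""
        if data.shape != self.shape:
            raise ValueError(f"shape mismatch: {data.shape} vs {self.shape}")
        return ImageVolume(np.asarray(data, dtype=np.float64), self.spacing, self.origin)

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path: str) -> None:
        """Write as NIfTI-1 (.nii or .nii.gz); spacing/origin go in the affine."""
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine()), path)

    @classmethod
    def from_nifti(cls, path: str) -> "ImageVolume":
        img = nib.load(path)
        aff = img.affine
        spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
        origin = tuple(float(x) for x in aff[:3, 3])
        return cls(np.asarray(img.get_fdata(), dtype=np.float64), spacing, origin)


@dataclass
class ROIMask:
    """A boolean region-of-interest aligned to an :class:`ImageVolume`."""

    mask: np.ndarray
    label: int
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        self.label = int(self.label)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    def count(self) -> int:
        return int(self.mask.sum())

    def is_empty(self) -> bool:
        return not self.mask.any()


def masks_to_label_volume(masks: list[ROIMask]) -> ImageVolume:
    """Collapse disjoint ROI masks into one integer label volume (0 = background)."""
    if not masks:
        raise ValueError("no masks given")
    lab = np.zeros(masks[0].shape, dtype=np.float64)
    for m in masks:
        if (lab[m.mask] != 0).any():
            raise ValueError("masks overlap; cannot build a label volume")
        lab[m.mask] = m.label
    return ImageVolume(lab, masks[0].spacing, masks[0].origin)


def label_volume_to_masks(vol: ImageVolume) -> list[ROIMask]:
    """Split an integer label volume into one ROIMask per nonzero label."""
    labels = np.unique(vol.data)
    labels = labels[labels != 0]
    return [
        ROIMask(vol.data == lab, int(lab), vol.spacing, vol.origin) for lab in labels
    ]
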