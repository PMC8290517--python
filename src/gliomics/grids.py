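"""Image containers: 3D scalar volumes and binary masks on a physical grid.

``VolumeGrid`` is the unit of all image math in this package: a 3D array of
intensities together with voxel spacing (mm) and the physical position of the
first voxel center. ``MaskGrid`` is the same thing restricted to {0, 1}.
NIfTI-1 round-trips go through nibabel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import InvalidInputError

__all__ = ["VolumeGrid", "MaskGrid", "load_volume", "load_mask"]


@dataclass
class VolumeGrid:
    """A 3D scalar image with voxel spacing and origin, both in millimetres."""

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3 or self.values.size == 0:
            raise InvalidInputError("volume must be a non-empty 3D array")
        if any(s <= 0 for s in self.spacing_mm):
            raise InvalidInputError(f"spacing must be positive, got {self.spacing_mm}")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.spacing_mm) + [1.0]).astype(float)
        affine[:3, 3] = self.origin_mm
        return nib.Nifti1Image(np.asarray(self.values, dtype=np.float32), affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))


@dataclass
class MaskGrid(VolumeGrid):
    """A binary region of interest aligned voxel-for-voxel to a VolumeGrid."""

    values: np.ndarray = field(default_factory=lambda: np.zeros((1, 1, 1), dtype=np.uint8))

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if not np.isin(arr, (0, 1)).all():
            raise InvalidInputError("mask values must be 0 or 1")
        self.values = arr.astype(np.uint8)
        super().__post_init__()

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())

    @property
    def volume_cm3(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3 / 1000.0

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.spacing_mm) + [1.0]).astype(float)
        affine[:3, 3] = self.origin_mm
        return nib.Nifti1Image(self.values.astype(np.uint8), affine)


def _from_nifti(img: nib.Nifti1Image) -> tuple[np.ndarray, tuple, tuple]:
    data = np.asanyarray(img.dataobj)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return data, zooms, origin


def load_volume(path) -> VolumeGrid:
    data, zooms, origin = _from_nifti(nib.load(str(path)))
    return VolumeGrid(data.astype(np.float64), zooms, origin)


def load_mask(path) -> MaskGrid:
    data, zooms, origin = _from_nifti(nib.load(str(path)))
    return MaskGrid((data > 0.5).astype(np.uint8), zooms, origin)
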