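"""Reslicing to isotropic grids and z-score intensity normalization.

Both steps run before feature extraction: volumes and masks are resampled to
a 1.0-mm isotropic lattice (trilinear for intensities, nearest-neighbor for
masks so they stay binary), and each volume's intensities are standardized
over its nonzero (brain) voxels so features are comparable across subjects
and sequences. The z-score uses the population standard deviation (divide by
n), fixed for bit-reproducibility; at brain scale the sample/population
distinction is immaterial.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .errors import DegenerateIntensityError, InvalidInputError
from .grids import MaskGrid, VolumeGrid

__all__ = ["resample_isotropic", "zscore_normalize", "preprocess_subject"]


def _target_shape(shape, spacing, target_mm: float) -> tuple[int, ...]:
    # preserve physical extent: new_n * target ≈ n * spacing
    return tuple(max(1, int(round(n * s / target_mm))) for n, s in zip(shape, spacing))


def resample_isotropic(
    volume: VolumeGrid, target_mm: float = 1.0, interpolation: str = "trilinear"
) -> VolumeGrid:
    """Reslice a volume (or mask) to an isotropic grid of ``target_mm`` spacing.

    Parameters
    ----------
    volume
        Input grid; a :class:`MaskGrid` input yields a :class:`MaskGrid`
        output and must use ``interpolation="nearest"``.
    target_mm
        Desired isotropic voxel edge length in millimetres.
    interpolation
        ``"trilinear"`` for intensity images, ``"nearest"`` for masks.
    """
    if target_mm <= 0:
        raise InvalidInputError(f"target spacing must be positive, got {target_mm}")
    if interpolation not in ("trilinear", "nearest"):
        raise InvalidInputError(f"unknown interpolation {interpolation!r}")
    is_mask = isinstance(volume, MaskGrid)
    if is_mask and interpolation != "nearest":
        raise InvalidInputError("masks must be resampled with nearest-neighbor")

    old_spacing = np.asarray(volume.spacing_mm, dtype=float)
    new_shape = _target_shape(volume.shape, old_spacing, target_mm)
    if tuple(new_shape) == tuple(volume.shape) and np.allclose(old_spacing, target_mm):
        cls = MaskGrid if is_mask else VolumeGrid
        return cls(volume.values.copy(), (target_mm,) * 3, volume.origin_mm)

    # sample new voxel centers at their physical positions in the old index space
    coords = np.meshgrid(
        *[
            (np.arange(n) * target_mm) / s  # physical mm -> old fractional index
            for n, s in zip(new_shape, old_spacing)
        ],
        indexing="ij",
    )
    order = 0 if interpolation == "nearest" else 1
    src = volume.values.astype(np.float64)
    out = ndimage.map_coordinates(src, coords, order=order, mode="nearest")
    if is_mask:
        return MaskGrid((out > 0.5).astype(np.uint8), (target_mm,) * 3, volume.origin_mm)
    return VolumeGrid(out, (target_mm,) * 3, volume.origin_mm)


def zscore_normalize(volume: VolumeGrid, support: MaskGrid | None = None) -> VolumeGrid:
    """Affinely rescale intensities to mean 0 / sd 1 over the support voxels.

    The support defaults to the volume's nonzero voxels (the brain foreground);
    the same affine transform is applied to the entire volume.
    """
    if support is not None:
        if support.values.shape != volume.values.shape:
            raise InvalidInputError("support mask shape does not match volume")
        sel = support.values.astype(bool)
    else:
        sel = volume.values != 0
    if not sel.any():
        raise InvalidInputError("normalization support is empty")
    vals = volume.values[sel]
    mu = float(vals.mean())
    sd = float(vals.std())  # population sd
    if sd == 0.0:
        raise DegenerateIntensityError("zero intensity variance over support")
    return VolumeGrid((volume.values - mu) / sd, volume.spacing_mm, volume.origin_mm)


def preprocess_subject(
    channels: dict[str, VolumeGrid], mask: MaskGrid, target_mm: float = 1.0
) -> tuple[dict[str, VolumeGrid], MaskGrid]:
    """Reslice all channels and the mask to isotropic spacing, then z-score.

    Channels are assumed voxel-aligned to the mask (registered inputs).
    """
    out = {}
    for name, vol in channels.items():
        iso = resample_isotropic(vol, target_mm, "trilinear")
        out[name] = zscore_normalize(iso)
    mask_iso = resample_isotropic(mask, target_mm, "nearest")
    return out, mask_iso
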