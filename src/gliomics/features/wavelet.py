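"""Group 4: undecimated 3D wavelet decomposition and sub-band features.

A single-level separable transform applies the wavelet's low-pass (L) or
high-pass (H) decomposition filter along each axis, giving 2³ = 8 sub-bands
(LLL ... HHH), each with the full spatial shape of the input (no
downsampling, so the original tumor mask applies unchanged to every band).
The 14 first-order and 33 texture features recomputed on each band give
8 x 47 = 376 wavelet features. Default family: coiflet-1, configurable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pywt
from scipy import ndimage

from .discretize import DiscretizationConfig
from .firstorder import first_order_features
from .texture import GLCM_NAMES, GLRLM_NAMES, RoiTextureContext, glcm_features, glrlm_features

__all__ = ["BAND_ORDER", "wavelet_decompose", "wavelet_features"]

#: band-index convention: suffix k in feature names refers to BAND_ORDER[k-1]
BAND_ORDER = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


def _filters(family: str) -> tuple[np.ndarray, np.ndarray]:
    w = pywt.Wavelet(family)
    return np.asarray(w.dec_lo, dtype=np.float64), np.asarray(w.dec_hi, dtype=np.float64)


def wavelet_decompose(volume, family: str = "coif1") -> dict[str, np.ndarray]:
    """Eight undecimated sub-band arrays of a volume grid, keyed LLL..HHH.

    Boundary handling is mirror reflection, which maps a constant volume to a
    constant LLL band and (numerically) zero in every band containing a
    high-pass factor. Axes shorter than the filter are reflect-padded with a
    warning instead of failing.
    """
    lo, hi = _filters(family)
    arr = np.asarray(volume.values, dtype=np.float64)
    pad = [0, 0, 0]
    flen = lo.size
    if any(s < flen for s in arr.shape):
        warnings.warn(f"axis shorter than {family} filter ({flen}); reflect-padding")
        pad = [max(0, flen - s) for s in arr.shape]
        arr = np.pad(arr, [(p, p) for p in pad], mode="reflect")
    # separable filtering: share the axis-0 and axis-01 intermediates
    stage0 = {c: ndimage.correlate1d(arr, f, axis=0, mode="reflect") for c, f in (("L", lo), ("H", hi))}
    stage1 = {
        c0 + c1: ndimage.correlate1d(v0, f, axis=1, mode="reflect")
        for c0, v0 in stage0.items()
        for c1, f in (("L", lo), ("H", hi))
    }
    bands = {
        c01 + c2: ndimage.correlate1d(v01, f, axis=2, mode="reflect")
        for c01, v01 in stage1.items()
        for c2, f in (("L", lo), ("H", hi))
    }
    if any(pad):
        sl = tuple(slice(p, s - p if p else None) for p, s in zip(pad, arr.shape))
        bands = {k: v[sl] for k, v in bands.items()}
    return {k: bands[k] for k in BAND_ORDER}


def wavelet_features(
    volume,
    mask,
    cfg: DiscretizationConfig | None = None,
    ctx: RoiTextureContext | None = None,
    family: str = "coif1",
) -> dict[str, float]:
    """376 wavelet features: first-order + texture on each band within the mask.

    Names carry the band index suffix ``_k`` with k = 1..8 in
    :data:`BAND_ORDER` order.
    """
    from ..grids import VolumeGrid  # local import to avoid a cycle

    cfg = cfg or DiscretizationConfig()
    ctx = ctx or RoiTextureContext(mask.values)
    out: dict[str, float] = {}
    bands = wavelet_decompose(volume, family)
    for k, band_name in enumerate(BAND_ORDER, start=1):
        bvol = VolumeGrid(bands[band_name], volume.spacing_mm, volume.origin_mm)
        feats: dict[str, float] = {}
        feats.update(first_order_features(bvol, mask, cfg))
        feats.update(glcm_features(bvol, mask, cfg, ctx))
        feats.update(glrlm_features(bvol, mask, cfg, ctx))
        for name, val in feats.items():
            out[f"{name}_{k}"] = val
    assert len(out) == 8 * (14 + len(GLCM_NAMES) + len(GLRLM_NAMES))
    return out
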