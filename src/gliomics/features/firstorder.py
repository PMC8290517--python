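"""Group 1: 14 first-order statistics of the ROI intensity distribution."""

from __future__ import annotations

import warnings

import numpy as np

from ..errors import InvalidRoiError
from .discretize import DiscretizationConfig, discretize

__all__ = ["FIRST_ORDER_NAMES", "first_order_features", "first_order_from_values"]

FIRST_ORDER_NAMES = (
    "Energy",
    "Entropy",
    "Kurtosis",
    "Maximum",
    "Mean",
    "Mean Absolute Deviation",
    "Median",
    "Minimum",
    "Range",
    "Root Mean Square",
    "Skewness",
    "Standard Deviation",
    "Uniformity",
    "Variance",
)


def first_order_from_values(
    values: np.ndarray, cfg: DiscretizationConfig | None = None
) -> dict[str, float]:
    """First-order statistics of a 1D array of ROI intensities.

    Entropy and uniformity are computed from the fixed-bin-count histogram of
    the discretization config (default 32 bins over the ROI range). Variance
    and standard deviation use the population convention (divide by n).
    Skewness and kurtosis of a zero-variance ROI are degenerate and returned
    as 0 with a warning; kurtosis is the non-excess (Pearson) form m4/m2².
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size == 0:
        raise InvalidRoiError("empty ROI")
    cfg = cfg or DiscretizationConfig()
    n = x.size
    mu = float(x.mean())
    var = float(x.var())
    sd = float(np.sqrt(var))
    m = x - mu
    if var > 0:
        skew = float(np.mean(m**3) / sd**3)
        kurt = float(np.mean(m**4) / var**2)
    else:
        warnings.warn("zero-variance ROI: skewness/kurtosis degenerate, returned as 0")
        skew = kurt = 0.0
    lv = discretize(x, cfg.n_levels)
    p = np.bincount(lv)[1:].astype(np.float64)
    p = p[p > 0] / n
    return {
        "Energy": float(np.sum(x**2)),
        "Entropy": float(-np.sum(p * np.log2(p))),
        "Kurtosis": kurt,
        "Maximum": float(x.max()),
        "Mean": mu,
        "Mean Absolute Deviation": float(np.mean(np.abs(m))),
        "Median": float(np.median(x)),
        "Minimum": float(x.min()),
        "Range": float(x.max() - x.min()),
        "Root Mean Square": float(np.sqrt(np.mean(x**2))),
        "Skewness": skew,
        "Standard Deviation": sd,
        "Uniformity": float(np.sum(p**2)),
        "Variance": var,
    }


def first_order_features(volume, mask, cfg: DiscretizationConfig | None = None) -> dict[str, float]:
    """First-order statistics over the masked voxels of a volume grid."""
    sel = mask.values.astype(bool)
    if not sel.any():
        raise InvalidRoiError("empty mask")
    return first_order_from_values(volume.values[sel], cfg)
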