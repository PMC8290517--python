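"""Gray-level discretization for texture matrices.

Fixed-bin-count binning over the ROI's intensity range (default 32 levels):
texture features become invariant to affine intensity shifts, which keeps
them comparable after per-volume z-scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import InvalidSpecError

__all__ = ["DiscretizationConfig", "discretize"]


@dataclass(frozen=True)
class DiscretizationConfig:
    """Binning rule for gray-level matrices: fixed bin count over ROI range."""

    n_levels: int = 32

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise InvalidSpecError("n_levels must be >= 2")


def discretize(values: np.ndarray, n_levels: int) -> np.ndarray:
    """Map ROI intensities to integer levels 1..n_levels over their min-max range.

    A constant ROI maps entirely to level 1.
    """
    values = np.asarray(values, dtype=np.float64)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones(values.shape, dtype=np.int64)
    lv = np.floor((values - lo) / (hi - lo) * n_levels).astype(np.int64) + 1
    return np.clip(lv, 1, n_levels)
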