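"""Group 3: 33 texture features — 22 GLCM + 11 GLRLM.

Gray-level co-occurrence is accumulated over all 13 unique 3D direction
offsets at distance 1, symmetrized and summed into a single matrix before
feature computation. Run-length matrices are computed per direction and the
11 features averaged over the 13 directions.

Because the neighbor-pair lists and the run-scanning orders depend only on
the mask geometry — not on the intensities — they are precomputed once per
mask in :class:`RoiTextureContext` and reused across the 27 filtered volumes
(3 sequences x (original + 8 wavelet bands)) extracted per subject.

Degenerate single-gray-level ROIs return the analytic limits of every
feature (contrast 0, energy 1, maximum probability 1, IMC 0, ...) rather
than NaN. The three GLCM features whose conventional names collide with
first-order ones are prefixed ("GLCM Energy", "GLCM Entropy",
"GLCM Variance") so each of the 431 per-sequence names is unique.
"""

from __future__ import annotations

import numpy as np

from ..errors import InvalidRoiError
from .discretize import DiscretizationConfig, discretize

__all__ = [
    "DIRECTIONS_3D",
    "GLCM_NAMES",
    "GLRLM_NAMES",
    "RoiTextureContext",
    "glcm_matrix",
    "glcm_features",
    "glrlm_features",
]

#: the 13 unique distance-1 direction offsets of a 3D lattice (26-neighborhood / 2)
DIRECTIONS_3D: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
)

GLCM_NAMES = (
    "Autocorrelation",
    "Cluster Prominence",
    "Cluster Shade",
    "Cluster Tendency",
    "Contrast",
    "Correlation",
    "Difference Entropy",
    "Dissimilarity",
    "GLCM Energy",
    "GLCM Entropy",
    "Homogeneity 1",
    "Homogeneity 2",
    "Informational Measure of Correlation 1",
    "Informational Measure of Correlation 2",
    "Inverse Difference Moment Normalized",
    "Inverse Difference Normalized",
    "Inverse Variance",
    "Maximum Probability",
    "Sum Average",
    "Sum Entropy",
    "Sum Variance",
    "GLCM Variance",
)

GLRLM_NAMES = (
    "Short Run Emphasis",
    "Long Run Emphasis",
    "Gray Level Nonuniformity",
    "Run Length Nonuniformity",
    "Run Percentage",
    "Low Gray Level Run Emphasis",
    "High Gray Level Run Emphasis",
    "Short Run Low Gray Level Emphasis",
    "Short Run High Gray Level Emphasis",
    "Long Run Low Gray Level Emphasis",
    "Long Run High Gray Level Emphasis",
)


class RoiTextureContext:
    """Intensity-independent mask geometry shared by GLCM and GLRLM.

    Holds, for one binary mask: the flat indices of ROI voxels, the
    co-occurring voxel-pair index lists over the 13 offsets, and per
    direction the run-scanning permutation of ROI voxels plus the positions
    where a new scan line (or a gap in the mask) forces a run break.
    """

    def __init__(self, mask_values: np.ndarray):
        mask = np.asarray(mask_values).astype(bool)
        if not mask.any():
            raise InvalidRoiError("empty mask")
        self.shape = mask.shape
        self.roi_flat = np.flatnonzero(mask)
        self.n_voxels = self.roi_flat.size
        # position of each volume voxel inside the ROI list (only valid on ROI)
        pos = np.full(mask.size, -1, dtype=np.int64)
        pos[self.roi_flat] = np.arange(self.n_voxels)

        coords = np.argwhere(mask)  # (N, 3)
        strides = np.array(
            [mask.shape[1] * mask.shape[2], mask.shape[2], 1], dtype=np.int64
        )
        src_all, dst_all = [], []
        self.run_orders: list[tuple[np.ndarray, np.ndarray]] = []
        shp = np.asarray(mask.shape)
        for d in DIRECTIONS_3D:
            dv = np.asarray(d)
            nbr = coords + dv
            ok = np.all((nbr >= 0) & (nbr < shp), axis=1)
            nbr_flat = (nbr[ok] * strides).sum(axis=1)
            in_roi = pos[nbr_flat] >= 0
            src_all.append(pos[(coords[ok][in_roi] * strides).sum(axis=1)])
            dst_all.append(pos[nbr_flat[in_roi]])

            # run scanning order along direction d
            dd = int(dv @ dv)
            t = coords @ dv
            line_key = coords * dd - t[:, None] * dv  # invariant along the line
            order = np.lexsort((t, line_key[:, 2], line_key[:, 1], line_key[:, 0]))
            lk, ts = line_key[order], t[order]
            brk = np.ones(self.n_voxels, dtype=bool)
            if self.n_voxels > 1:
                same_line = np.all(lk[1:] == lk[:-1], axis=1)
                contiguous = (ts[1:] - ts[:-1]) == dd
                brk[1:] = ~(same_line & contiguous)
            self.run_orders.append((order, brk))
        #: ROI-relative (source, destination) index pairs pooled over offsets
        self.pair_src = np.concatenate(src_all) if src_all else np.empty(0, np.int64)
        self.pair_dst = np.concatenate(dst_all) if dst_all else np.empty(0, np.int64)


def _roi_levels(volume, mask, cfg: DiscretizationConfig, ctx: RoiTextureContext):
    vals = volume.values.reshape(-1)[ctx.roi_flat]
    return discretize(vals, cfg.n_levels)


def glcm_matrix(
    volume, mask, cfg: DiscretizationConfig | None = None, ctx: RoiTextureContext | None = None
) -> np.ndarray:
    """Normalized symmetric GLCM summed over the 13 distance-1 directions."""
    cfg = cfg or DiscretizationConfig()
    ctx = ctx or RoiTextureContext(mask.values)
    lv = _roi_levels(volume, mask, cfg, ctx)
    ng = cfg.n_levels
    if ctx.pair_src.size == 0:
        # isolated voxels: no co-occurring pairs; degenerate all-mass-at-(l,l)
        p = np.zeros((ng, ng))
        p[lv[0] - 1, lv[0] - 1] = 1.0
        return p
    a, b = lv[ctx.pair_src] - 1, lv[ctx.pair_dst] - 1
    counts = np.bincount(a * ng + b, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
    counts = counts + counts.T  # symmetrize
    return counts / counts.sum()


def _entropy2(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def glcm_features(
    volume, mask, cfg: DiscretizationConfig | None = None, ctx: RoiTextureContext | None = None
) -> dict[str, float]:
    """The 22 GLCM features from the direction-summed normalized matrix."""
    cfg = cfg or DiscretizationConfig()
    p = glcm_matrix(volume, mask, cfg, ctx)
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)  # = py by symmetry
    mu = float(i @ px)
    sig2 = float(((i - mu) ** 2) @ px)
    sig = np.sqrt(sig2)

    psum = np.bincount((ii + jj).astype(np.int64).ravel(), weights=p.ravel(), minlength=2 * ng + 1)
    pdiff = np.bincount(
        np.abs(ii - jj).astype(np.int64).ravel(), weights=p.ravel(), minlength=ng
    )
    k_sum = np.arange(psum.size, dtype=np.float64)
    k_diff = np.arange(pdiff.size, dtype=np.float64)

    hxy = _entropy2(p.ravel())
    hx = _entropy2(px)
    outer = np.outer(px, px)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_outer = np.where(outer > 0, np.log2(np.where(outer > 0, outer, 1.0)), 0.0)
    hxy1 = float(-np.sum(np.where(p > 0, p * log_outer, 0.0)))
    hxy2 = float(-np.sum(outer * log_outer))

    imc1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    corr = (float(np.sum(ii * jj * p)) - mu * mu) / sig2 if sig2 > 0 else 0.0

    off = ii + jj - 2.0 * mu
    diff2 = (ii - jj) ** 2
    nz = diff2 > 0
    sum_avg = float(k_sum @ psum)
    return {
        "Autocorrelation": float(np.sum(ii * jj * p)),
        "Cluster Prominence": float(np.sum(off**4 * p)),
        "Cluster Shade": float(np.sum(off**3 * p)),
        "Cluster Tendency": float(np.sum(off**2 * p)),
        "Contrast": float(np.sum(diff2 * p)),
        "Correlation": corr,
        "Difference Entropy": _entropy2(pdiff),
        "Dissimilarity": float(np.sum(np.abs(ii - jj) * p)),
        "GLCM Energy": float(np.sum(p**2)),
        "GLCM Entropy": hxy,
        "Homogeneity 1": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Homogeneity 2": float(np.sum(p / (1.0 + diff2))),
        "Informational Measure of Correlation 1": imc1,
        "Informational Measure of Correlation 2": imc2,
        "Inverse Difference Moment Normalized": float(np.sum(p / (1.0 + diff2 / ng**2))),
        "Inverse Difference Normalized": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "Inverse Variance": float(np.sum(p[nz] / diff2[nz])),
        "Maximum Probability": float(p.max()),
        "Sum Average": sum_avg,
        "Sum Entropy": _entropy2(psum),
        "Sum Variance": float(((k_sum - sum_avg) ** 2) @ psum),
        "GLCM Variance": float(np.sum((ii - mu) ** 2 * p)),
    }


def _glrlm_counts(lv_sorted: np.ndarray, brk: np.ndarray, ng: int) -> np.ndarray:
    """Run-length matrix (ng x max_len) from direction-ordered levels."""
    new_run = brk.copy()
    new_run[1:] |= lv_sorted[1:] != lv_sorted[:-1]
    starts = np.flatnonzero(new_run)
    lengths = np.diff(np.append(starts, lv_sorted.size))
    gl = lv_sorted[starts]
    max_len = int(lengths.max())
    counts = np.bincount(
        (gl - 1) * max_len + (lengths - 1), minlength=ng * max_len
    ).reshape(ng, max_len)
    return counts.astype(np.float64)


def _glrlm_features_single(counts: np.ndarray, n_voxels: int) -> dict[str, float]:
    ng, max_len = counts.shape
    nr = counts.sum()
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, max_len + 1, dtype=np.float64)[None, :]
    p = counts / nr
    r_j = counts.sum(axis=0)  # runs per length
    r_i = counts.sum(axis=1)  # runs per gray level
    return {
        "Short Run Emphasis": float(np.sum(p / j**2)),
        "Long Run Emphasis": float(np.sum(p * j**2)),
        "Gray Level Nonuniformity": float(np.sum(r_i**2) / nr),
        "Run Length Nonuniformity": float(np.sum(r_j**2) / nr),
        "Run Percentage": float(nr / n_voxels),
        "Low Gray Level Run Emphasis": float(np.sum(p / i**2)),
        "High Gray Level Run Emphasis": float(np.sum(p * i**2)),
        "Short Run Low Gray Level Emphasis": float(np.sum(p / (i**2 * j**2))),
        "Short Run High Gray Level Emphasis": float(np.sum(p * i**2 / j**2)),
        "Long Run Low Gray Level Emphasis": float(np.sum(p * j**2 / i**2)),
        "Long Run High Gray Level Emphasis": float(np.sum(p * i**2 * j**2)),
    }


def glrlm_features(
    volume, mask, cfg: DiscretizationConfig | None = None, ctx: RoiTextureContext | None = None
) -> dict[str, float]:
    """The 11 run-length features, averaged feature-wise over 13 directions."""
    cfg = cfg or DiscretizationConfig()
    ctx = ctx or RoiTextureContext(mask.values)
    lv = _roi_levels(volume, mask, cfg, ctx)
    acc = {name: 0.0 for name in GLRLM_NAMES}
    for order, brk in ctx.run_orders:
        counts = _glrlm_counts(lv[order], brk, cfg.n_levels)
        for name, val in _glrlm_features_single(counts, ctx.n_voxels).items():
            acc[name] += val
    n_dir = len(ctx.run_orders)
    return {name: val / n_dir for name, val in acc.items()}
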