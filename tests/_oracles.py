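"""Independent brute-force oracles for texture features.

Everything here is deliberately loop-based and written from the matrix
definitions, sharing no code with the package implementation. Used on tiny
ROIs (<= a few hundred voxels) where exhaustive enumeration is feasible.
"""

import math

import numpy as np

DIRECTIONS = [
    (1, 0, 0), (0, 1, 0), (0, 0, 1),
    (1, 1, 0), (1, -1, 0), (1, 0, 1), (1, 0, -1), (0, 1, 1), (0, 1, -1),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


def discretize_oracle(values, n_levels):
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones_like(values, dtype=int)
    lv = np.floor((values - lo) / (hi - lo) * n_levels).astype(int) + 1
    return np.minimum(lv, n_levels)


def _level_volume(volume, mask, n_levels):
    lv = np.zeros(mask.shape, dtype=int)
    lv[mask.astype(bool)] = discretize_oracle(volume[mask.astype(bool)], n_levels)
    return lv


def glcm_matrix_bruteforce(volume, mask, n_levels):
    """Count every co-occurring ordered pair over all 26 neighbor offsets."""
    mask = mask.astype(bool)
    lv = _level_volume(volume, mask, n_levels)
    m = np.zeros((n_levels, n_levels))
    offsets = [d for d in DIRECTIONS] + [(-a, -b, -c) for a, b, c in DIRECTIONS]
    for x, y, z in zip(*np.nonzero(mask)):
        for dx, dy, dz in offsets:
            u, v, w = x + dx, y + dy, z + dz
            if 0 <= u < mask.shape[0] and 0 <= v < mask.shape[1] and 0 <= w < mask.shape[2]:
                if mask[u, v, w]:
                    m[lv[x, y, z] - 1, lv[u, v, w] - 1] += 1
    return m / m.sum()


def glcm_features_bruteforce(volume, mask, n_levels):
    p = glcm_matrix_bruteforce(volume, mask, n_levels)
    ng = p.shape[0]
    px = p.sum(axis=1)
    mu = sum((i + 1) * px[i] for i in range(ng))
    sig2 = sum((i + 1 - mu) ** 2 * px[i] for i in range(ng))
    psum = np.zeros(2 * ng + 1)
    pdiff = np.zeros(ng)
    feats = dict.fromkeys(
        [
            "Autocorrelation", "Cluster Prominence", "Cluster Shade", "Cluster Tendency",
            "Contrast", "Correlation", "Difference Entropy", "Dissimilarity",
            "GLCM Energy", "GLCM Entropy", "Homogeneity 1", "Homogeneity 2",
            "Informational Measure of Correlation 1", "Informational Measure of Correlation 2",
            "Inverse Difference Moment Normalized", "Inverse Difference Normalized",
            "Inverse Variance", "Maximum Probability", "Sum Average", "Sum Entropy",
            "Sum Variance", "GLCM Variance",
        ],
        0.0,
    )
    hxy = hxy1 = hxy2 = 0.0
    for i in range(ng):
        for j in range(ng):
            v = p[i, j]
            a, b = i + 1, j + 1
            psum[a + b] += v
            pdiff[abs(a - b)] += v
            feats["Autocorrelation"] += a * b * v
            feats["Cluster Prominence"] += (a + b - 2 * mu) ** 4 * v
            feats["Cluster Shade"] += (a + b - 2 * mu) ** 3 * v
            feats["Cluster Tendency"] += (a + b - 2 * mu) ** 2 * v
            feats["Contrast"] += (a - b) ** 2 * v
            feats["Dissimilarity"] += abs(a - b) * v
            feats["GLCM Energy"] += v * v
            feats["Homogeneity 1"] += v / (1 + abs(a - b))
            feats["Homogeneity 2"] += v / (1 + (a - b) ** 2)
            feats["Inverse Difference Moment Normalized"] += v / (1 + (a - b) ** 2 / ng**2)
            feats["Inverse Difference Normalized"] += v / (1 + abs(a - b) / ng)
            if a != b:
                feats["Inverse Variance"] += v / (a - b) ** 2
            feats["GLCM Variance"] += (a - mu) ** 2 * v
            if v > 0:
                hxy -= v * math.log2(v)
            if px[i] * px[j] > 0:
                if v > 0:
                    hxy1 -= v * math.log2(px[i] * px[j])
                hxy2 -= px[i] * px[j] * math.log2(px[i] * px[j])
    hx = -sum(q * math.log2(q) for q in px if q > 0)
    feats["GLCM Entropy"] = hxy
    feats["Correlation"] = (feats["Autocorrelation"] - mu * mu) / sig2 if sig2 > 0 else 0.0
    feats["Informational Measure of Correlation 1"] = (hxy - hxy1) / hx if hx > 0 else 0.0
    feats["Informational Measure of Correlation 2"] = math.sqrt(
        max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy)))
    )
    feats["Maximum Probability"] = float(p.max())
    sa = sum(k * psum[k] for k in range(len(psum)))
    feats["Sum Average"] = sa
    feats["Sum Entropy"] = -sum(q * math.log2(q) for q in psum if q > 0)
    feats["Sum Variance"] = sum((k - sa) ** 2 * psum[k] for k in range(len(psum)))
    feats["Difference Entropy"] = -sum(q * math.log2(q) for q in pdiff if q > 0)
    return feats


def glrlm_runs_bruteforce(volume, mask, n_levels, direction):
    """All maximal same-level runs along one direction, as (level, length)."""
    mask = mask.astype(bool)
    lv = _level_volume(volume, mask, n_levels)
    sh = mask.shape

    def inside(c):
        return all(0 <= c[i] < sh[i] for i in range(3)) and mask[tuple(c)]

    runs = []
    for start in zip(*np.nonzero(mask)):
        prev = tuple(np.array(start) - direction)
        # only count runs from their first voxel
        if inside(prev) and lv[prev] == lv[start]:
            continue
        length = 1
        cur = np.array(start)
        while True:
            nxt = cur + direction
            if inside(tuple(nxt)) and lv[tuple(nxt)] == lv[tuple(start)]:
                length += 1
                cur = nxt
            else:
                break
        runs.append((int(lv[start]), length))
    return runs


def glrlm_features_bruteforce(volume, mask, n_levels):
    """11 run-length features averaged over the 13 directions."""
    n_vox = int(mask.astype(bool).sum())
    names = [
        "Short Run Emphasis", "Long Run Emphasis", "Gray Level Nonuniformity",
        "Run Length Nonuniformity", "Run Percentage", "Low Gray Level Run Emphasis",
        "High Gray Level Run Emphasis", "Short Run Low Gray Level Emphasis",
        "Short Run High Gray Level Emphasis", "Long Run Low Gray Level Emphasis",
        "Long Run High Gray Level Emphasis",
    ]
    acc = dict.fromkeys(names, 0.0)
    for d in DIRECTIONS:
        runs = glrlm_runs_bruteforce(volume, mask, n_levels, np.array(d))
        nr = len(runs)
        by_level = {}
        by_length = {}
        f = dict.fromkeys(names, 0.0)
        for g, l in runs:
            by_level[g] = by_level.get(g, 0) + 1
            by_length[l] = by_length.get(l, 0) + 1
            f["Short Run Emphasis"] += 1.0 / (nr * l**2)
            f["Long Run Emphasis"] += l**2 / nr
            f["Low Gray Level Run Emphasis"] += 1.0 / (nr * g**2)
            f["High Gray Level Run Emphasis"] += g**2 / nr
            f["Short Run Low Gray Level Emphasis"] += 1.0 / (nr * g**2 * l**2)
            f["Short Run High Gray Level Emphasis"] += g**2 / (nr * l**2)
            f["Long Run Low Gray Level Emphasis"] += l**2 / (nr * g**2)
            f["Long Run High Gray Level Emphasis"] += g**2 * l**2 / nr
        f["Gray Level Nonuniformity"] = sum(c**2 for c in by_level.values()) / nr
        f["Run Length Nonuniformity"] = sum(c**2 for c in by_length.values()) / nr
        f["Run Percentage"] = nr / n_vox
        for k in names:
            acc[k] += f[k]
    return {k: v / len(DIRECTIONS) for k, v in acc.items()}


def auc_pairwise_bruteforce(scores, labels):
    """AUC by exhaustive positive-negative pair concordance with tie = 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for sp in pos:
        for sn in neg:
            total += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
    return total / (len(pos) * len(neg))
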