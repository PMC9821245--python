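"""Independent brute-force oracles for texture features and statistics.

Everything here enumerates voxel pairs/neighbourhoods with plain Python
loops and computes features from first principles, deliberately sharing
no code with the package implementation.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

CHEB3D = [(dz, dy, dx) for dz in (-1, 0, 1) for dy in (-1, 0, 1)
          for dx in (-1, 0, 1) if (dz, dy, dx) != (0, 0, 0)]
CHEB2D = [(0, dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
          if (dy, dx) != (0, 0)]
DIRS_2D = [(0, 0, 1), (0, 1, 0), (0, 1, 1), (0, 1, -1)]
DIRS_3D = [d for d in itertools.product((0, 1), (-1, 0, 1), (-1, 0, 1))
           if d > (0, 0, 0)]


def bf_glcm_counts(levels, mask, offset, n_bins):
    """Symmetric co-occurrence counts by enumerating every voxel."""
    counts = np.zeros((n_bins, n_bins))
    Z, Y, X = levels.shape
    for z in range(Z):
        for y in range(Y):
            for x in range(X):
                if not mask[z, y, x]:
                    continue
                q = (z + offset[0], y + offset[1], x + offset[2])
                if all(0 <= q[i] < levels.shape[i] for i in range(3)) \
                        and mask[q]:
                    a, b = levels[z, y, x] - 1, levels[q] - 1
                    counts[a, b] += 1
                    counts[b, a] += 1
    return counts


def bf_glcm_feature_from_counts(counts, feature):
    total = counts.sum()
    if total == 0:
        return None
    P = counts / total
    n = P.shape[0]
    if feature == "contrast":
        return sum((i - j) ** 2 * P[i, j] for i in range(n) for j in range(n))
    if feature == "dissimilarity":
        return sum(abs(i - j) * P[i, j] for i in range(n) for j in range(n))
    pk = [sum(P[i, j] for i in range(n) for j in range(n)
              if abs(i - j) == k) for k in range(n)]
    da = sum(k * pk[k] for k in range(n))
    if feature == "difference_average":
        return da
    if feature == "difference_variance":
        return sum((k - da) ** 2 * pk[k] for k in range(n))
    raise ValueError(feature)


def bf_glcm_aggregate(levels, mask, n_bins, feature, mode):
    """Aggregated GLCM feature by explicit matrix-set construction."""
    Z = levels.shape[0]

    def slice_counts(z, d):
        m = np.zeros_like(mask)
        m[z] = mask[z]
        return bf_glcm_counts(levels, m, d, n_bins)

    if mode == "2Davg":
        vals = [bf_glcm_feature_from_counts(slice_counts(z, d), feature)
                for z in range(Z) for d in DIRS_2D]
    elif mode == "2Dmrg":
        vals = [bf_glcm_feature_from_counts(
            sum(slice_counts(z, d) for d in DIRS_2D), feature)
            for z in range(Z)]
    elif mode == "2DDmrg":
        vals = [bf_glcm_feature_from_counts(
            sum(slice_counts(z, d) for z in range(Z)), feature)
            for d in DIRS_2D]
    elif mode == "2Dvmrg":
        vals = [bf_glcm_feature_from_counts(
            sum(slice_counts(z, d) for z in range(Z) for d in DIRS_2D),
            feature)]
    elif mode == "3Davg":
        vals = [bf_glcm_feature_from_counts(
            bf_glcm_counts(levels, mask, d, n_bins), feature)
            for d in DIRS_3D]
    elif mode == "3Dmrg":
        vals = [bf_glcm_feature_from_counts(
            sum(bf_glcm_counts(levels, mask, d, n_bins) for d in DIRS_3D),
            feature)]
    else:
        raise ValueError(mode)
    vals = [v for v in vals if v is not None]
    if not vals:
        return None
    return float(np.mean(vals))


def _bf_ngtdm_tables(levels, mask, n_bins, offsets):
    n_i = np.zeros(n_bins)
    s_i = np.zeros(n_bins)
    Z, Y, X = levels.shape
    for z in range(Z):
        for y in range(Y):
            for x in range(X):
                if not mask[z, y, x]:
                    continue
                nbrs = []
                for dz, dy, dx in offsets:
                    q = (z + dz, y + dy, x + dx)
                    if all(0 <= q[i] < levels.shape[i] for i in range(3)) \
                            and mask[q]:
                        nbrs.append(levels[q])
                if not nbrs:
                    continue
                i = levels[z, y, x] - 1
                n_i[i] += 1
                s_i[i] += abs(levels[z, y, x] - np.mean(nbrs))
    return n_i, s_i


def bf_ngtdm_complexity(levels, mask, n_bins, mode):
    if mode == "3D":
        n_i, s_i = _bf_ngtdm_tables(levels, mask, n_bins, CHEB3D)
    else:  # 2Dmrg: per-slice in-plane tables merged over slices
        n_i = np.zeros(n_bins)
        s_i = np.zeros(n_bins)
        for z in range(levels.shape[0]):
            m = np.zeros_like(mask)
            m[z] = mask[z]
            ni, si = _bf_ngtdm_tables(levels, m, n_bins, CHEB2D)
            n_i += ni
            s_i += si
    n_vc = n_i.sum()
    if n_vc == 0:
        return None
    p = n_i / n_vc
    total = 0.0
    for a in range(n_bins):
        for b in range(n_bins):
            if a != b and p[a] > 0 and p[b] > 0:
                total += abs(a - b) * (p[a] * s_i[a] + p[b] * s_i[b]) / (
                    p[a] + p[b])
    return total / n_vc


def bf_ngldm_energy(levels, mask, n_bins, alpha=0):
    """3D dependence count energy by per-voxel neighbour counting."""
    from collections import Counter

    cells = Counter()
    Z, Y, X = levels.shape
    n_s = 0
    for z in range(Z):
        for y in range(Y):
            for x in range(X):
                if not mask[z, y, x]:
                    continue
                dep = 0
                for dz, dy, dx in CHEB3D:
                    q = (z + dz, y + dy, x + dx)
                    if all(0 <= q[i] < levels.shape[i] for i in range(3)) \
                            and mask[q] \
                            and abs(int(levels[z, y, x]) - int(levels[q])) \
                            <= alpha:
                        dep += 1
                cells[(levels[z, y, x], dep)] += 1
                n_s += 1
    return sum((c / n_s) ** 2 for c in cells.values())


def bf_gearys_c(image, mask, spacing):
    """Geary's C with inverse-distance weights, full double loop."""
    pts = np.argwhere(mask)
    x = image[mask].astype(float)
    n = len(x)
    num = 0.0
    W = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = math.dist(pts[i] * np.asarray(spacing),
                          pts[j] * np.asarray(spacing))
            w = 1.0 / d
            W += w
            num += w * (x[i] - x[j]) ** 2
    den = np.sum((x - x.mean()) ** 2)
    if den == 0:
        return None
    return (n - 1) / (2.0 * W) * num / den


def bf_auc_mannwhitney(scores, labels):
    """AUC as the Mann-Whitney U statistic / (n1 n0), ties = 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, bool)
    pos = scores[labels]
    neg = scores[~labels]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


def bf_mcnemar_midp(b, c):
    """Mid-p McNemar by explicit binomial enumeration."""
    n = b + c
    k = min(b, c)
    def pmf(i):
        return math.comb(n, i) * 0.5 ** n
    return min(1.0, 2.0 * sum(pmf(i) for i in range(k + 1)) - pmf(k))
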