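"""Naive brute-force reference implementations used as independent oracles.

Everything here is written with explicit Python loops over voxels and
matrix entries, following the textbook definitions directly, so that
agreement with the vectorized implementations is a meaningful check.
"""

from __future__ import annotations

import math

import numpy as np


def _in_bounds(p, shape):
    return all(0 <= c < n for c, n in zip(p, shape))


def _voxels(mask):
    return [tuple(p) for p in np.argwhere(mask)]


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix_naive(levels, mask, ng, offset):
    mat = np.zeros((ng, ng))
    for p in _voxels(mask):
        q = tuple(c + o for c, o in zip(p, offset))
        if _in_bounds(q, mask.shape) and mask[q]:
            mat[levels[p] - 1, levels[q] - 1] += 1
            mat[levels[q] - 1, levels[p] - 1] += 1
    return mat


def glcm_features_naive(P):
    ng = P.shape[0]
    eps = np.spacing(1.0)
    px = [sum(P[i, j] for j in range(ng)) for i in range(ng)]
    py = [sum(P[i, j] for i in range(ng)) for j in range(ng)]
    mux = sum((i + 1) * px[i] for i in range(ng))
    muy = sum((j + 1) * py[j] for j in range(ng))
    sigx = math.sqrt(sum(px[i] * ((i + 1) - mux) ** 2 for i in range(ng)))
    sigy = math.sqrt(sum(py[j] * ((j + 1) - muy) ** 2 for j in range(ng)))
    p_sum = {k: 0.0 for k in range(2, 2 * ng + 1)}
    p_diff = {k: 0.0 for k in range(0, ng)}
    for i in range(ng):
        for j in range(ng):
            p_sum[i + j + 2] += P[i, j]
            p_diff[abs(i - j)] += P[i, j]
    f = {}
    f["Autocorrelation"] = sum(
        P[i, j] * (i + 1) * (j + 1) for i in range(ng) for j in range(ng)
    )
    f["JointAverage"] = mux
    for name, power in (("ClusterProminence", 4), ("ClusterShade", 3),
                        ("ClusterTendency", 2)):
        f[name] = sum(
            P[i, j] * ((i + 1) + (j + 1) - mux - muy) ** power
            for i in range(ng) for j in range(ng)
        )
    f["Contrast"] = sum(
        P[i, j] * (i - j) ** 2 for i in range(ng) for j in range(ng)
    )
    if sigx > 0 and sigy > 0:
        f["Correlation"] = (f["Autocorrelation"] - mux * muy) / (sigx * sigy)
    else:
        f["Correlation"] = 1.0
    da = sum(k * v for k, v in p_diff.items())
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = -sum(
        v * math.log2(v + eps) for v in p_diff.values()
    )
    f["DifferenceVariance"] = sum(
        v * (k - da) ** 2 for k, v in p_diff.items()
    )
    f["JointEnergy"] = sum(P[i, j] ** 2 for i in range(ng) for j in range(ng))
    hxy = -sum(
        P[i, j] * math.log2(P[i, j] + eps) for i in range(ng) for j in range(ng)
    )
    f["JointEntropy"] = hxy
    hxy1 = -sum(
        P[i, j] * math.log2(px[i] * py[j] + eps)
        for i in range(ng) for j in range(ng)
    )
    hxy2 = -sum(
        px[i] * py[j] * math.log2(px[i] * py[j] + eps)
        for i in range(ng) for j in range(ng)
    )
    hx = -sum(v * math.log2(v + eps) for v in px)
    hy = -sum(v * math.log2(v + eps) for v in py)
    f["Imc1"] = (hxy - hxy1) / max(hx, hy) if max(hx, hy) > 0 else 0.0
    f["Imc2"] = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - hxy))))
    f["Idm"] = sum(
        P[i, j] / (1.0 + (i - j) ** 2) for i in range(ng) for j in range(ng)
    )
    f["Idmn"] = sum(
        P[i, j] / (1.0 + (i - j) ** 2 / ng**2)
        for i in range(ng) for j in range(ng)
    )
    f["Id"] = sum(
        P[i, j] / (1.0 + abs(i - j)) for i in range(ng) for j in range(ng)
    )
    f["Idn"] = sum(
        P[i, j] / (1.0 + abs(i - j) / ng) for i in range(ng) for j in range(ng)
    )
    f["InverseVariance"] = sum(
        P[i, j] / (i - j) ** 2 for i in range(ng) for j in range(ng) if i != j
    )
    f["MaximumProbability"] = max(
        P[i, j] for i in range(ng) for j in range(ng)
    )
    f["SumAverage"] = sum(k * v for k, v in p_sum.items())
    f["SumEntropy"] = -sum(v * math.log2(v + eps) for v in p_sum.values())
    f["SumSquares"] = sum(
        P[i, j] * ((i + 1) - mux) ** 2 for i in range(ng) for j in range(ng)
    )
    if ng > 1:
        Q = np.zeros((ng, ng))
        for i in range(ng):
            for j in range(ng):
                acc = 0.0
                for k in range(ng):
                    if px[i] > 0 and py[k] > 0:
                        acc += P[i, k] * P[j, k] / (px[i] * py[k])
                Q[i, j] = acc
        ev = sorted(np.real(np.linalg.eigvals(Q)), reverse=True)
        f["MCC"] = math.sqrt(max(0.0, min(1.0, ev[1])))
    else:
        f["MCC"] = 1.0
    return f


def glcm_naive(levels, mask, ng, offsets):
    acc = {}
    for off in offsets:
        mat = glcm_matrix_naive(levels, mask, ng, off)
        if mat.sum() == 0:
            continue
        for k, v in glcm_features_naive(mat / mat.sum()).items():
            acc.setdefault(k, []).append(v)
    return {k: float(np.mean(v)) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrix_naive(levels, mask, ng, direction):
    runs = []
    for p in _voxels(mask):
        prev = tuple(c - o for c, o in zip(p, direction))
        if _in_bounds(prev, mask.shape) and mask[prev] and levels[prev] == levels[p]:
            continue  # not a run start
        length = 1
        q = tuple(c + o for c, o in zip(p, direction))
        while _in_bounds(q, mask.shape) and mask[q] and levels[q] == levels[p]:
            length += 1
            q = tuple(c + o for c, o in zip(q, direction))
        runs.append((levels[p], length))
    lmax = max(l for _, l in runs)
    mat = np.zeros((ng, lmax))
    for lev, length in runs:
        mat[lev - 1, length - 1] += 1
    return mat


def glrlm_features_naive(R, n_voxels):
    eps = np.spacing(1.0)
    ng, lmax = R.shape
    nr = R.sum()
    f = {k: 0.0 for k in (
        "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelVariance",
        "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
        "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
        "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
        "LongRunHighGrayLevelEmphasis")}
    mu_i = sum(
        R[i, l] / nr * (i + 1) for i in range(ng) for l in range(lmax)
    )
    mu_l = sum(
        R[i, l] / nr * (l + 1) for i in range(ng) for l in range(lmax)
    )
    for i in range(ng):
        for l in range(lmax):
            p = R[i, l] / nr
            gi, rl = i + 1, l + 1
            f["ShortRunEmphasis"] += p / rl**2
            f["LongRunEmphasis"] += p * rl**2
            f["GrayLevelVariance"] += p * (gi - mu_i) ** 2
            f["RunVariance"] += p * (rl - mu_l) ** 2
            f["RunEntropy"] -= p * math.log2(p + eps)
            f["LowGrayLevelRunEmphasis"] += p / gi**2
            f["HighGrayLevelRunEmphasis"] += p * gi**2
            f["ShortRunLowGrayLevelEmphasis"] += p / (gi**2 * rl**2)
            f["ShortRunHighGrayLevelEmphasis"] += p * gi**2 / rl**2
            f["LongRunLowGrayLevelEmphasis"] += p * rl**2 / gi**2
            f["LongRunHighGrayLevelEmphasis"] += p * gi**2 * rl**2
    f["GrayLevelNonUniformity"] = sum(
        sum(R[i, :]) ** 2 for i in range(ng)
    ) / nr
    f["GrayLevelNonUniformityNormalized"] = sum(
        (sum(R[i, :]) / nr) ** 2 for i in range(ng)
    )
    f["RunLengthNonUniformity"] = sum(
        sum(R[:, l]) ** 2 for l in range(lmax)
    ) / nr
    f["RunLengthNonUniformityNormalized"] = sum(
        (sum(R[:, l]) / nr) ** 2 for l in range(lmax)
    )
    f["RunPercentage"] = nr / n_voxels
    return f


def glrlm_naive(levels, mask, ng, directions):
    n_vox = int(mask.sum())
    acc = {}
    for d in directions:
        mat = glrlm_matrix_naive(levels, mask, ng, d)
        for k, v in glrlm_features_naive(mat, n_vox).items():
            acc.setdefault(k, []).append(v)
    return {k: float(np.mean(v)) for k, v in acc.items()}


# ---------------------------------------------------------------------------
# GLSZM (flood fill per level)

_NBRS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def glszm_matrix_naive(levels, mask, ng):
    seen = np.zeros_like(mask, dtype=bool)
    zones = []
    for p in _voxels(mask):
        if seen[p]:
            continue
        level = levels[p]
        stack, size = [p], 0
        seen[p] = True
        while stack:
            cur = stack.pop()
            size += 1
            for off in _NBRS:
                q = tuple(c + o for c, o in zip(cur, off))
                if (_in_bounds(q, mask.shape) and mask[q] and not seen[q]
                        and levels[q] == level):
                    seen[q] = True
                    stack.append(q)
        zones.append((level, size))
    smax = max(s for _, s in zones)
    mat = np.zeros((ng, smax))
    for lev, size in zones:
        mat[lev - 1, size - 1] += 1
    return mat


def glszm_naive(levels, mask, ng):
    mat = glszm_matrix_naive(levels, mask, ng)
    feats = glrlm_features_naive(mat, int(mask.sum()))
    rename = {
        "ShortRunEmphasis": "SmallAreaEmphasis",
        "LongRunEmphasis": "LargeAreaEmphasis",
        "RunLengthNonUniformity": "SizeZoneNonUniformity",
        "RunLengthNonUniformityNormalized": "SizeZoneNonUniformityNormalized",
        "RunPercentage": "ZonePercentage",
        "RunVariance": "ZoneVariance",
        "RunEntropy": "ZoneEntropy",
        "LowGrayLevelRunEmphasis": "LowGrayLevelZoneEmphasis",
        "HighGrayLevelRunEmphasis": "HighGrayLevelZoneEmphasis",
        "ShortRunLowGrayLevelEmphasis": "SmallAreaLowGrayLevelEmphasis",
        "ShortRunHighGrayLevelEmphasis": "SmallAreaHighGrayLevelEmphasis",
        "LongRunLowGrayLevelEmphasis": "LargeAreaLowGrayLevelEmphasis",
        "LongRunHighGrayLevelEmphasis": "LargeAreaHighGrayLevelEmphasis",
    }
    return {rename.get(k, k): v for k, v in feats.items()}


# ---------------------------------------------------------------------------
# GLDM


def gldm_matrix_naive(levels, mask, ng, alpha=0):
    entries = []
    for p in _voxels(mask):
        k = 0
        for off in _NBRS:
            q = tuple(c + o for c, o in zip(p, off))
            if (_in_bounds(q, mask.shape) and mask[q]
                    and abs(int(levels[q]) - int(levels[p])) <= alpha):
                k += 1
        entries.append((levels[p], k))
    kmax = max(k for _, k in entries)
    mat = np.zeros((ng, kmax + 1))
    for lev, k in entries:
        mat[lev - 1, k] += 1
    return mat


def gldm_naive(levels, mask, ng, alpha=0):
    eps = np.spacing(1.0)
    D = gldm_matrix_naive(levels, mask, ng, alpha)
    nz = D.sum()
    ng_, kmax1 = D.shape
    mu_i = sum(
        D[i, k] / nz * (i + 1) for i in range(ng_) for k in range(kmax1)
    )
    mu_j = sum(
        D[i, k] / nz * (k + 1) for i in range(ng_) for k in range(kmax1)
    )
    f = {k: 0.0 for k in (
        "SmallDependenceEmphasis", "LargeDependenceEmphasis",
        "GrayLevelVariance", "DependenceVariance", "DependenceEntropy",
        "LowGrayLevelEmphasis", "HighGrayLevelEmphasis",
        "SmallDependenceLowGrayLevelEmphasis",
        "SmallDependenceHighGrayLevelEmphasis",
        "LargeDependenceLowGrayLevelEmphasis",
        "LargeDependenceHighGrayLevelEmphasis")}
    for i in range(ng_):
        for k in range(kmax1):
            p = D[i, k] / nz
            gi, dj = i + 1, k + 1  # dependence size includes the center voxel
            f["SmallDependenceEmphasis"] += p / dj**2
            f["LargeDependenceEmphasis"] += p * dj**2
            f["GrayLevelVariance"] += p * (gi - mu_i) ** 2
            f["DependenceVariance"] += p * (dj - mu_j) ** 2
            f["DependenceEntropy"] -= p * math.log2(p + eps)
            f["LowGrayLevelEmphasis"] += p / gi**2
            f["HighGrayLevelEmphasis"] += p * gi**2
            f["SmallDependenceLowGrayLevelEmphasis"] += p / (gi**2 * dj**2)
            f["SmallDependenceHighGrayLevelEmphasis"] += p * gi**2 / dj**2
            f["LargeDependenceLowGrayLevelEmphasis"] += p * dj**2 / gi**2
            f["LargeDependenceHighGrayLevelEmphasis"] += p * gi**2 * dj**2
    f["GrayLevelNonUniformity"] = sum(
        sum(D[i, :]) ** 2 for i in range(ng_)
    ) / nz
    f["DependenceNonUniformity"] = sum(
        sum(D[:, k]) ** 2 for k in range(kmax1)
    ) / nz
    f["DependenceNonUniformityNormalized"] = sum(
        sum(D[:, k]) ** 2 for k in range(kmax1)
    ) / nz**2
    return f


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_naive(levels, mask, ng):
    n = np.zeros(ng)
    s = np.zeros(ng)
    for p in _voxels(mask):
        nbr = []
        for off in _NBRS:
            q = tuple(c + o for c, o in zip(p, off))
            if _in_bounds(q, mask.shape) and mask[q]:
                nbr.append(levels[q])
        if not nbr:
            continue
        i = levels[p] - 1
        n[i] += 1
        s[i] += abs(levels[p] - sum(nbr) / len(nbr))
    N = n.sum()
    p = n / N
    present = [i for i in range(ng) if p[i] > 0]
    ngp = len(present)
    denom = sum(p[i] * s[i] for i in range(ng))
    f = {"Coarseness": 1.0 / denom if denom > 0 else 1e6}
    if ngp > 1:
        f["Contrast"] = (
            sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
            / (ngp * (ngp - 1)) * s.sum() / N
        )
        busy = sum(
            abs((i + 1) * p[i] - (j + 1) * p[j])
            for i in present for j in present
        )
        f["Busyness"] = denom / busy if busy > 0 else 0.0
        f["Complexity"] = sum(
            abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
            for i in present for j in present
        ) / N
        stot = s.sum()
        f["Strength"] = (
            sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present)
            / stot if stot > 0 else 0.0
        )
    else:
        f.update(Contrast=0.0, Busyness=0.0, Complexity=0.0, Strength=0.0)
    return f
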