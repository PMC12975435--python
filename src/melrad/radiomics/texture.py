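"""Texture-matrix features on discretized regions.

Five matrix families are implemented on 3D regions of integer gray levels:

* GLCM  — symmetric co-occurrence counts at distance 1, per direction;
* GLRLM — maximal same-level runs, per direction;
* GLSZM — 26-connected same-level zones (direction-free);
* GLDM  — per-voxel counts of "dependent" 26-neighbors (|Δlevel| <= alpha);
* NGTDM — absolute difference between a voxel level and its 26-neighborhood
  mean.

Directional families use the 13 unique direction vectors of the 26-
neighborhood at distance 1 and report the per-direction feature values
averaged over directions. Normalized matrices sum to one; variance- and
prominence-like features are zero on constant regions. Degenerate regions
(fewer than two voxels for the GLCM) yield a documented fallback of 0 for
every feature, with a warning.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedRegion

__all__ = [
    "unique_directions",
    "all_neighbor_offsets",
    "glcm_matrix",
    "glcm_features",
    "glrlm_matrix",
    "glrlm_features",
    "glszm_matrix",
    "glszm_features",
    "gldm_matrix",
    "gldm_features",
    "ngtdm_table",
    "ngtdm_features",
]

_EPS = np.spacing(1.0)


def unique_directions() -> list[tuple[int, int, int]]:
    """The 13 unique (up to sign) 3D direction vectors at distance 1."""
    dirs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                if (dz, dy, dx) < (0, 0, 0):
                    continue  # keep one of each +/- pair
                dirs.append((dz, dy, dx))
    assert len(dirs) == 13
    return dirs


def all_neighbor_offsets() -> list[tuple[int, int, int]]:
    """All 26 neighbor offsets of the 3D Moore neighborhood."""
    return [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]


def _slices(shape, offset):
    """Slice pair (src, dst) such that A[dst] aligns with positions p and
    A[src] with positions p + offset, over all valid p."""
    src, dst = [], []
    for n, o in zip(shape, offset):
        if o >= 0:
            src.append(slice(o, n))
            dst.append(slice(0, n - o))
        else:
            src.append(slice(0, n + o))
            dst.append(slice(-o, n))
    return tuple(src), tuple(dst)


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(region: DiscretizedRegion, offset) -> np.ndarray:
    """Symmetric co-occurrence counts for one voxel offset."""
    lv, m = region.levels, region.mask
    src, dst = _slices(lv.shape, offset)
    valid = m[dst] & m[src]
    i = lv[dst][valid] - 1
    j = lv[src][valid] - 1
    mat = np.zeros((region.n_levels, region.n_levels))
    np.add.at(mat, (i, j), 1.0)
    np.add.at(mat, (j, i), 1.0)
    return mat


def _glcm_features_from_matrix(P: np.ndarray) -> dict[str, float]:
    ng = P.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii = i[:, None]
    jj = i[None, :]
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mux = float((px * i).sum())
    muy = float((py * i).sum())
    sigx = float(np.sqrt((px * (i - mux) ** 2).sum()))
    sigy = float(np.sqrt((py * (i - muy) ** 2).sum()))

    k_sum = np.arange(2, 2 * ng + 1, dtype=float)
    p_sum = np.zeros(k_sum.size)
    k_diff = np.arange(0, ng, dtype=float)
    p_diff = np.zeros(k_diff.size)
    sums = (ii + jj).astype(int)
    diffs = np.abs(ii - jj).astype(int)
    np.add.at(p_sum, sums.ravel() - 2, P.ravel())
    np.add.at(p_diff, diffs.ravel(), P.ravel())

    f: dict[str, float] = {}
    f["Autocorrelation"] = float((P * ii * jj).sum())
    f["JointAverage"] = mux
    cm = ii + jj - mux - muy
    f["ClusterProminence"] = float((P * cm**4).sum())
    f["ClusterShade"] = float((P * cm**3).sum())
    f["ClusterTendency"] = float((P * cm**2).sum())
    f["Contrast"] = float((P * (ii - jj) ** 2).sum())
    if sigx > 0 and sigy > 0:
        f["Correlation"] = (f["Autocorrelation"] - mux * muy) / (sigx * sigy)
    else:
        f["Correlation"] = 1.0  # single gray level: perfectly correlated
    da = float((p_diff * k_diff).sum())
    f["DifferenceAverage"] = da
    f["DifferenceEntropy"] = float(-(p_diff * np.log2(p_diff + _EPS)).sum())
    f["DifferenceVariance"] = float((p_diff * (k_diff - da) ** 2).sum())
    f["JointEnergy"] = float((P**2).sum())
    hxy = float(-(P * np.log2(P + _EPS)).sum())
    f["JointEntropy"] = hxy
    pxpy = px[:, None] * py[None, :]
    hxy1 = float(-(P * np.log2(pxpy + _EPS)).sum())
    hxy2 = float(-(pxpy * np.log2(pxpy + _EPS)).sum())
    hx = float(-(px * np.log2(px + _EPS)).sum())
    hy = float(-(py * np.log2(py + _EPS)).sum())
    div = max(hx, hy)
    f["Imc1"] = (hxy - hxy1) / div if div > 0 else 0.0
    f["Imc2"] = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    d2 = (ii - jj) ** 2
    f["Idm"] = float((P / (1.0 + d2)).sum())
    f["Idmn"] = float((P / (1.0 + d2 / ng**2)).sum())
    ad = np.abs(ii - jj)
    f["Id"] = float((P / (1.0 + ad)).sum())
    f["Idn"] = float((P / (1.0 + ad / ng)).sum())
    off = ~np.eye(ng, dtype=bool)
    f["InverseVariance"] = float((P[off] / d2[off]).sum()) if ng > 1 else 0.0
    f["MaximumProbability"] = float(P.max())
    f["SumAverage"] = float((p_sum * k_sum).sum())
    f["SumEntropy"] = float(-(p_sum * np.log2(p_sum + _EPS)).sum())
    f["SumSquares"] = float((P * (ii - mux) ** 2).sum())
    if ng > 1:
        with np.errstate(divide="ignore", invalid="ignore"):
            A = np.where(px[:, None] > 0, P / px[:, None], 0.0)
            B = np.where(py[None, :] > 0, P / py[None, :], 0.0)
        Q = A @ B.T
        ev = np.sort(np.real(np.linalg.eigvals(Q)))[::-1]
        f["MCC"] = float(np.sqrt(max(0.0, min(1.0, ev[1]))))
    else:
        f["MCC"] = 1.0
    return f


def glcm_features(region: DiscretizedRegion, offsets=None) -> dict[str, float]:
    """24 co-occurrence features, per-direction values averaged."""
    from .registry import GLCM as _NAMES

    if region.n_voxels < 2:
        warnings.warn("GLCM on a single-voxel region: fallback 0", stacklevel=2)
        return {name: 0.0 for name in _NAMES}
    offsets = offsets if offsets is not None else unique_directions()
    acc: dict[str, list[float]] = {}
    for off in offsets:
        mat = glcm_matrix(region, off)
        total = mat.sum()
        if total == 0:
            continue  # no co-occurring pair along this direction
        for name, val in _glcm_features_from_matrix(mat / total).items():
            acc.setdefault(name, []).append(val)
    if not acc:
        warnings.warn("no co-occurring voxel pairs in any direction", stacklevel=2)
        return {name: 0.0 for name in _NAMES}
    return {name: float(np.mean(vals)) for name, vals in acc.items()}


# ---------------------------------------------------------------------------
# GLRLM


def glrlm_matrix(region: DiscretizedRegion, direction) -> np.ndarray:
    """Run-length counts r(level, run length) along one direction.

    A run is a maximal set of consecutive in-mask voxels of equal level
    along the direction; out-of-mask voxels break runs.
    """
    lv, m = region.levels, region.mask
    shape = lv.shape
    src, dst = _slices(shape, direction)
    same_next = np.zeros(shape, dtype=bool)  # p and p+d in the same run
    same_next[dst] = m[dst] & m[src] & (lv[dst] == lv[src])
    same_prev = np.zeros(shape, dtype=bool)
    same_prev[src] = same_next[dst]
    starts = m & ~same_prev

    length = np.zeros(shape, dtype=np.int64)
    length[starts] = 1
    cur = starts & same_next  # runs of length >= 2
    k = 0
    while cur.any():
        length[cur] += 1
        k += 1
        # extend further iff the link k steps ahead also continues the run
        shifted = np.zeros(shape, dtype=bool)
        s_k, d_k = _slices(shape, tuple(k * o for o in direction))
        shifted[d_k] = same_next[s_k]
        cur &= shifted
    run_levels = lv[starts]
    run_lengths = length[starts]
    mat = np.zeros((region.n_levels, int(run_lengths.max())))
    np.add.at(mat, (run_levels - 1, run_lengths - 1), 1.0)
    return mat


def _glrlm_features_from_matrix(R: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = R.sum()
    p = R / nr
    ng, lmax = R.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    l = np.arange(1, lmax + 1, dtype=float)[None, :]
    pg = p.sum(axis=1)
    pl = p.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_l = float((p * l).sum())
    f = {
        "ShortRunEmphasis": float((p / l**2).sum()),
        "LongRunEmphasis": float((p * l**2).sum()),
        "GrayLevelNonUniformity": float((R.sum(axis=1) ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum()),
        "RunLengthNonUniformity": float((R.sum(axis=0) ** 2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((pl**2).sum()),
        "RunPercentage": float(nr / n_voxels),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "RunVariance": float((p * (l - mu_l) ** 2).sum()),
        "RunEntropy": float(-(p * np.log2(p + _EPS)).sum()),
        "LowGrayLevelRunEmphasis": float((p / i**2).sum()),
        "HighGrayLevelRunEmphasis": float((p * i**2).sum()),
        "ShortRunLowGrayLevelEmphasis": float((p / (i**2 * l**2)).sum()),
        "ShortRunHighGrayLevelEmphasis": float((p * i**2 / l**2).sum()),
        "LongRunLowGrayLevelEmphasis": float((p * l**2 / i**2).sum()),
        "LongRunHighGrayLevelEmphasis": float((p * i**2 * l**2).sum()),
    }
    return f


def glrlm_features(region: DiscretizedRegion, directions=None) -> dict[str, float]:
    """16 run-length features, per-direction values averaged."""
    directions = directions if directions is not None else unique_directions()
    acc: dict[str, list[float]] = {}
    for d in directions:
        mat = glrlm_matrix(region, d)
        for name, val in _glrlm_features_from_matrix(mat, region.n_voxels).items():
            acc.setdefault(name, []).append(val)
    return {name: float(np.mean(vals)) for name, vals in acc.items()}


# ---------------------------------------------------------------------------
# GLSZM

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(region: DiscretizedRegion) -> np.ndarray:
    """Zone counts s(level, zone size); zones are 26-connected same-level
    components of the masked region."""
    lv = region.levels
    zones: list[tuple[int, int]] = []
    max_size = 1
    for level in range(1, region.n_levels + 1):
        labeled, n = ndimage.label(lv == level, structure=_STRUCT26)
        if n == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        for s in sizes:
            zones.append((level, int(s)))
            max_size = max(max_size, int(s))
    mat = np.zeros((region.n_levels, max_size))
    for level, size in zones:
        mat[level - 1, size - 1] += 1.0
    return mat


def _glszm_features_from_matrix(S: np.ndarray, n_voxels: int) -> dict[str, float]:
    nz = S.sum()
    p = S / nz
    ng, smax = S.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    s = np.arange(1, smax + 1, dtype=float)[None, :]
    pg = p.sum(axis=1)
    ps = p.sum(axis=0)
    mu_i = float((p * i).sum())
    mu_s = float((p * s).sum())
    return {
        "SmallAreaEmphasis": float((p / s**2).sum()),
        "LargeAreaEmphasis": float((p * s**2).sum()),
        "GrayLevelNonUniformity": float((S.sum(axis=1) ** 2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum()),
        "SizeZoneNonUniformity": float((S.sum(axis=0) ** 2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((ps**2).sum()),
        "ZonePercentage": float(nz / n_voxels),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "ZoneVariance": float((p * (s - mu_s) ** 2).sum()),
        "ZoneEntropy": float(-(p * np.log2(p + _EPS)).sum()),
        "LowGrayLevelZoneEmphasis": float((p / i**2).sum()),
        "HighGrayLevelZoneEmphasis": float((p * i**2).sum()),
        "SmallAreaLowGrayLevelEmphasis": float((p / (i**2 * s**2)).sum()),
        "SmallAreaHighGrayLevelEmphasis": float((p * i**2 / s**2).sum()),
        "LargeAreaLowGrayLevelEmphasis": float((p * s**2 / i**2).sum()),
        "LargeAreaHighGrayLevelEmphasis": float((p * i**2 * s**2).sum()),
    }


def glszm_features(region: DiscretizedRegion) -> dict[str, float]:
    return _glszm_features_from_matrix(glszm_matrix(region), region.n_voxels)


# ---------------------------------------------------------------------------
# GLDM


def gldm_matrix(region: DiscretizedRegion, alpha: int = 0) -> np.ndarray:
    """Dependence counts d(level, k): in-mask voxels of a given level with k
    26-neighbors whose level differs by at most ``alpha``.

    The matrix is indexed by the raw neighbor count k (column j holds
    k = j); dependence-*size* features count the center voxel as part of the
    dependence, i.e. use size = k + 1.
    """
    lv, m = region.levels, region.mask
    shape = lv.shape
    dep = np.zeros(shape, dtype=np.int64)
    for off in all_neighbor_offsets():
        src, dst = _slices(shape, off)
        ok = m[dst] & m[src] & (np.abs(lv[dst] - lv[src]) <= alpha)
        dep[dst] += ok
    kmax = int(dep[m].max())
    mat = np.zeros((region.n_levels, kmax + 1))
    np.add.at(mat, (lv[m] - 1, dep[m]), 1.0)
    return mat


def _gldm_features_from_matrix(D: np.ndarray) -> dict[str, float]:
    nz = D.sum()  # equals the voxel count: every in-mask voxel contributes
    p = D / nz
    ng, kmax1 = D.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, kmax1 + 1, dtype=float)[None, :]  # dependence size k+1
    mu_i = float((p * i).sum())
    mu_j = float((p * j).sum())
    return {
        "SmallDependenceEmphasis": float((p / j**2).sum()),
        "LargeDependenceEmphasis": float((p * j**2).sum()),
        "GrayLevelNonUniformity": float((D.sum(axis=1) ** 2).sum() / nz),
        "DependenceNonUniformity": float((D.sum(axis=0) ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float(
            (D.sum(axis=0) ** 2).sum() / nz**2
        ),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "DependenceVariance": float((p * (j - mu_j) ** 2).sum()),
        "DependenceEntropy": float(-(p * np.log2(p + _EPS)).sum()),
        "LowGrayLevelEmphasis": float((p / i**2).sum()),
        "HighGrayLevelEmphasis": float((p * i**2).sum()),
        "SmallDependenceLowGrayLevelEmphasis": float((p / (i**2 * j**2)).sum()),
        "SmallDependenceHighGrayLevelEmphasis": float((p * i**2 / j**2).sum()),
        "LargeDependenceLowGrayLevelEmphasis": float((p * j**2 / i**2).sum()),
        "LargeDependenceHighGrayLevelEmphasis": float((p * i**2 * j**2).sum()),
    }


def gldm_features(region: DiscretizedRegion, alpha: int = 0) -> dict[str, float]:
    return _gldm_features_from_matrix(gldm_matrix(region, alpha))


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_table(region: DiscretizedRegion):
    """Per-level occupancy n_i, probability p_i and summed absolute
    difference s_i from the 26-neighborhood mean. Voxels with no in-mask
    neighbor are excluded."""
    lv, m = region.levels, region.mask
    shape = lv.shape
    nbr_sum = np.zeros(shape)
    nbr_cnt = np.zeros(shape, dtype=np.int64)
    for off in all_neighbor_offsets():
        src, dst = _slices(shape, off)
        ok = m[dst] & m[src]
        nbr_sum[dst] += np.where(ok, lv[src], 0)
        nbr_cnt[dst] += ok
    valid = m & (nbr_cnt > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        abar = np.where(valid, nbr_sum / np.maximum(nbr_cnt, 1), 0.0)
    ng = region.n_levels
    n = np.zeros(ng)
    s = np.zeros(ng)
    levels = lv[valid]
    diffs = np.abs(levels - abar[valid])
    np.add.at(n, levels - 1, 1.0)
    np.add.at(s, levels - 1, diffs)
    total = n.sum()
    p = n / total if total > 0 else n
    return n, p, s


def ngtdm_features(region: DiscretizedRegion) -> dict[str, float]:
    n, p, s = ngtdm_table(region)
    N = n.sum()
    i = np.arange(1, p.size + 1, dtype=float)
    present = p > 0
    ngp = int(present.sum())
    f: dict[str, float] = {}
    denom = float((p * s).sum())
    f["Coarseness"] = 1.0 / denom if denom > 0 else 1e6  # documented cap
    if ngp > 1 and N > 0:
        ipr = i[present]
        ppr = p[present]
        spr = s[present]
        dif2 = (ipr[:, None] - ipr[None, :]) ** 2
        f["Contrast"] = float(
            (ppr[:, None] * ppr[None, :] * dif2).sum()
            / (ngp * (ngp - 1))
            * s.sum()
            / N
        )
        busy_den = float(
            np.abs(ipr[:, None] * ppr[:, None] - ipr[None, :] * ppr[None, :]).sum()
        )
        f["Busyness"] = denom / busy_den if busy_den > 0 else 0.0
        pis = ppr[:, None] * spr[:, None] + ppr[None, :] * spr[None, :]
        psum = ppr[:, None] + ppr[None, :]
        f["Complexity"] = float(
            (np.abs(ipr[:, None] - ipr[None, :]) * pis / psum).sum() / N
        )
        stot = float(s.sum())
        f["Strength"] = (
            float((psum * dif2).sum()) / stot if stot > 0 else 0.0
        )
    else:
        f["Contrast"] = 0.0
        f["Busyness"] = 0.0
        f["Complexity"] = 0.0
        f["Strength"] = 0.0
    return f
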