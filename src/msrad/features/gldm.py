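"""Gray-level dependence matrix (GLDM) features — 14 features.

A 26-neighbor is dependent on the center voxel when their gray levels differ
by at most the similarity tolerance alpha (0 here, i.e. exact equality).  The
dependence size of an in-ROI voxel is 1 (itself) plus its number of dependent
in-ROI neighbors at Chebyshev distance 1; the matrix counts voxels by
(gray level, dependence size), so its total equals the ROI voxel count.
"""

from __future__ import annotations

import numpy as np

GLDM_NAMES = (
    "DependenceEntropy",
    "DependenceNonUniformity",
    "DependenceNonUniformityNormalized",
    "DependenceVariance",
    "GrayLevelNonUniformity",
    "GrayLevelVariance",
    "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis",
    "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

_OFFSETS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


def gldm_matrix(levels: np.ndarray, n_levels: int, alpha: int = 0) -> np.ndarray:
    """Dependence count matrix P[level-1, dependence-1]."""
    roi = levels > 0
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in _OFFSETS_26:
        a, b = _aligned_views(levels, off)
        both = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
        target = _aligned_views(dep, off)[0]
        target += both
    dep = dep + 1  # the center voxel itself

    lev = levels[roi]
    dsz = dep[roi]
    max_dep = int(dsz.max())
    P = np.zeros((n_levels, max_dep))
    np.add.at(P, (lev - 1, dsz - 1), 1.0)
    return P


def _aligned_views(arr: np.ndarray, offset):
    sl_a, sl_b = [], []
    for d, size in zip(offset, arr.shape):
        if d == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif d > 0:
            sl_a.append(slice(0, size - d))
            sl_b.append(slice(d, size))
        else:
            sl_a.append(slice(-d, size))
            sl_b.append(slice(0, size + d))
    return arr[tuple(sl_a)], arr[tuple(sl_b)]


def _features(P: np.ndarray) -> dict[str, float]:
    nd = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=np.float64)[:, None]
    j = np.arange(1, P.shape[1] + 1, dtype=np.float64)[None, :]
    p = P / nd
    mu_i = (p * i).sum()
    mu_j = (p * j).sum()
    pg = P.sum(axis=1)
    pd = P.sum(axis=0)
    pnz = p[p > 0]
    return {
        "DependenceEntropy": float(-(pnz * np.log2(pnz)).sum()),
        "DependenceNonUniformity": float((pd**2).sum() / nd),
        "DependenceNonUniformityNormalized": float((pd**2).sum() / nd**2),
        "DependenceVariance": float((p * (j - mu_j) ** 2).sum()),
        "GrayLevelNonUniformity": float((pg**2).sum() / nd),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "HighGrayLevelEmphasis": float((P * i**2).sum() / nd),
        "LargeDependenceEmphasis": float((P * j**2).sum() / nd),
        "LargeDependenceHighGrayLevelEmphasis": float((P * i**2 * j**2).sum() / nd),
        "LargeDependenceLowGrayLevelEmphasis": float((P * j**2 / i**2).sum() / nd),
        "LowGrayLevelEmphasis": float((P / i**2).sum() / nd),
        "SmallDependenceEmphasis": float((P / j**2).sum() / nd),
        "SmallDependenceHighGrayLevelEmphasis": float((P * i**2 / j**2).sum() / nd),
        "SmallDependenceLowGrayLevelEmphasis": float((P / (i**2 * j**2)).sum() / nd),
    }


def gldm_features(d, alpha: int = 0) -> dict[str, float]:
    if d.n_voxels == 0:
        raise ValueError("empty ROI")
    ng = int(d.roi_levels.max())
    P = gldm_matrix(d.levels, ng, alpha=alpha)
    return _features(P)
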