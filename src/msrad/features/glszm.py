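"""Gray-level size-zone matrix (GLSZM) features — 16 features.

A zone is a 26-connected component of in-ROI voxels sharing one gray level;
the matrix counts zones by (gray level, zone size) and is direction-free.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

GLSZM_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelZoneEmphasis",
    "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis",
    "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis",
    "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized",
    "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis",
    "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy",
    "ZonePercentage",
    "ZoneVariance",
)

_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(levels: np.ndarray, n_levels: int) -> np.ndarray:
    """Zone count matrix P[level-1, size-1] using 26-connectivity."""
    zones: list[tuple[int, int]] = []
    for g in range(1, n_levels + 1):
        binary = levels == g
        if not binary.any():
            continue
        labeled, n_comp = ndimage.label(binary, structure=_STRUCTURE_26)
        sizes = np.bincount(labeled.ravel())[1:]
        zones.extend((g, int(s)) for s in sizes)
    max_size = max(s for _, s in zones)
    P = np.zeros((n_levels, max_size))
    for g, s in zones:
        P[g - 1, s - 1] += 1.0
    return P


def _features(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    nz = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=np.float64)[:, None]
    s = np.arange(1, P.shape[1] + 1, dtype=np.float64)[None, :]
    p = P / nz
    mu_i = (p * i).sum()
    mu_s = (p * s).sum()
    pg = P.sum(axis=1)
    ps = P.sum(axis=0)
    pnz = p[p > 0]
    return {
        "GrayLevelNonUniformity": float((pg**2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / nz**2),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "HighGrayLevelZoneEmphasis": float((P * i**2).sum() / nz),
        "LargeAreaEmphasis": float((P * s**2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((P * i**2 * s**2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((P * s**2 / i**2).sum() / nz),
        "LowGrayLevelZoneEmphasis": float((P / i**2).sum() / nz),
        "SizeZoneNonUniformity": float((ps**2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((ps**2).sum() / nz**2),
        "SmallAreaEmphasis": float((P / s**2).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((P * i**2 / s**2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((P / (i**2 * s**2)).sum() / nz),
        "ZoneEntropy": float(-(pnz * np.log2(pnz)).sum()),
        "ZonePercentage": float(nz / n_voxels),
        "ZoneVariance": float((p * (s - mu_s) ** 2).sum()),
    }


def glszm_features(d) -> dict[str, float]:
    if d.n_voxels == 0:
        raise ValueError("empty ROI")
    ng = int(d.roi_levels.max())
    P = glszm_matrix(d.levels, ng)
    return _features(P, d.n_voxels)
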