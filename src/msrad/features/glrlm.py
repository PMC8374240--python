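"""Gray-level run-length matrix (GLRLM) features — 16 features.

A run is a maximal set of consecutive in-ROI voxels with the same gray level
along a direction; out-of-ROI voxels break runs.  Matrices are built for the
13 unique 3D directions and the features averaged over directions.
"""

from __future__ import annotations

import numpy as np

from .discretize import DIRECTIONS_13, DiscretizedROI

GLRLM_NAMES = (
    "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance",
    "HighGrayLevelRunEmphasis",
    "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis",
    "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis",
    "RunEntropy",
    "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized",
    "RunPercentage",
    "RunVariance",
    "ShortRunEmphasis",
    "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)


def glrlm_matrix(levels: np.ndarray, n_levels: int, direction) -> np.ndarray:
    """Run-length count matrix P[level-1, length-1] for one direction."""
    d = np.asarray(direction)
    shape = np.asarray(levels.shape)
    pos = np.argwhere(levels > 0)
    if pos.size == 0:
        return np.zeros((n_levels, 1))
    lev = levels[tuple(pos.T)]

    prev = pos - d
    inside = ((prev >= 0) & (prev < shape)).all(axis=1)
    prev_lev = np.zeros(len(pos), dtype=levels.dtype)
    prev_lev[inside] = levels[tuple(prev[inside].T)]
    start = prev_lev != lev  # run starts where the predecessor differs

    cur = pos[start]
    run_lev = lev[start]
    length = np.ones(len(cur), dtype=np.int64)
    active = np.ones(len(cur), dtype=bool)
    while active.any():
        nxt = cur[active] + d
        ok = ((nxt >= 0) & (nxt < shape)).all(axis=1)
        cont = np.zeros(ok.shape, dtype=bool)
        if ok.any():
            cont[ok] = levels[tuple(nxt[ok].T)] == run_lev[active][ok]
        idx = np.flatnonzero(active)
        length[idx[cont]] += 1
        cur[idx[cont]] = nxt[cont]
        active[idx[~cont]] = False

    max_len = int(length.max())
    P = np.zeros((n_levels, max_len))
    np.add.at(P, (run_lev - 1, length - 1), 1.0)
    return P


def _features_one(P: np.ndarray, n_voxels: int) -> dict[str, float]:
    nr = P.sum()
    i = np.arange(1, P.shape[0] + 1, dtype=np.float64)[:, None]
    l = np.arange(1, P.shape[1] + 1, dtype=np.float64)[None, :]
    p = P / nr
    mu_i = (p * i).sum()
    mu_l = (p * l).sum()
    pg = P.sum(axis=1)  # per gray level
    pl = P.sum(axis=0)  # per run length
    pnz = p[p > 0]
    return {
        "GrayLevelNonUniformity": float((pg**2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((pg**2).sum() / nr**2),
        "GrayLevelVariance": float((p * (i - mu_i) ** 2).sum()),
        "HighGrayLevelRunEmphasis": float((P * i**2).sum() / nr),
        "LongRunEmphasis": float((P * l**2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((P * i**2 * l**2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((P * l**2 / i**2).sum() / nr),
        "LowGrayLevelRunEmphasis": float((P / i**2).sum() / nr),
        "RunEntropy": float(-(pnz * np.log2(pnz)).sum()),
        "RunLengthNonUniformity": float((pl**2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((pl**2).sum() / nr**2),
        "RunPercentage": float(nr / n_voxels),
        "RunVariance": float((p * (l - mu_l) ** 2).sum()),
        "ShortRunEmphasis": float((P / l**2).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((P * i**2 / l**2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((P / (i**2 * l**2)).sum() / nr),
    }


def glrlm_features(d: DiscretizedROI) -> dict[str, float]:
    if d.n_voxels == 0:
        raise ValueError("empty ROI")
    ng = int(d.roi_levels.max())
    per_dir = []
    for direction in DIRECTIONS_13:
        P = glrlm_matrix(d.levels, ng, direction)
        per_dir.append(_features_one(P, d.n_voxels))
    return {name: float(np.mean([f[name] for f in per_dir])) for name in GLRLM_NAMES}
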