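"""Gray-level co-occurrence matrix (GLCM) features — 24 features.

Symmetric co-occurrence matrices at Chebyshev distance 1 are built for the 13
unique 3D direction offsets; each is normalized to sum 1 and the 24 features
are computed per direction and then averaged over directions.  Only voxel
pairs with both members inside the ROI contribute.

Degenerate conventions: with a single occupied gray level the correlation
feature is 1 and MCC is 1; Imc1 is 0 when both marginal entropies vanish.
"""

from __future__ import annotations

import numpy as np

from .discretize import DIRECTIONS_13, DiscretizedROI

GLCM_NAMES = (
    "Autocorrelation",
    "ClusterProminence",
    "ClusterShade",
    "ClusterTendency",
    "Contrast",
    "Correlation",
    "DifferenceAverage",
    "DifferenceEntropy",
    "DifferenceVariance",
    "Id",
    "Idm",
    "Idmn",
    "Idn",
    "Imc1",
    "Imc2",
    "InverseVariance",
    "JointAverage",
    "JointEnergy",
    "JointEntropy",
    "MCC",
    "MaximumProbability",
    "SumAverage",
    "SumEntropy",
    "SumSquares",
)

_EPS = np.finfo(np.float64).eps


def glcm_matrices(levels: np.ndarray, n_levels: int) -> list[np.ndarray]:
    """One symmetric (unnormalized) co-occurrence count matrix per direction.

    ``levels`` uses 0 for out-of-ROI voxels; matrices are indexed by
    ``level - 1``.
    """
    mats = []
    for dz, dy, dx in DIRECTIONS_13:
        a, b = _shift_pairs(levels, (dz, dy, dx))
        valid = (a > 0) & (b > 0)
        a, b = a[valid] - 1, b[valid] - 1
        counts = np.bincount(a * n_levels + b, minlength=n_levels * n_levels)
        mat = counts.reshape(n_levels, n_levels).astype(np.float64)
        mats.append(mat + mat.T)
    return mats


def _shift_pairs(levels: np.ndarray, offset: tuple[int, int, int]):
    """Aligned (source, neighbor) level arrays for an offset."""
    sl_a, sl_b = [], []
    for d, size in zip(offset, levels.shape):
        if d == 0:
            sl_a.append(slice(None))
            sl_b.append(slice(None))
        elif d > 0:
            sl_a.append(slice(0, size - d))
            sl_b.append(slice(d, size))
        else:
            sl_a.append(slice(-d, size))
            sl_b.append(slice(0, size + d))
    return levels[tuple(sl_a)], levels[tuple(sl_b)]


def _features_one(P: np.ndarray) -> dict[str, float]:
    ng = P.shape[0]
    total = P.sum()
    p = P / total
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")

    px = p.sum(axis=1)  # symmetric: px == py
    mu = float((px * i).sum())
    sigma2 = float((px * (i - mu) ** 2).sum())

    # diagonal / cross-diagonal distributions
    k_diff = np.arange(ng, dtype=np.float64)  # |i-j| = 0..ng-1
    p_diff = np.zeros(ng)
    k_sum = np.arange(2, 2 * ng + 1, dtype=np.float64)
    p_sum = np.zeros(2 * ng - 1)
    for d in range(ng):
        p_diff[d] = np.trace(p, offset=d) + (np.trace(p, offset=-d) if d else 0.0)
    for s in range(2, 2 * ng + 1):
        p_sum[s - 2] = p[ii + jj == s].sum()

    da = float((p_diff * k_diff).sum())
    joint_entropy = float(-(p[p > 0] * np.log2(p[p > 0])).sum())

    hx = float(-(px[px > 0] * np.log2(px[px > 0])).sum())
    pxy = np.outer(px, px)
    nz = p > 0
    hxy1 = float(-(p[nz] * np.log2(pxy[nz] + _EPS)).sum())
    nz2 = pxy > 0
    hxy2 = float(-(pxy[nz2] * np.log2(pxy[nz2])).sum())
    imc1 = (joint_entropy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - joint_entropy)))))

    if sigma2 > 0:
        correlation = float(((p * ii * jj).sum() - mu * mu) / sigma2)
    else:
        correlation = 1.0

    off = ii != jj
    inv_var = float((p[off] / (ii - jj)[off] ** 2).sum())

    return {
        "Autocorrelation": float((p * ii * jj).sum()),
        "ClusterProminence": float((p * (ii + jj - 2 * mu) ** 4).sum()),
        "ClusterShade": float((p * (ii + jj - 2 * mu) ** 3).sum()),
        "ClusterTendency": float((p * (ii + jj - 2 * mu) ** 2).sum()),
        "Contrast": float((p * (ii - jj) ** 2).sum()),
        "Correlation": correlation,
        "DifferenceAverage": da,
        "DifferenceEntropy": float(
            -(p_diff[p_diff > 0] * np.log2(p_diff[p_diff > 0])).sum()
        ),
        "DifferenceVariance": float((p_diff * (k_diff - da) ** 2).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + (ii - jj) ** 2 / ng**2)).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "Imc1": imc1,
        "Imc2": imc2,
        "InverseVariance": inv_var,
        "JointAverage": mu,
        "JointEnergy": float((p**2).sum()),
        "JointEntropy": joint_entropy,
        "MCC": _mcc(p, px),
        "MaximumProbability": float(p.max()),
        "SumAverage": float((p_sum * k_sum).sum()),
        "SumEntropy": float(-(p_sum[p_sum > 0] * np.log2(p_sum[p_sum > 0])).sum()),
        "SumSquares": sigma2,
    }


def _mcc(p: np.ndarray, px: np.ndarray) -> float:
    """Maximal correlation coefficient: sqrt of the second-largest eigenvalue
    of Q(i,j) = sum_k p(i,k) p(j,k) / (px(i) px(k)), over occupied levels."""
    keep = px > 0
    if keep.sum() < 2:
        return 1.0
    ps = p[np.ix_(keep, keep)]
    pxs = px[keep]
    Q = (ps / pxs[:, None]) @ (ps / pxs[None, :]).T
    eig = np.linalg.eigvals(Q).real
    eig.sort()
    return float(np.sqrt(max(0.0, eig[-2])))


def glcm_features(d: DiscretizedROI) -> dict[str, float]:
    if d.n_voxels < 2:
        raise ValueError("GLCM requires at least 2 in-ROI voxels")
    ng = int(d.roi_levels.max())
    mats = glcm_matrices(d.levels, ng)
    per_dir = [_features_one(P) for P in mats if P.sum() > 0]
    if not per_dir:  # isolated voxels in every direction
        return {name: 0.0 for name in GLCM_NAMES}
    return {name: float(np.mean([f[name] for f in per_dir])) for name in GLCM_NAMES}
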