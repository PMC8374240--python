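"""Neighboring gray-tone difference matrix (NGTDM) features — 5 features.

For every in-ROI voxel with at least one in-ROI 26-neighbor, the absolute
difference between its gray level and the mean level of those neighbors is
accumulated per gray level (``s_i``), alongside occupancy counts (``n_i``).

Degenerate conventions: coarseness with a vanishing denominator is capped at
1e6 (the conventional cap for a perfectly uniform region); contrast with one
occupied level is 0; busyness and strength with vanishing denominators are 0.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

NGTDM_NAMES = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")

_COARSENESS_CAP = 1e6

_KERNEL = np.ones((3, 3, 3))
_KERNEL[1, 1, 1] = 0.0


def ngtdm_table(levels: np.ndarray, n_levels: int):
    """Return (n_i, p_i, s_i) arrays indexed by gray level - 1."""
    roi = levels > 0
    neigh_sum = ndimage.convolve(
        (levels * roi).astype(np.float64), _KERNEL, mode="constant"
    )
    neigh_cnt = ndimage.convolve(roi.astype(np.float64), _KERNEL, mode="constant")
    valid = roi & (neigh_cnt > 0.5)
    abar = np.zeros_like(neigh_sum)
    abar[valid] = neigh_sum[valid] / neigh_cnt[valid]

    lev = levels[valid]
    diff = np.abs(lev - abar[valid])
    n_i = np.bincount(lev - 1, minlength=n_levels).astype(np.float64)
    s_i = np.bincount(lev - 1, weights=diff, minlength=n_levels)
    nvp = n_i.sum()
    p_i = n_i / nvp if nvp > 0 else n_i
    return n_i, p_i, s_i


def ngtdm_features(d) -> dict[str, float]:
    if d.n_voxels == 0:
        raise ValueError("empty ROI")
    ng = int(d.roi_levels.max())
    n_i, p_i, s_i = ngtdm_table(d.levels, ng)
    nvp = n_i.sum()
    i = np.arange(1, ng + 1, dtype=np.float64)
    occ = p_i > 0
    ngp = int(occ.sum())

    ps = float((p_i * s_i).sum())
    coarseness = 1.0 / ps if ps > 0 else _COARSENESS_CAP
    coarseness = min(coarseness, _COARSENESS_CAP)

    io, po, so = i[occ], p_i[occ], s_i[occ]
    dif = io[:, None] - io[None, :]

    if ngp > 1:
        contrast = float(
            (po[:, None] * po[None, :] * dif**2).sum()
            / (ngp * (ngp - 1))
            * (s_i.sum() / nvp)
        )
        busy_den = float(np.abs(io * po - (io * po)[:, None]).sum())
        busyness = ps / busy_den if busy_den > 0 else 0.0
        complexity = float(
            (
                np.abs(dif)
                * (po[:, None] * so[:, None] + po[None, :] * so[None, :])
                / (po[:, None] + po[None, :])
            ).sum()
            / nvp
        )
        s_sum = float(s_i.sum())
        strength = (
            float(((po[:, None] + po[None, :]) * dif**2).sum()) / s_sum
            if s_sum > 0
            else 0.0
        )
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "Busyness": busyness,
        "Coarseness": coarseness,
        "Complexity": complexity,
        "Contrast": contrast,
        "Strength": strength,
    }
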