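"""Feature saliency (distribution) maps.

For every ROI voxel, the selected feature is evaluated on the voxel's
3x3x3 (26-connected) neighborhood intersected with the ROI, using the global
ROI bin edges for discretization so neighboring values stay comparable; the
resulting raw map is min-max normalized over the ROI.  Border voxels use the
truncated neighborhood; voxels whose patch holds fewer than 2 ROI voxels get
value 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Volume
from .features.discretize import DEFAULT_N_BINS, DiscretizedROI, discretize_fbn
from .features.registry import FEATURE_NAMES, compute_feature


@dataclass
class SaliencyMap:
    data: np.ndarray  # in [0,1] inside ROI, 0 outside
    raw: np.ndarray  # un-normalized feature values on the same grid
    feature_name: str
    channel: str
    roi_mask: np.ndarray


def _patch_roi(d: DiscretizedROI, z: int, y: int, x: int) -> DiscretizedROI | None:
    sl = tuple(
        slice(max(c - 1, 0), min(c + 2, n))
        for c, n in zip((z, y, x), d.levels.shape)
    )
    mask = d.roi_mask[sl]
    if mask.sum() < 2:
        return None
    return DiscretizedROI(
        levels=np.where(mask, d.levels[sl], 0),
        roi_mask=mask,
        raw=d.raw[sl],
        n_bins=d.n_bins,
        bin_edges=d.bin_edges,
        bounding_box=(0, 0, 0, 0, 0, 0),
        voxel_size_mm=d.voxel_size_mm,
    )


def saliency_map(
    v: Volume,
    roi: np.ndarray,
    feature_name: str,
    n_bins: int = DEFAULT_N_BINS,
) -> SaliencyMap:
    """Voxelwise saliency of one of the 93 registry features over an ROI."""
    if feature_name not in FEATURE_NAMES:
        raise KeyError(f"unknown feature {feature_name!r}")
    d = discretize_fbn(v, roi, n_bins=n_bins, padding=1)
    raw_map = np.zeros(d.levels.shape)
    for z, y, x in np.argwhere(d.roi_mask):
        patch = _patch_roi(d, z, y, x)
        if patch is None:
            continue
        raw_map[z, y, x] = compute_feature(patch, feature_name)

    # min-max normalize over the ROI; constant maps collapse to all-zero
    vals = raw_map[d.roi_mask]
    lo, hi = vals.min(), vals.max()
    norm = np.zeros_like(raw_map)
    if hi > lo:
        norm[d.roi_mask] = (vals - lo) / (hi - lo)

    # paste back into the full grid
    z0, z1, y0, y1, x0, x1 = d.bounding_box
    full = np.zeros(v.data.shape)
    full[z0:z1, y0:y1, x0:x1] = norm
    full_raw = np.zeros(v.data.shape)
    full_raw[z0:z1, y0:y1, x0:x1] = raw_map
    return SaliencyMap(
        data=full, raw=full_raw, feature_name=feature_name, channel=v.channel,
        roi_mask=np.asarray(roi, dtype=bool),
    )
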