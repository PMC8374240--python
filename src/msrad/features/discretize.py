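"""Fixed-bin-number (FBN) intensity discretization and ROI cropping.

Texture matrices are computed on gray levels, not raw intensities.  Levels are
obtained by splitting the ROI intensity range into ``n_bins`` equal-width bins
(default 50, the IBSI-recommended fixed-bin-number setting), which makes the
texture features invariant to any monotone affine rescaling of the channel —
the property that lets arbitrary-unit and quantitative channels share one
extraction pipeline.  Before any matrix is built the ROI is cropped to its
bounding box with a 5-voxel pad (clipped at the image border).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core import Volume

DEFAULT_N_BINS = 50
DEFAULT_PADDING = 5

#: the 13 unique direction offsets of the 26-neighborhood (one per antipodal pair)
DIRECTIONS_13 = tuple(
    (dz, dy, dx)
    for dz in (0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)
assert len(DIRECTIONS_13) == 13


@dataclass
class DiscretizedROI:
    """A cropped ROI with integer gray levels.

    ``levels`` holds values in ``1..n_bins`` inside the ROI and 0 outside;
    ``raw`` is the matching crop of the original intensities.  ``bounding_box``
    records ``(z0, z1, y0, y1, x0, x1)`` half-open crop limits in the original
    grid, after padding.
    """

    levels: np.ndarray
    roi_mask: np.ndarray
    raw: np.ndarray
    n_bins: int
    bin_edges: np.ndarray
    bounding_box: tuple[int, int, int, int, int, int]
    voxel_size_mm: tuple[float, float, float]

    @property
    def n_voxels(self) -> int:
        return int(self.roi_mask.sum())

    @property
    def roi_values(self) -> np.ndarray:
        """Raw intensities of the in-ROI voxels (1D)."""
        return self.raw[self.roi_mask]

    @property
    def roi_levels(self) -> np.ndarray:
        """Gray levels of the in-ROI voxels (1D)."""
        return self.levels[self.roi_mask]


def bounding_box(mask: np.ndarray, padding: int = DEFAULT_PADDING) -> tuple[int, ...]:
    """Half-open bounding box of a mask, padded and clipped at the border."""
    if not mask.any():
        raise ValueError("empty ROI: bounding box undefined")
    bbox = []
    for axis in range(3):
        proj = mask.any(axis=tuple(a for a in range(3) if a != axis))
        idx = np.flatnonzero(proj)
        lo = max(int(idx[0]) - padding, 0)
        hi = min(int(idx[-1]) + 1 + padding, mask.shape[axis])
        bbox += [lo, hi]
    return tuple(bbox)


def discretize_fbn(
    v: Volume,
    roi: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    padding: int = DEFAULT_PADDING,
) -> DiscretizedROI:
    """Discretize a volume inside an ROI with a fixed number of bins.

    The level of an in-ROI voxel with intensity ``x`` is
    ``min(n_bins, floor(n_bins * (x - min) / (max - min)) + 1)``; a constant
    ROI maps every voxel to level 1.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != v.data.shape:
        raise ValueError("ROI and volume shapes differ")
    if not roi.any():
        raise ValueError("empty ROI")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")

    z0, z1, y0, y1, x0, x1 = bounding_box(roi, padding)
    raw = v.data[z0:z1, y0:y1, x0:x1].copy()
    mask = roi[z0:z1, y0:y1, x0:x1].copy()

    vals = raw[mask]
    lo, hi = float(vals.min()), float(vals.max())
    levels = np.zeros(raw.shape, dtype=np.int32)
    if hi > lo:
        lev = np.floor(n_bins * (raw[mask] - lo) / (hi - lo)).astype(np.int32) + 1
        np.minimum(lev, n_bins, out=lev)
        levels[mask] = lev
        edges = np.linspace(lo, hi, n_bins + 1)
    else:
        levels[mask] = 1
        edges = np.linspace(lo, lo + 1.0, n_bins + 1)  # degenerate range

    return DiscretizedROI(
        levels=levels,
        roi_mask=mask,
        raw=raw,
        n_bins=n_bins,
        bin_edges=edges,
        bounding_box=(z0, z1, y0, y1, x0, x1),
        voxel_size_mm=v.voxel_size_mm,
    )
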