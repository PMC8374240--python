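"""Shared in-memory containers for volumes and tissue masks.

Conventions used throughout the package:

* a volume is a 3D scalar grid with an isotropic-or-not voxel size in mm and a
  channel label (``T1w`` conventional MRI, or the quantitative maps ``PD``,
  ``MT``, ``R1``, ``R2*``);
* tissue masks are boolean grids; the white-matter mask is the voxelwise union
  of normal-appearing white matter (NAWM) and focal lesions, and the total
  intracranial volume (TIV) is the union of CSF, GM, NAWM and lesion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: channel labels accepted on a Volume
CHANNELS = ("T1w", "PD", "MT", "R1", "R2*", "FLAIR")

#: the three regions features are extracted from (lesion-only ROIs are not)
ROIS = ("WM", "NAWM", "GM")


@dataclass
class Volume:
    """One subject's 3D scalar grid for a single image channel."""

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    channel: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("Volume data must be 3D")
        self.voxel_size_mm = tuple(float(s) for s in self.voxel_size_mm)
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError("voxel sizes must be positive")
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


@dataclass
class TissueMasks:
    """Binary tissue masks plus the derived WM and TIV composites.

    ``wm = nawm | lesion`` voxelwise; ``tiv = csf | gm | nawm | lesion``.
    The four base masks are pairwise disjoint.
    """

    csf: np.ndarray
    gm: np.ndarray
    nawm: np.ndarray
    lesion: np.ndarray
    wm: np.ndarray = field(init=False)
    tiv: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        for name in ("csf", "gm", "nawm", "lesion"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=bool))
        shapes = {getattr(self, n).shape for n in ("csf", "gm", "nawm", "lesion")}
        if len(shapes) != 1:
            raise ValueError("tissue masks must share one grid shape")
        overlap = (
            self.csf.astype(np.uint8)
            + self.gm.astype(np.uint8)
            + self.nawm.astype(np.uint8)
            + self.lesion.astype(np.uint8)
        )
        if (overlap > 1).any():
            raise ValueError("base tissue masks must be pairwise disjoint")
        self.wm = self.nawm | self.lesion
        self.tiv = self.csf | self.gm | self.nawm | self.lesion

    def roi(self, name: str) -> np.ndarray:
        """Return the mask for an extraction ROI (``WM``, ``NAWM`` or ``GM``)."""
        key = name.lower()
        if key not in ("wm", "nawm", "gm", "csf", "lesion", "tiv"):
            raise KeyError(f"unknown ROI {name!r}")
        return getattr(self, key)
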