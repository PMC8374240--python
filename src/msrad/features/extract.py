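"""Cohort-level feature extraction into a wide feature table.

The feature table is the central exchange object of the pipeline: one row per
subject, with outcome/covariate columns (``status``, ``age``, ``gender``,
``scanner``), one ROI-volume column per ROI (mm^3) and one column per
(channel, ROI, feature) named ``<channel>__<roi>__<family>_<feature>``.
Five channels x three ROIs x 93 features gives the full 1,395-column table.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from ..core import ROIS, TissueMasks, Volume
from .discretize import DEFAULT_N_BINS, DEFAULT_PADDING
from .registry import FEATURE_NAMES, extract_roi

COVARIATE_COLUMNS = ("status", "age", "gender", "scanner")


def feature_column(channel: str, roi: str, feature: str) -> str:
    return f"{channel}__{roi}__{feature}"


def parse_feature_column(column: str) -> tuple[str, str, str]:
    channel, roi, feature = column.split("__")
    return channel, roi, feature


def volume_column(roi: str) -> str:
    return f"roi_volume__{roi}"


def feature_columns_of(table: pd.DataFrame) -> list[str]:
    """The radiomic feature columns of a table (excludes covariates/volumes)."""
    return [c for c in table.columns if c.count("__") == 2 and not c.startswith("roi_volume")]


def extract_subject(
    volumes: dict[str, Volume],
    masks: TissueMasks,
    channels: Sequence[str],
    rois: Sequence[str] = ROIS,
    n_bins: int = DEFAULT_N_BINS,
    padding: int = DEFAULT_PADDING,
) -> dict[str, float]:
    """93 x |channels| x |rois| features for one subject, plus ROI volumes."""
    row: dict[str, float] = {}
    for roi in rois:
        mask = masks.roi(roi)
        if not mask.any():
            raise ValueError(f"empty {roi} mask")
        any_channel = volumes[channels[0]]
        row[volume_column(roi)] = float(mask.sum()) * any_channel.voxel_volume_mm3
    for channel in channels:
        v = volumes[channel]
        for roi in rois:
            values = extract_roi(v, masks.roi(roi), n_bins=n_bins, padding=padding)
            for feature in FEATURE_NAMES:
                row[feature_column(channel, roi, feature)] = values[feature]
    return row


def extract_all(
    subjects: Iterable,
    channels: Sequence[str],
    rois: Sequence[str] = ROIS,
    n_bins: int = DEFAULT_N_BINS,
    padding: int = DEFAULT_PADDING,
) -> pd.DataFrame:
    """Extract the wide feature table for a preprocessed cohort.

    Each subject must expose ``id``, ``status``, ``age``, ``gender``,
    ``scanner``, ``volumes`` (channel -> Volume) and ``masks`` (TissueMasks).
    Any non-finite feature raises, naming the offending cell.
    """
    rows = []
    index = []
    for s in subjects:
        if s.masks is None:
            raise ValueError(f"subject {s.id}: masks missing (run preprocessing first)")
        row: dict[str, object] = {
            "status": int(s.status),
            "age": float(s.age),
            "gender": s.gender,
            "scanner": s.scanner,
        }
        row.update(
            extract_subject(
                s.volumes, s.masks, channels, rois, n_bins=n_bins, padding=padding
            )
        )
        for key, val in row.items():
            if isinstance(val, float) and not np.isfinite(val):
                raise ValueError(f"non-finite feature for subject {s.id}: {key}")
        rows.append(row)
        index.append(s.id)
    table = pd.DataFrame(rows, index=pd.Index(index, name="subject_id"))
    return table
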