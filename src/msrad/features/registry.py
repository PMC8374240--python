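"""The normative 93-feature registry and single-ROI extraction entry points.

The registry fixes the family cardinalities at FO=18, GLCM=24, GLRLM=16,
GLSZM=16, NGTDM=5, GLDM=14 (93 in total) — the original-image default set of
the widely used radiomics extraction tooling that this package's analysis is
designed around.  Names follow the ``<family>_<FeatureName>`` convention,
e.g. ``firstorder_Minimum`` or ``gldm_LargeDependenceHighGrayLevelEmphasis``.
"""

from __future__ import annotations

import numpy as np

from ..core import Volume
from .discretize import DEFAULT_N_BINS, DEFAULT_PADDING, DiscretizedROI, discretize_fbn
from .firstorder import FIRSTORDER_NAMES, first_order
from .glcm import GLCM_NAMES, glcm_features
from .gldm import GLDM_NAMES, gldm_features
from .glrlm import GLRLM_NAMES, glrlm_features
from .glszm import GLSZM_NAMES, glszm_features
from .ngtdm import NGTDM_NAMES, ngtdm_features

FAMILIES: dict[str, tuple[str, ...]] = {
    "firstorder": FIRSTORDER_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "glszm": GLSZM_NAMES,
    "ngtdm": NGTDM_NAMES,
    "gldm": GLDM_NAMES,
}

#: all 93 feature names, grouped by family in a fixed order
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{family}_{name}" for family, names in FAMILIES.items() for name in names
)
assert len(FEATURE_NAMES) == 93

_FAMILY_FN = {
    "firstorder": first_order,
    "glcm": glcm_features,
    "glrlm": glrlm_features,
    "glszm": glszm_features,
    "ngtdm": ngtdm_features,
    "gldm": gldm_features,
}


def compute_all(d: DiscretizedROI) -> dict[str, float]:
    """All 93 features of a discretized ROI, keyed ``<family>_<name>``."""
    out: dict[str, float] = {}
    for family, names in FAMILIES.items():
        values = _FAMILY_FN[family](d)
        for name in names:
            out[f"{family}_{name}"] = values[name]
    return out


def compute_feature(d: DiscretizedROI, feature_name: str) -> float:
    """A single named feature (computes only its family)."""
    family, _, name = feature_name.partition("_")
    if family not in FAMILIES or name not in FAMILIES[family]:
        raise KeyError(f"unknown feature {feature_name!r}")
    return _FAMILY_FN[family](d)[name]


def extract_roi(
    v: Volume,
    roi: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    padding: int = DEFAULT_PADDING,
) -> dict[str, float]:
    """Discretize an ROI and compute the full 93-feature vector."""
    d = discretize_fbn(v, roi, n_bins=n_bins, padding=padding)
    return compute_all(d)
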