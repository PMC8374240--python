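"""First-order (intensity histogram) features — 18 features.

Intensity-based statistics are computed on the raw in-ROI values; entropy and
uniformity are computed on the discretized gray levels.  Population (biased)
moments are used throughout.  Degenerate conventions: zero-variance skewness
and kurtosis are 0, entropy of a single occupied level is 0, uniformity of a
single level is 1.
"""

from __future__ import annotations

import numpy as np

from .discretize import DiscretizedROI

FIRSTORDER_NAMES = (
    "Energy",
    "TotalEnergy",
    "Entropy",
    "Minimum",
    "10Percentile",
    "90Percentile",
    "Maximum",
    "Mean",
    "Median",
    "InterquartileRange",
    "Range",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "RootMeanSquared",
    "Skewness",
    "Kurtosis",
    "Variance",
    "Uniformity",
)


def first_order(d: DiscretizedROI) -> dict[str, float]:
    x = d.roi_values
    n = x.size
    if n == 0:
        raise ValueError("empty ROI")
    mean = float(x.mean())
    var = float(x.var())  # population variance
    p10, p25, p75, p90 = (float(np.percentile(x, q)) for q in (10, 25, 75, 90))

    if var > 0:
        std = np.sqrt(var)
        skew = float(((x - mean) ** 3).mean() / std**3)
        kurt = float(((x - mean) ** 4).mean() / std**4)
    else:
        skew = 0.0
        kurt = 0.0

    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0

    # histogram statistics on the discretized levels
    counts = np.bincount(d.roi_levels, minlength=d.n_bins + 1)[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    energy = float((x**2).sum())
    voxel_volume = float(np.prod(d.voxel_size_mm))

    return {
        "Energy": energy,
        "TotalEnergy": voxel_volume * energy,
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": p10,
        "90Percentile": p90,
        "Maximum": float(x.max()),
        "Mean": mean,
        "Median": float(np.median(x)),
        "InterquartileRange": p75 - p25,
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": uniformity,
    }
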