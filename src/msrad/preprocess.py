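"""Preprocessing chain: resample -> threshold masks -> bias-correct -> normalize.

Only the conventional (arbitrary-unit) T1w channel is bias-corrected and
z-normalized; quantitative maps (PD, MT, R1, R2*) carry physical units and
must not be rescaled.  Tissue probability maps are binarized at a high
threshold (default 0.9) to keep only voxels confidently assigned to a tissue.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from scipy import ndimage

from .core import TissueMasks, Volume

MASK_THRESHOLD = 0.9

#: when a voxel clears the threshold for several tissues, ties go to the
#: highest probability, then by this priority (highest first)
_TIE_PRIORITY = ("lesion", "nawm", "gm", "csf")


def resample_isotropic(v: Volume, target_mm) -> Volume:
    """Resample to a target voxel spacing with cubic-spline interpolation.

    The output grid spans the same physical extent (voxel-center convention);
    an identity target returns values unchanged.
    """
    t = np.atleast_1d(np.asarray(target_mm, dtype=float))
    if t.size == 1:
        target = (float(t[0]),) * 3
    elif t.size == 3:
        target = tuple(float(x) for x in t)
    else:
        raise ValueError("target spacing must be a scalar or 3 values")
    if any(x <= 0 for x in target):
        raise ValueError("target spacing must be positive")

    in_sp = v.voxel_size_mm
    if np.allclose(target, in_sp):
        return replace(v, data=v.data.copy())

    new_shape = tuple(
        max(1, int(round((n - 1) * s / t)) + 1)
        for n, s, t in zip(v.data.shape, in_sp, target)
    )
    grids = [
        np.arange(m, dtype=np.float64) * t / s
        for m, s, t in zip(new_shape, in_sp, target)
    ]
    coords = np.meshgrid(*grids, indexing="ij")
    out = ndimage.map_coordinates(
        v.data, np.stack(coords), order=3, mode="nearest", prefilter=True
    )
    return Volume(out, target, v.channel)


def threshold_masks(
    prob_maps: dict[str, np.ndarray], threshold: float = MASK_THRESHOLD
) -> TissueMasks:
    """Binarize tissue probability maps at a high confidence threshold.

    A voxel enters a tissue mask iff its probability >= threshold; voxels
    clearing the threshold for more than one tissue go to the most probable
    tissue (ties resolved lesion > nawm > gm > csf).
    """
    names = ("csf", "gm", "nawm", "lesion")
    maps = {}
    for name in names:
        key = name if name in prob_maps else name.upper()
        if key not in prob_maps:
            if name == "lesion":
                maps[name] = None
                continue
            raise KeyError(f"probability map for {name!r} missing")
        pm = np.asarray(prob_maps[key], dtype=np.float64)
        if pm.min() < 0 or pm.max() > 1:
            raise ValueError(f"{name} probabilities outside [0, 1]")
        maps[name] = pm
    shape = maps["gm"].shape
    if maps["lesion"] is None:
        maps["lesion"] = np.zeros(shape)

    stack = np.stack([maps[n] for n in names])
    supra = stack >= threshold
    # rank by probability, broken by fixed priority for exact ties
    prio = np.array([_TIE_PRIORITY.index(n) for n in names], dtype=np.float64)
    score = np.where(supra, stack - 1e-12 * prio[:, None, None, None], -np.inf)
    winner = score.argmax(axis=0)
    any_supra = supra.any(axis=0)

    masks = {n: (winner == k) & any_supra for k, n in enumerate(names)}
    tm = TissueMasks(**masks)
    if not tm.nawm.any() or not tm.gm.any():
        raise ValueError("thresholding produced an empty NAWM or GM mask")
    return tm


def correct_bias(
    v: Volume,
    tiv: np.ndarray,
    degree: int = 3,
    method: str = "poly",
    n_classes: int = 7,
    n_iter: int = 5,
) -> Volume:
    """Remove a smooth multiplicative intensity field from a T1w volume.

    The default estimator alternates, in the log domain within the TIV,
    between (a) a K-class 1D clustering of the corrected intensities (the
    tissue decomposition) and (b) a degree-<=3 polynomial least-squares fit
    to the residual log intensity after subtracting each voxel's class mean
    — so anatomy is explained by the class means and only the smooth
    low-frequency remainder is attributed to bias and divided out.  The TIV
    mean intensity is preserved.  ``method="n4"`` delegates to the N4
    algorithm via SimpleITK instead.
    """
    if v.channel != "T1w":
        raise ValueError("bias correction applies to the T1w channel only")
    tiv = np.asarray(tiv, dtype=bool)
    if not tiv.any():
        raise ValueError("empty TIV mask")

    if method == "n4":
        return _correct_bias_n4(v, tiv)
    if method != "poly":
        raise ValueError(f"unknown bias-correction method {method!r}")

    data = v.data
    floor = np.abs(data[tiv]).max() * 1e-6 + np.finfo(float).tiny
    log_tiv = np.log(np.maximum(data[tiv], floor))

    coords = np.argwhere(tiv).astype(np.float64)
    center = (np.asarray(data.shape) - 1) / 2.0
    scale = np.maximum((np.asarray(data.shape) - 1) / 2.0, 1.0)
    X = _poly_design((coords - center) / scale, degree)
    gram = np.linalg.pinv(X.T @ X) @ X.T  # reused across iterations

    field_tiv = np.zeros(log_tiv.shape)
    for _ in range(n_iter):
        corrected_log = log_tiv - field_tiv
        class_means = _kmeans_1d(corrected_log, n_classes)
        assigned = class_means[
            np.argmin(np.abs(corrected_log[:, None] - class_means[None, :]), axis=1)
        ]
        beta = gram @ (log_tiv - assigned)
        field_tiv = X @ beta
        field_tiv -= field_tiv.mean()

    grids = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in data.shape], indexing="ij")
    all_coords = (np.stack([g.ravel() for g in grids], axis=1) - center) / scale
    field = (_poly_design(all_coords, degree) @ beta).reshape(data.shape)
    field -= field[tiv].mean()  # unit-mean multiplicative field in log domain
    corrected = data / np.exp(field)
    corrected *= data[tiv].mean() / corrected[tiv].mean()
    return replace(v, data=corrected)


def _kmeans_1d(x: np.ndarray, k: int, n_iter: int = 25) -> np.ndarray:
    """Deterministic 1D k-means (Lloyd) seeded at evenly spaced quantiles."""
    centers = np.quantile(x, (np.arange(k) + 0.5) / k)
    for _ in range(n_iter):
        idx = np.argmin(np.abs(x[:, None] - centers[None, :]), axis=1)
        new = np.array([x[idx == j].mean() if (idx == j).any() else centers[j] for j in range(k)])
        if np.allclose(new, centers):
            break
        centers = new
    return centers


def _poly_design(x: np.ndarray, degree: int) -> np.ndarray:
    """Trivariate polynomial design matrix with total degree <= degree."""
    cols = []
    for i in range(degree + 1):
        for j in range(degree + 1 - i):
            for k in range(degree + 1 - i - j):
                cols.append(x[:, 0] ** i * x[:, 1] ** j * x[:, 2] ** k)
    return np.stack(cols, axis=1)


def _correct_bias_n4(v: Volume, tiv: np.ndarray) -> Volume:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(v.data)
    img.SetSpacing(tuple(reversed(v.voxel_size_mm)))
    mask = sitk.GetImageFromArray(tiv.astype(np.uint8))
    mask.CopyInformation(img)
    shift = float(max(0.0, -v.data.min())) + 1e-3  # N4 needs positive input
    out = sitk.N4BiasFieldCorrection(sitk.Cast(img + shift, sitk.sitkFloat64), mask)
    corrected = sitk.GetArrayFromImage(out) - shift
    corrected *= v.data[tiv].mean() / corrected[tiv].mean()
    return replace(v, data=corrected)


def normalize_tiv(v: Volume, tiv: np.ndarray) -> Volume:
    """Z-normalize a T1w volume using the TIV mean and population SD.

    All voxels are transformed with the TIV statistics, so in-TIV intensities
    end at mean 0 / SD 1 while out-of-TIV voxels never influence them.
    """
    if v.channel != "T1w":
        raise ValueError("z-normalization applies to the T1w channel only")
    tiv = np.asarray(tiv, dtype=bool)
    vals = v.data[tiv]
    if vals.size < 2:
        raise ValueError("TIV must contain at least 2 voxels")
    mu = vals.mean()
    sigma = vals.std()  # population SD
    if sigma == 0:
        raise ValueError("zero intensity variance within TIV")
    return replace(v, data=(v.data - mu) / sigma)


def preprocess_subject(subject, threshold: float = MASK_THRESHOLD, bias_method: str = "poly"):
    """Apply the full chain to one synthetic subject; returns a new subject
    with ``masks`` set and the T1w channel bias-corrected and normalized."""
    masks = threshold_masks(subject.prob_maps, threshold)
    volumes = dict(subject.volumes)
    if "T1w" in volumes:
        t1 = volumes["T1w"]
        vals = t1.data[masks.tiv]
        # an already z-normalized volume (TIV mean 0, SD 1) has been through
        # the chain before; reprocessing it must be a no-op
        already = abs(vals.mean()) < 1e-9 and abs(vals.std() - 1.0) < 1e-9
        if not already:
            t1 = correct_bias(t1, masks.tiv, method=bias_method)
            volumes["T1w"] = normalize_tiv(t1, masks.tiv)
    return replace(subject, volumes=volumes, masks=masks)
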