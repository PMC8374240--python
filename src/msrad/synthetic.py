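"""Seeded synthetic multi-channel brain cohorts.

The generator emulates the statistical structure the analysis assumes, not
anatomy: a brain phantom of nested ellipsoids (background -> CSF -> GM shell
-> WM core), per-tissue intensities with between-subject variability and
spatially correlated intra-tissue texture, focal WM lesions for patients
(MSP) only, an optional multiplicative low-frequency bias field on the
arbitrary-unit T1w channel, and demographic covariates.  Tissue probability
maps are smoothed indicator functions, so the downstream 0.9-threshold step
has genuine partial-volume boundaries to resolve.

Channel units are arbitrary for T1w; quantitative channels use plausible
positive scales (percent units for PD, p.u. for MT saturation, 1/s for R1
and R2*).  Absolute scales are irrelevant downstream except for T1w, which
is the only channel that gets z-normalized.

Class differences are planted through :class:`EffectSpec` (diffuse mean
shifts and texture-correlation-length shifts per channel and ROI) and
through the lesions themselves, which are hypo-intense on T1w and MT and
hyper-intense on PD.  ``null_effect=True`` zeroes every planted class
difference — including lesions, which would otherwise leak class signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import Volume

DEFAULT_CHANNELS = ("T1w", "PD", "MT", "R1", "R2*")

#: per-channel tissue mean intensities (documented constants; a.u. for T1w,
#: % for PD, p.u. for MT, 1/s for R1 and R2*)
TISSUE_MEANS: dict[str, dict[str, float]] = {
    "T1w": {"csf": 30.0, "gm": 70.0, "wm": 100.0},
    "PD": {"csf": 100.0, "gm": 85.0, "wm": 70.0},
    "MT": {"csf": 0.3, "gm": 1.2, "wm": 2.0},
    "R1": {"csf": 0.35, "gm": 0.70, "wm": 1.05},
    "R2*": {"csf": 1.5, "gm": 15.0, "wm": 21.0},
}

#: lesion intensity as a multiple of the WM mean: hypo-intense on T1w and MT,
#: hyper-intense on PD, isointense on R1/R2*
LESION_CONTRAST: dict[str, float] = {
    "T1w": 0.70,
    "PD": 1.15,
    "MT": 0.60,
    "R1": 1.0,
    "R2*": 1.0,
}

#: default i.i.d. voxel noise SD per channel (~3-4% of the WM mean)
NOISE_SIGMA: dict[str, float] = {
    "T1w": 4.0,
    "PD": 2.5,
    "MT": 0.08,
    "R1": 0.04,
    "R2*": 0.8,
}

#: between-subject SD of a tissue mean, as a fraction of that mean — the
#: biological variability that keeps per-subject tissue means from being
#: trivially separable
REL_BETWEEN_SUBJECT_SD = 0.03

#: SD of the spatially correlated intra-tissue fluctuation field, as a
#: multiple of the channel noise SD
TEXTURE_AMPLITUDE = 1.0

#: base spatial correlation length of intra-tissue fluctuations (mm)
BASE_TEXTURE_LENGTH_MM = 2.0

_TISSUES = ("csf", "gm", "nawm", "lesion")


def between_subject_sd(channel: str, tissue: str = "wm") -> float:
    """Between-subject SD of the per-subject tissue mean for a channel."""
    return REL_BETWEEN_SUBJECT_SD * TISSUE_MEANS[channel][tissue]


@dataclass
class EffectSpec:
    """Planted class differences (MSP minus HCS).

    ``channel_roi_mean_shift`` maps ``(channel, roi)`` (roi in WM/NAWM/GM) to
    an additive shift of the tissue mean in channel units; a WM entry applies
    to NAWM and lesion tissue alike.  ``channel_roi_texture_scale`` shifts
    the spatial correlation length (mm) of the intra-tissue fluctuations.
    ``null_effect=True`` zeroes all shifts and suppresses lesions.
    """

    channel_roi_mean_shift: dict[tuple[str, str], float] = field(default_factory=dict)
    channel_roi_texture_scale: dict[tuple[str, str], float] = field(default_factory=dict)
    null_effect: bool = False

    def mean_shift(self, channel: str, tissue: str) -> float:
        if self.null_effect:
            return 0.0
        shift = 0.0
        if tissue in ("nawm", "lesion"):
            shift += self.channel_roi_mean_shift.get((channel, "WM"), 0.0)
        if tissue == "nawm":
            shift += self.channel_roi_mean_shift.get((channel, "NAWM"), 0.0)
        if tissue == "gm":
            shift += self.channel_roi_mean_shift.get((channel, "GM"), 0.0)
        return shift

    def texture_shift(self, channel: str, tissue: str) -> float:
        if self.null_effect:
            return 0.0
        shift = 0.0
        if tissue in ("nawm", "lesion"):
            shift += self.channel_roi_texture_scale.get((channel, "WM"), 0.0)
        if tissue == "nawm":
            shift += self.channel_roi_texture_scale.get((channel, "NAWM"), 0.0)
        if tissue == "gm":
            shift += self.channel_roi_texture_scale.get((channel, "GM"), 0.0)
        return shift


def default_effect() -> EffectSpec:
    """Diffuse qMRI alterations of the kind MS produces in NAWM and GM:
    demyelination lowers MT and R1, raises free-water PD, and slightly lowers
    R2*; shifts are modest (~1 between-subject SD).  T1w carries no diffuse
    shift — its class contrast comes from lesions only."""
    return EffectSpec(
        channel_roi_mean_shift={
            ("MT", "NAWM"): -0.06,
            ("MT", "GM"): -0.035,
            ("R1", "NAWM"): -0.03,
            ("R1", "GM"): -0.02,
            ("PD", "NAWM"): 2.0,
            ("PD", "GM"): 2.0,
            ("R2*", "NAWM"): -0.6,
            ("R2*", "GM"): -0.4,
        },
        channel_roi_texture_scale={("MT", "NAWM"): 0.5, ("R1", "NAWM"): 0.5},
    )


@dataclass
class CohortSpec:
    """Generation recipe for one cohort (development-style default: 36 HCS /
    36 MSP, five channels, two scanners, 1 mm isotropic 48^3 grids)."""

    n_hcs: int = 36
    n_msp: int = 36
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_scanners: int = 2
    lesion_count_range: tuple[int, int] = (2, 5)
    lesion_radius_range_mm: tuple[float, float] = (1.5, 3.0)
    effect: EffectSpec = field(default_factory=default_effect)
    noise_sigma: dict[str, float] = field(default_factory=lambda: dict(NOISE_SIGMA))
    bias_amplitude: float = 0.2
    seed: int = 0
    id_prefix: str = ""
    scanner_prefix: str = "scanner"

    def __post_init__(self) -> None:
        if self.n_hcs < 2 or self.n_msp < 2:
            raise ValueError("need at least 2 subjects per class")
        if any(g < 32 for g in self.grid_shape):
            raise ValueError("grid_shape must be >= 32 per axis")
        unknown = set(self.channels) - set(DEFAULT_CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")


@dataclass
class Subject:
    """One participant: covariates, channel volumes, tissue probability maps
    and (after preprocessing) binary tissue masks."""

    id: str
    status: int  # 0 = HCS, 1 = MSP
    age: float
    gender: str
    scanner: str
    volumes: dict[str, Volume]
    prob_maps: dict[str, np.ndarray]
    masks: object | None = None


def generate_cohort(spec: CohortSpec) -> list[Subject]:
    """Generate a deterministic cohort (HCS first, then MSP)."""
    n_total = spec.n_hcs + spec.n_msp
    children = np.random.SeedSequence(spec.seed).spawn(n_total)
    subjects = []
    for k in range(n_total):
        status = int(k >= spec.n_hcs)
        label = "HCS" if status == 0 else "MSP"
        number = k if status == 0 else k - spec.n_hcs
        subjects.append(
            _generate_subject(
                spec,
                subject_id=f"{spec.id_prefix}{label}{number:03d}",
                status=status,
                gender="MF"[k % 2],
                scanner=f"{spec.scanner_prefix}{k % spec.n_scanners}",
                rng=np.random.default_rng(children[k]),
            )
        )
    return subjects


def _ellipsoid(shape, semi_frac) -> np.ndarray:
    grids = np.meshgrid(
        *[(np.arange(n) - (n - 1) / 2.0) / (n * f) for n, f in zip(shape, semi_frac)],
        indexing="ij",
    )
    return sum(g**2 for g in grids) <= 1.0


def _generate_subject(spec, subject_id, status, gender, scanner, rng) -> Subject:
    shape = spec.grid_shape
    vox = spec.voxel_size_mm

    brain = _ellipsoid(shape, (0.47, 0.47, 0.47))
    gm_outer = _ellipsoid(shape, (0.38, 0.38, 0.38))
    wm_core = _ellipsoid(shape, (0.28, 0.28, 0.28))
    labels = np.zeros(shape, dtype=np.int8)  # 0 bg, 1 csf, 2 gm, 3 nawm, 4 lesion
    labels[brain] = 1
    labels[gm_outer] = 2
    labels[wm_core] = 3

    lesion_mask = np.zeros(shape, dtype=bool)
    plant_lesions = status == 1 and not spec.effect.null_effect
    if plant_lesions:
        n_lesions = int(rng.integers(spec.lesion_count_range[0], spec.lesion_count_range[1] + 1))
        dist = ndimage.distance_transform_edt(wm_core, sampling=vox)
        for _ in range(n_lesions):
            radius = float(rng.uniform(*spec.lesion_radius_range_mm))
            fits = dist > radius
            if lesion_mask.any():
                # keep lesions disjoint (a one-voxel gap) so component counts
                # match the requested lesion count
                gap = ndimage.distance_transform_edt(~lesion_mask, sampling=vox)
                fits &= gap > radius + max(vox) * 1.8
            candidates = np.argwhere(fits)
            if candidates.size == 0:
                raise ValueError(
                    f"subject {subject_id}: lesion radius {radius:.1f} mm "
                    "cannot fit inside the WM core"
                )
            center = candidates[rng.integers(len(candidates))]
            zz, yy, xx = np.meshgrid(
                *[(np.arange(n) - c) * s for n, c, s in zip(shape, center, vox)],
                indexing="ij",
            )
            lesion_mask |= zz**2 + yy**2 + xx**2 <= radius**2
        labels[lesion_mask] = 4

    # probability maps: Gaussian-smoothed one-hot indicators (plus implicit
    # background class), so voxelwise sums stay <= 1
    prob_maps = {}
    for code, name in ((1, "csf"), (2, "gm"), (3, "nawm"), (4, "lesion")):
        prob_maps[name] = np.clip(
            ndimage.gaussian_filter(
                (labels == code).astype(np.float64), sigma=0.8, mode="constant"
            ),
            0.0,
            1.0,
        )

    # per-subject tissue means: base + between-subject variation + class shift
    volumes = {}
    tissue_codes = {"csf": 1, "gm": 2, "nawm": 3, "lesion": 4}
    for channel in spec.channels:
        base = TISSUE_MEANS[channel]
        means = {
            "csf": base["csf"],
            "gm": base["gm"],
            "nawm": base["wm"],
            "lesion": base["wm"] * LESION_CONTRAST[channel],
        }
        data = np.zeros(shape, dtype=np.float64)
        total_prob = np.zeros(shape, dtype=np.float64)
        for tissue in _TISSUES:
            mean_t = means[tissue] + rng.normal(0.0, REL_BETWEEN_SUBJECT_SD * abs(means[tissue]))
            if status == 1:
                mean_t += spec.effect.mean_shift(channel, tissue)
            corr_len = BASE_TEXTURE_LENGTH_MM
            if status == 1:
                corr_len += spec.effect.texture_shift(channel, tissue)
            sigma_vox = np.maximum(np.asarray(corr_len) / np.asarray(vox), 1e-3)
            white = rng.normal(size=shape)
            fieldv = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
            fstd = fieldv.std()
            if fstd > 0:
                fieldv *= TEXTURE_AMPLITUDE * spec.noise_sigma[channel] / fstd
            p = prob_maps[tissue]
            data += p * (mean_t + fieldv)
            total_prob += p
        data += rng.normal(0.0, spec.noise_sigma[channel], size=shape)
        if channel == "T1w" and spec.bias_amplitude > 0:
            bias = ndimage.gaussian_filter(rng.normal(size=shape), sigma=min(shape) / 3.0, mode="reflect")
            span = np.abs(bias).max()
            if span > 0:
                bias /= span
            data *= 1.0 + spec.bias_amplitude * bias
        volumes[channel] = Volume(data, vox, channel)

    return Subject(
        id=subject_id,
        status=status,
        age=float(rng.uniform(25.0, 65.0)),
        gender=gender,
        scanner=scanner,
        volumes=volumes,
        prob_maps=prob_maps,
    )


def cohort_dataframe(subjects) -> "pandas.DataFrame":  # noqa: F821
    """Covariate table (id, status, age, gender, scanner)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": [s.id for s in subjects],
            "status": [s.status for s in subjects],
            "age": [s.age for s in subjects],
            "gender": [s.gender for s in subjects],
            "scanner": [s.scanner for s in subjects],
        }
    )


def validation_spec(seed: int = 1, n_hcs: int = 30, n_msp: int = 4, **kw) -> CohortSpec:
    """An unbalanced external-validation cohort (many controls, few patients,
    different scanner labels), mirroring open multi-site validation data."""
    defaults = dict(
        n_hcs=n_hcs,
        n_msp=n_msp,
        channels=("T1w",),
        n_scanners=3,
        seed=seed,
        id_prefix="VAL-",
        scanner_prefix="val-scanner",
    )
    defaults.update(kw)
    return CohortSpec(**defaults)


def apply_effect(spec: CohortSpec, effect: EffectSpec) -> CohortSpec:
    return replace(spec, effect=effect)
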