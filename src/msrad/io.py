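"""NIfTI / CSV / YAML serialization of cohorts and results."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .core import Volume
from .synthetic import CohortSpec, EffectSpec, Subject


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_volume(v: Volume, path: Path) -> None:
    nib.save(nib.Nifti1Image(v.data.astype(np.float32), _affine(v.voxel_size_mm)), str(path))


def load_volume(path: Path, channel: str) -> Volume:
    img = nib.load(str(path))
    voxel = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(np.asarray(img.dataobj, dtype=np.float64), voxel, channel)


def save_mask(mask: np.ndarray, voxel_size_mm, path: Path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), _affine(voxel_size_mm)), str(path))


def save_map(data: np.ndarray, voxel_size_mm, path: Path) -> None:
    nib.save(nib.Nifti1Image(data.astype(np.float32), _affine(voxel_size_mm)), str(path))


_CHANNEL_FILE = {"T1w": "T1w", "PD": "PD", "MT": "MT", "R1": "R1", "R2*": "R2star"}
_FILE_CHANNEL = {v: k for k, v in _CHANNEL_FILE.items()}


def save_cohort(subjects: list[Subject], out_dir: Path) -> None:
    """Per-subject NIfTI volumes and probability maps plus a cohort CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in subjects:
        sdir = out_dir / s.id
        sdir.mkdir(exist_ok=True)
        for channel, v in s.volumes.items():
            save_volume(v, sdir / f"{_CHANNEL_FILE[channel]}.nii.gz")
        voxel = next(iter(s.volumes.values())).voxel_size_mm
        for tissue, pm in s.prob_maps.items():
            nib.save(
                nib.Nifti1Image(pm.astype(np.float32), _affine(voxel)),
                str(sdir / f"prob_{tissue}.nii.gz"),
            )
        rows.append(
            {"id": s.id, "status": s.status, "age": s.age,
             "gender": s.gender, "scanner": s.scanner}
        )
    pd.DataFrame(rows).to_csv(out_dir / "cohort.csv", index=False)


def load_cohort(in_dir: Path) -> list[Subject]:
    in_dir = Path(in_dir)
    table = pd.read_csv(in_dir / "cohort.csv")
    subjects = []
    for _, row in table.iterrows():
        sdir = in_dir / str(row["id"])
        volumes = {}
        for f in sorted(sdir.glob("*.nii.gz")):
            stem = f.name.replace(".nii.gz", "")
            if stem.startswith("prob_"):
                continue
            channel = _FILE_CHANNEL[stem]
            volumes[channel] = load_volume(f, channel)
        prob_maps = {
            f.name.replace(".nii.gz", "").replace("prob_", ""): np.asarray(
                nib.load(str(f)).dataobj, dtype=np.float64
            )
            for f in sorted(sdir.glob("prob_*.nii.gz"))
        }
        subjects.append(
            Subject(
                id=str(row["id"]), status=int(row["status"]), age=float(row["age"]),
                gender=str(row["gender"]), scanner=str(row["scanner"]),
                volumes=volumes, prob_maps=prob_maps,
            )
        )
    return subjects


def cohort_spec_from_yaml(path: Path) -> CohortSpec:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return cohort_spec_from_dict(raw)


def cohort_spec_from_dict(raw: dict) -> CohortSpec:
    raw = dict(raw)
    if "effect" in raw and isinstance(raw["effect"], dict):
        eff = raw["effect"]
        raw["effect"] = EffectSpec(
            channel_roi_mean_shift={
                tuple(k.split("/")): v
                for k, v in eff.get("channel_roi_mean_shift", {}).items()
            },
            channel_roi_texture_scale={
                tuple(k.split("/")): v
                for k, v in eff.get("channel_roi_texture_scale", {}).items()
            },
            null_effect=bool(eff.get("null_effect", False)),
        )
    for key in ("channels", "grid_shape", "voxel_size_mm", "lesion_count_range",
                "lesion_radius_range_mm"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return CohortSpec(**raw)
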