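"""Shared fixtures: tiny deterministic cohorts and ROIs.

Heavy artifacts (the planted-effect pipeline run) are session-scoped so the
full-pipeline and permutation-audit checks share one computation.
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from msrad.core import Volume
from msrad.features.discretize import DiscretizedROI
from msrad.preprocess import preprocess_subject
from msrad.synthetic import CohortSpec, EffectSpec, generate_cohort


def make_discretized(levels: np.ndarray, raw: np.ndarray | None = None,
                     n_bins: int | None = None) -> DiscretizedROI:
    """Wrap an explicit integer level grid as a DiscretizedROI (0 = out-of-ROI)."""
    levels = np.asarray(levels, dtype=np.int32)
    mask = levels > 0
    if raw is None:
        raw = levels.astype(np.float64)
    nb = n_bins or max(int(levels.max()), 1)
    return DiscretizedROI(
        levels=levels,
        roi_mask=mask,
        raw=np.asarray(raw, dtype=np.float64),
        n_bins=nb,
        bin_edges=np.linspace(0, 1, nb + 1),
        bounding_box=(0, levels.shape[0], 0, levels.shape[1], 0, levels.shape[2]),
        voxel_size_mm=(1.0, 1.0, 1.0),
    )


def random_level_grids(n_grids: int, shape=(5, 5, 5), max_levels: int = 4, seed: int = 0):
    """Random small level grids with occasional out-of-ROI voxels."""
    rng = np.random.default_rng(seed)
    grids = []
    for _ in range(n_grids):
        g = rng.integers(1, max_levels + 1, size=shape).astype(np.int32)
        # poke some holes so the ROI is not the full box
        holes = rng.random(shape) < 0.15
        g[holes] = 0
        if not (g > 0).any():
            g[0, 0, 0] = 1
        grids.append(g)
    return grids


@pytest.fixture
def volume_cube():
    """An 8x8x8 unit-spacing volume with a reproducible random field."""
    rng = np.random.default_rng(42)
    return Volume(rng.normal(size=(8, 8, 8)), (1.0, 1.0, 1.0), "MT")


@pytest.fixture(scope="session")
def tiny_cohort():
    """4-subject two-channel cohort at the minimum grid size, preprocessed."""
    spec = CohortSpec(
        n_hcs=2, n_msp=2, channels=("T1w", "MT"), grid_shape=(32, 32, 32), seed=11,
        lesion_count_range=(1, 2), lesion_radius_range_mm=(1.5, 2.5),
    )
    return [preprocess_subject(s) for s in generate_cohort(spec)]


def smoke_config(tmp_path=None, channels=("T1w", "MT"), seed=0, permute=True):
    """A small but complete study configuration (16 subjects, 32^3 grids)."""
    from msrad.model import ModelConfig
    from msrad.select import SelectionConfig
    from msrad.study import StudyConfig
    from msrad.synthetic import validation_spec

    return StudyConfig(
        cohort=CohortSpec(
            n_hcs=8, n_msp=8, channels=channels, grid_shape=(32,) * 3,
            n_scanners=2, seed=0,
            lesion_count_range=(1, 2), lesion_radius_range_mm=(1.5, 2.5),
        ),
        validation_cohort=validation_spec(
            n_hcs=10, n_msp=3, grid_shape=(32,) * 3,
            lesion_count_range=(1, 2), lesion_radius_range_mm=(1.5, 2.5),
        ),
        selection=SelectionConfig(n_iterations=2, cohort_size=20),
        model=ModelConfig(n_boot=25, cohort_size=20),
        output_dir=tmp_path,
        global_seed=seed,
        run_permutation=permute,
    )


@pytest.fixture(scope="session")
def smoke_report(tmp_path_factory):
    from msrad.study import run_study

    out = tmp_path_factory.mktemp("study")
    return run_study(smoke_config(out)), out


@pytest.fixture(scope="session")
def null_cohort_spec():
    return CohortSpec(
        n_hcs=6, n_msp=6, channels=("MT",), grid_shape=(32, 32, 32),
        effect=EffectSpec(null_effect=True), seed=3,
    )


def planted_cohort_spec(shift_sd: float = 1.5) -> CohortSpec:
    """40-subject MT cohort with a planted WM mean shift of ``shift_sd``
    pooled between-subject SDs (plus the default focal lesions)."""
    from msrad.synthetic import between_subject_sd

    shift = -shift_sd * between_subject_sd("MT", "wm")
    return CohortSpec(
        n_hcs=20, n_msp=20, channels=("MT",), grid_shape=(48,) * 3,
        effect=EffectSpec(channel_roi_mean_shift={("MT", "WM"): shift}),
        seed=0,
    )


@pytest.fixture(scope="session")
def planted_run():
    """Full pipeline (100-iteration stability selection, LR) on the
    planted-effect cohort; shared by the recovery and permutation checks."""
    from msrad.select import SelectionConfig
    from msrad.study import run_single_combination, stage_seed

    return run_single_combination(
        planted_cohort_spec(),
        channel="MT",
        roi="WM",
        selection=SelectionConfig(n_iterations=100, seed=stage_seed(7, "select")),
        seed=7,
    )
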