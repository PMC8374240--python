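"""Feature extraction: discretization, first-order statistics, registry
cardinality, the wide table, and invariance properties."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_discretized
from msrad.core import Volume
from msrad.features import (
    FAMILIES,
    FEATURE_NAMES,
    compute_all,
    discretize_fbn,
    extract_all,
    extract_roi,
    first_order,
)
from msrad.features.extract import feature_columns_of


class TestDiscretize:
    def test_hand_computed_levels(self):
        data = np.zeros((1, 1, 3))
        data[0, 0] = [0.0, 0.5, 1.0]
        v = Volume(data, (1, 1, 1), "MT")
        d = discretize_fbn(v, np.ones_like(data, dtype=bool), n_bins=2, padding=0)
        np.testing.assert_array_equal(d.levels[0, 0], [1, 2, 2])

    def test_constant_roi_maps_to_level_one(self):
        v = Volume(np.full((4, 4, 4), 2.0), (1, 1, 1), "MT")
        d = discretize_fbn(v, np.ones((4, 4, 4), dtype=bool), n_bins=50)
        assert set(np.unique(d.roi_levels)) == {1}

    def test_levels_bounded_by_n_bins(self, volume_cube):
        roi = np.ones(volume_cube.data.shape, dtype=bool)
        d = discretize_fbn(volume_cube, roi, n_bins=50)
        assert d.roi_levels.min() >= 1 and d.roi_levels.max() <= 50

    def test_bounding_box_pads_and_clips(self, volume_cube):
        roi = np.zeros(volume_cube.data.shape, dtype=bool)
        roi[3:5, 3:5, 3:5] = True
        d = discretize_fbn(volume_cube, roi, n_bins=4, padding=5)
        assert d.levels.shape == volume_cube.data.shape  # clipped at borders

    def test_empty_roi_errors(self, volume_cube):
        with pytest.raises(ValueError):
            discretize_fbn(volume_cube, np.zeros(volume_cube.data.shape, bool))


class TestFirstOrder:
    def test_constant_roi_conventions(self):
        d = make_discretized(np.ones((3, 3, 3), dtype=int), raw=np.full((3, 3, 3), 4.0))
        f = first_order(d)
        assert f["Mean"] == f["Median"] == f["Minimum"] == f["Maximum"] == 4.0
        assert f["Variance"] == 0.0
        assert f["Skewness"] == 0.0 and f["Kurtosis"] == 0.0
        assert f["Uniformity"] == 1.0 and f["Entropy"] == 0.0

    def test_hand_computed_statistics(self):
        raw = np.array([1.0, 2.0, 3.0, 4.0]).reshape(1, 1, 4)
        d = make_discretized(np.array([1, 1, 2, 2]).reshape(1, 1, 4), raw=raw)
        f = first_order(d)
        assert f["Mean"] == 2.5
        assert f["Variance"] == 1.25  # population
        assert f["Range"] == 3.0
        assert f["Energy"] == 1 + 4 + 9 + 16
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt(30 / 4))
        assert f["Entropy"] == pytest.approx(1.0)  # two equally occupied bins

    def test_family_cardinalities_sum_to_93(self):
        sizes = {fam: len(names) for fam, names in FAMILIES.items()}
        assert sizes == {
            "firstorder": 18, "glcm": 24, "glrlm": 16,
            "glszm": 16, "ngtdm": 5, "gldm": 14,
        }
        assert len(FEATURE_NAMES) == 93

    def test_headline_feature_names_exist(self):
        # the names the analysis reports on must be extractable
        for name in (
            "firstorder_Minimum",
            "glcm_ClusterShade",
            "gldm_LargeDependenceHighGrayLevelEmphasis",
            "gldm_SmallDependenceLowGrayLevelEmphasis",
        ):
            assert name in FEATURE_NAMES


class _FakeSubject:
    def __init__(self, sid, volumes, masks):
        self.id = sid
        self.status = 0
        self.age = 40.0
        self.gender = "F"
        self.scanner = "s0"
        self.volumes = volumes
        self.masks = masks


class TestExtractAll:
    def test_single_channel_single_roi_gives_93_columns(self, tiny_cohort):
        table = extract_all(tiny_cohort[:2], ("MT",), ("WM",))
        assert len(feature_columns_of(table)) == 93

    def test_two_channels_three_rois_scale_linearly(self, tiny_cohort):
        table = extract_all(tiny_cohort[:2], ("MT", "T1w"), ("WM", "NAWM", "GM"))
        assert len(feature_columns_of(table)) == 93 * 2 * 3
        assert not table[feature_columns_of(table)].isna().any().any()
        for roi in ("WM", "NAWM", "GM"):
            assert (table[f"roi_volume__{roi}"] > 0).all()

    def test_identical_subjects_give_identical_rows(self, tiny_cohort):
        s = tiny_cohort[0]
        clone = _FakeSubject("clone", s.volumes, s.masks)
        orig = _FakeSubject("orig", s.volumes, s.masks)
        table = extract_all([orig, clone], ("MT",), ("WM",))
        cols = feature_columns_of(table)
        pd.testing.assert_series_equal(
            table.loc["orig", cols], table.loc["clone", cols], check_names=False
        )


class TestInvariances:
    def test_translation_inside_larger_grid(self, volume_cube):
        roi = np.zeros((16, 16, 16), dtype=bool)
        roi[1:9, 1:9, 1:9] = True
        big = np.zeros((16, 16, 16))
        big[1:9, 1:9, 1:9] = volume_cube.data
        a = extract_roi(Volume(big, (1, 1, 1), "MT"), roi, n_bins=8)

        roi2 = np.roll(roi, (4, 3, 2), axis=(0, 1, 2))
        big2 = np.roll(big, (4, 3, 2), axis=(0, 1, 2))
        b = extract_roi(Volume(big2, (1, 1, 1), "MT"), roi2, n_bins=8)
        for name in FEATURE_NAMES:
            assert a[name] == pytest.approx(b[name], rel=1e-12), name

    def test_affine_intensity_transform_leaves_texture_unchanged(self, volume_cube):
        roi = np.ones(volume_cube.data.shape, dtype=bool)
        a = extract_roi(volume_cube, roi, n_bins=8)
        scaled = Volume(3.0 * volume_cube.data + 10.0, (1, 1, 1), "MT")
        b = extract_roi(scaled, roi, n_bins=8)
        texture = [n for n in FEATURE_NAMES if not n.startswith("firstorder")]
        for name in texture + ["firstorder_Entropy", "firstorder_Uniformity"]:
            assert a[name] == pytest.approx(b[name], rel=1e-9), name
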