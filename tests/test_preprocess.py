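"""Preprocessing chain: resampling, mask thresholding, bias correction and
TIV normalization, plus whole-chain idempotence."""

import numpy as np
import pytest

from msrad.core import Volume
from msrad.preprocess import (
    correct_bias,
    normalize_tiv,
    preprocess_subject,
    resample_isotropic,
    threshold_masks,
)
from msrad.synthetic import CohortSpec, generate_cohort


class TestResample:
    def test_identity_target_returns_values_unchanged(self):
        v = Volume(np.random.default_rng(0).normal(size=(10, 10, 10)), (1, 1, 1), "T1w")
        out = resample_isotropic(v, (1.0, 1.0, 1.0))
        assert out.data.shape == v.data.shape
        np.testing.assert_allclose(out.data, v.data, atol=1e-9)

    def test_constant_volume_stays_constant(self):
        v = Volume(np.full((9, 9, 9), 3.5), (2.0, 2.0, 2.0), "PD")
        out = resample_isotropic(v, 1.0)
        np.testing.assert_allclose(out.data, 3.5, atol=1e-9)

    def test_linear_ramp_is_exact_under_cubic_splines(self):
        # f(x) = x in mm, sampled at 2 mm, resampled to 1 mm; spline boundary
        # handling decays geometrically, so compare away from the edges
        n = 24
        ramp = np.tile(np.arange(n) * 2.0, (n, n, 1))
        v = Volume(ramp, (2.0, 2.0, 2.0), "T1w")
        out = resample_isotropic(v, 1.0)
        expected = np.arange(out.data.shape[2]) * 1.0
        interior = slice(20, -20)
        np.testing.assert_allclose(
            out.data[12, 12, interior], expected[interior], atol=1e-6
        )

    def test_nonpositive_target_rejected(self):
        v = Volume(np.zeros((8, 8, 8)), (1, 1, 1), "T1w")
        with pytest.raises(ValueError):
            resample_isotropic(v, 0.0)


class TestThresholdMasks:
    def _maps(self, shape=(4, 4, 4)):
        return {t: np.zeros(shape) for t in ("csf", "gm", "nawm", "lesion")}

    def test_boundary_probability_is_included(self):
        maps = self._maps()
        maps["nawm"][0, 0, 0] = 0.90
        maps["gm"][1, 1, 1] = 0.95
        tm = threshold_masks(maps, 0.9)
        assert tm.nawm[0, 0, 0]

    def test_all_subthreshold_probabilities_error(self):
        maps = {t: np.full((4, 4, 4), 0.5) for t in ("csf", "gm", "nawm", "lesion")}
        with pytest.raises(ValueError):
            threshold_masks(maps, 0.9)

    def test_overlap_resolves_to_highest_probability_tissue(self):
        maps = self._maps()
        maps["nawm"][0, 0, 0] = 0.95
        maps["lesion"][0, 0, 0] = 0.97
        maps["nawm"][0, 0, 1] = 0.92
        maps["gm"][1, 1, 1] = 0.95
        tm = threshold_masks(maps, 0.9)
        assert tm.lesion[0, 0, 0] and not tm.nawm[0, 0, 0]
        assert tm.wm[0, 0, 0], "WM composite contains the voxel either way"

    def test_wm_is_union_of_nawm_and_lesion(self, tiny_cohort):
        for s in tiny_cohort:
            np.testing.assert_array_equal(s.masks.wm, s.masks.nawm | s.masks.lesion)
            if s.status == 0:
                np.testing.assert_array_equal(s.masks.wm, s.masks.nawm)


@pytest.fixture(scope="module")
def clean_phantom():
    spec = CohortSpec(n_hcs=2, n_msp=2, channels=("T1w",), grid_shape=(48,) * 3,
                      bias_amplitude=0.0, seed=5)
    s = generate_cohort(spec)[0]
    masks = threshold_masks(s.prob_maps)
    return s.volumes["T1w"], masks.tiv


class TestCorrectBias:
    def test_bias_free_input_nearly_unchanged(self, clean_phantom):
        clean, tiv = clean_phantom
        out = correct_bias(clean, tiv)
        rel = np.abs(out.data[tiv] - clean.data[tiv]) / np.abs(clean.data[tiv])
        assert rel.mean() <= 0.02

    def test_known_smooth_field_removed(self, clean_phantom):
        clean, tiv = clean_phantom
        n = clean.data.shape[0]
        zz, yy, xx = np.meshgrid(*[np.linspace(-1, 1, n)] * 3, indexing="ij")
        field = 1 + 0.2 * (0.5 * zz + 0.3 * yy * xx - 0.4 * xx**2 + 0.2)
        field /= field[tiv].mean()
        biased = Volume(clean.data * field, clean.voxel_size_mm, "T1w")
        out = correct_bias(biased, tiv)
        rel = np.abs(out.data[tiv] - clean.data[tiv]) / np.abs(clean.data[tiv])
        assert rel.mean() <= 0.05

    def test_constant_image_unchanged(self, clean_phantom):
        _, tiv = clean_phantom
        const = Volume(np.full(tiv.shape, 7.0), (1, 1, 1), "T1w")
        out = correct_bias(const, tiv)
        np.testing.assert_allclose(out.data, 7.0, rtol=1e-9)

    def test_tiv_mean_preserved(self, clean_phantom):
        clean, tiv = clean_phantom
        out = correct_bias(clean, tiv)
        assert out.data[tiv].mean() == pytest.approx(clean.data[tiv].mean(), rel=1e-9)

    def test_qmri_channel_rejected(self, clean_phantom):
        _, tiv = clean_phantom
        v = Volume(np.ones(tiv.shape), (1, 1, 1), "MT")
        with pytest.raises(ValueError):
            correct_bias(v, tiv)


class TestNormalize:
    def test_three_point_hand_computation(self):
        data = np.zeros((1, 1, 3))
        data[0, 0] = [1.0, 2.0, 3.0]
        tiv = np.ones((1, 1, 3), dtype=bool)
        out = normalize_tiv(Volume(data, (1, 1, 1), "T1w"), tiv)
        np.testing.assert_allclose(
            out.data[0, 0], [-1.224744871391589, 0.0, 1.224744871391589], atol=1e-12
        )

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        v = Volume(rng.normal(2, 3, size=(6, 6, 6)), (1, 1, 1), "T1w")
        tiv = np.ones(v.data.shape, dtype=bool)
        once = normalize_tiv(v, tiv)
        twice = normalize_tiv(once, tiv)
        np.testing.assert_allclose(once.data, twice.data, atol=1e-9)

    def test_outliers_outside_tiv_do_not_affect_statistics(self):
        rng = np.random.default_rng(2)
        data = rng.normal(5, 2, size=(6, 6, 6))
        tiv = np.zeros(data.shape, dtype=bool)
        tiv[1:5, 1:5, 1:5] = True
        plain = normalize_tiv(Volume(data.copy(), (1, 1, 1), "T1w"), tiv)
        spiked = data.copy()
        spiked[0, 0, 0] = 1e6
        out = normalize_tiv(Volume(spiked, (1, 1, 1), "T1w"), tiv)
        np.testing.assert_allclose(out.data[tiv], plain.data[tiv], atol=1e-9)
        assert out.data[tiv].mean() == pytest.approx(0, abs=1e-9)
        assert out.data[tiv].std() == pytest.approx(1, abs=1e-9)

    def test_zero_variance_errors(self):
        v = Volume(np.ones((4, 4, 4)), (1, 1, 1), "T1w")
        with pytest.raises(ValueError):
            normalize_tiv(v, np.ones((4, 4, 4), dtype=bool))


def test_chain_is_idempotent_after_first_pass(tiny_cohort):
    s = tiny_cohort[0]  # already preprocessed once
    again = preprocess_subject(s)
    diff = np.abs(again.volumes["T1w"].data - s.volumes["T1w"].data)
    assert diff.max() < 1e-6
    tiv = s.masks.tiv
    vals = s.volumes["T1w"].data[tiv]
    assert vals.mean() == pytest.approx(0, abs=1e-9)
    assert vals.std() == pytest.approx(1, abs=1e-9)
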