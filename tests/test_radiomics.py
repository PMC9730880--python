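import math

import numpy as np
import pytest

from conftest import brute_force_glcm, brute_force_glrlm

from hyperrad.imaging import LesionMask, LesionVolume, discretize
from hyperrad.radiomics import (
    DIRECTIONS_3D,
    cooccurrence_matrix,
    extract_all,
    feature_catalog,
    glcm_features,
    glrlm_features,
    intensity_features,
    runlength_matrix,
    shape_features,
)
from hyperrad.synthetic import PhantomParams, generate_lesion_phantom


class TestIntensityFeatures:
    def test_worked_example_one_to_ten(self, unit_grid):
        vol, msk = unit_grid(np.arange(1, 11, dtype=float).reshape(1, 2, 5))
        roi = discretize(vol, msk, bin_width=1.0, anchor=0.0)
        f = intensity_features(vol, msk, roi)
        assert f["hist_percentile10"] == pytest.approx(1.9)
        assert f["hist_RMS"] == pytest.approx(math.sqrt(38.5))
        assert f["hist_energy"] == pytest.approx(385.0)
        assert f["hist_entropy"] == pytest.approx(math.log2(10))
        assert f["hist_median"] == pytest.approx(5.5)

    def test_constant_roi_degenerate(self, unit_grid):
        vol, msk = unit_grid(np.full((1, 2, 2), 2.0))
        roi = discretize(vol, msk, bin_width=1.0, anchor=0.0)
        f = intensity_features(vol, msk, roi)
        assert f["hist_RMS"] == 2.0
        assert f["hist_energy"] == 16.0
        assert f["hist_entropy"] == 0.0
        assert f["hist_percentile10"] == 2.0
        assert f["hist_skewness"] == 0.0 and f["hist_kurtosis"] == 0.0

    def test_entropy_invariant_to_permutation(self, unit_grid):
        rng = np.random.default_rng(7)
        vals = rng.normal(5, 2, 27)
        out = []
        for order in (vals, rng.permutation(vals)):
            vol, msk = unit_grid(order.reshape(3, 3, 3))
            roi = discretize(vol, msk, bin_width=0.5, anchor=0.0)
            out.append(intensity_features(vol, msk, roi)["hist_entropy"])
        assert out[0] == pytest.approx(out[1])

    def test_intensity_scaling_behavior(self, unit_grid):
        rng = np.random.default_rng(3)
        vals = rng.uniform(1, 9, (3, 3, 3))
        feats = []
        for scale in (1.0, 2.0):
            vol, msk = unit_grid(scale * vals)
            roi = discretize(vol, msk, bin_width=0.25, anchor=0.0)
            feats.append(intensity_features(vol, msk, roi))
        assert feats[1]["hist_mean"] == pytest.approx(2 * feats[0]["hist_mean"])
        assert feats[1]["hist_RMS"] == pytest.approx(2 * feats[0]["hist_RMS"])
        assert feats[1]["hist_energy"] == pytest.approx(
            4 * feats[0]["hist_energy"])

    def test_empty_roi_raises(self, unit_grid):
        vol, msk = unit_grid(np.ones((2, 2, 2)), mask=np.zeros((2, 2, 2)))
        roi = discretize(vol, msk, bin_width=1.0, anchor=0.0)
        with pytest.raises(ValueError, match="empty"):
            intensity_features(vol, msk, roi)


class TestShapeFeatures:
    def test_volume_counts_voxels(self):
        m = np.zeros((10, 10, 10), bool)
        m.ravel()[:63] = True
        f = shape_features(LesionMask(m, (2, 2, 2), (0, 0, 0)))
        assert f["shape_volume"] == pytest.approx(504.0)

    def test_digital_ball_sphericity_near_one(self):
        n = 25
        c = (n - 1) / 2
        idx = np.indices((n, n, n))
        ball = ((idx - c) ** 2).sum(0) <= 10**2
        f = shape_features(LesionMask(ball, (1, 1, 1), (0, 0, 0)))
        assert 0.95 <= f["shape_sphericity"] <= 1.02
        assert f["shape_elongation"] == pytest.approx(1.0, abs=0.05)
        assert f["shape_flatness"] == pytest.approx(1.0, abs=0.05)

    def test_two_adjacent_voxels_max_diameter(self):
        m = np.zeros((4, 3, 3), bool)
        m[1, 1, 1] = m[2, 1, 1] = True
        f = shape_features(LesionMask(m, (2, 2, 2), (0, 0, 0)))
        assert f["shape_max_diameter_3d"] == pytest.approx(2.0)

    def test_scaling_leaves_shape_ratios_invariant(self):
        n = 15
        c = (n - 1) / 2
        idx = np.indices((n, n, n))
        ball = ((idx - c) ** 2).sum(0) <= 5**2
        m = LesionMask(ball, (1, 1, 1), (0, 0, 0))
        f = shape_features(m)
        assert f["shape_sphericity"] == pytest.approx(
            shape_features(m)["shape_sphericity"])  # deterministic

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            shape_features(LesionMask(np.zeros((3, 3, 3), bool),
                                      (1, 1, 1), (0, 0, 0)))


class TestGLCM:
    def test_single_slice_worked_example(self, roi_from_bins):
        roi = roi_from_bins([[1, 1], [1, 2]])
        p = cooccurrence_matrix(roi)
        np.testing.assert_allclose(p, [[0.5, 0.25], [0.25, 0.0]])
        f = glcm_features(roi)
        assert f["glcm_joint_entropy"] == pytest.approx(1.5)
        assert f["glcm_contrast"] == pytest.approx(0.5)

    def test_constant_roi(self, roi_from_bins):
        f = glcm_features(roi_from_bins(np.ones((2, 2, 2), int)))
        assert f["glcm_joint_entropy"] == 0.0
        assert f["glcm_contrast"] == 0.0
        assert f["glcm_joint_maximum"] == 1.0

    def test_contrast_invariant_under_bin_shift(self, roi_from_bins):
        rng = np.random.default_rng(5)
        bins = rng.integers(1, 4, (3, 3, 3))
        f1 = glcm_features(roi_from_bins(bins))
        f2 = glcm_features(roi_from_bins(bins + 7))
        assert f1["glcm_contrast"] == pytest.approx(f2["glcm_contrast"])
        assert f1["glcm_dissimilarity"] == pytest.approx(
            f2["glcm_dissimilarity"])

    def test_single_voxel_warns_and_zeroes(self, roi_from_bins):
        with pytest.warns(UserWarning, match="no voxel pairs"):
            f = glcm_features(roi_from_bins([[1]]))
        assert all(v == 0.0 for v in f.values())

    def test_matches_exhaustive_enumeration(self, roi_from_bins):
        rng = np.random.default_rng(11)
        for _ in range(15):
            shape = tuple(rng.integers(1, 5, 3))
            bins = rng.integers(0, 5, shape)  # 0 = out of mask
            if not (bins > 0).any():
                continue
            roi = roi_from_bins(bins)
            from hyperrad.radiomics import _active_directions, _bounding_box

            box = _bounding_box(roi.mask)
            dirs = _active_directions(bins[box].shape)
            expected = brute_force_glcm(bins[box], dirs)
            np.testing.assert_allclose(cooccurrence_matrix(roi), expected,
                                       atol=1e-12)


class TestGLRLM:
    def test_one_dimensional_run_counting(self, roi_from_bins):
        f = glrlm_features(roi_from_bins([1, 1, 2]))
        assert f["glrlm_run_percentage"] == pytest.approx(2 / 3)

    def test_constant_row_single_run(self, roi_from_bins):
        for n in (1, 4, 7):
            f = glrlm_features(roi_from_bins([1] * n))
            assert f["glrlm_run_percentage"] == pytest.approx(1 / n)

    def test_sre_bounded_by_one(self, roi_from_bins):
        rng = np.random.default_rng(2)
        for _ in range(10):
            bins = rng.integers(1, 4, tuple(rng.integers(1, 5, 3)))
            assert glrlm_features(roi_from_bins(bins))["glrlm_sre"] <= 1 + 1e-12

    def test_matches_exhaustive_enumeration(self, roi_from_bins):
        rng = np.random.default_rng(13)
        for _ in range(15):
            shape = tuple(rng.integers(1, 5, 3))
            bins = rng.integers(0, 5, shape)
            if not (bins > 0).any():
                continue
            roi = roi_from_bins(bins)
            from hyperrad.radiomics import _active_directions, _bounding_box

            box = _bounding_box(roi.mask)
            dirs = _active_directions(bins[box].shape)
            expected = brute_force_glrlm(bins[box], dirs)
            R, _ = runlength_matrix(roi)
            np.testing.assert_allclose(R, expected)


@pytest.fixture(scope="module")
def phantom_pair():
    flat = PhantomParams(mean_intensity=50, intensity_sd=5, seed=1)
    spotty = PhantomParams(mean_intensity=50, intensity_sd=5,
                           n_hotspots=4, hotspot_amplitude=60, seed=1)
    return (generate_lesion_phantom(flat, "CT"),
            generate_lesion_phantom(spotty, "CT"))


class TestExtractAll:
    def test_hotspots_raise_histogram_entropy(self, phantom_pair):
        (v0, m0), (v1, m1) = phantom_pair
        f0 = extract_all(v0, v0, m0, m0)
        f1 = extract_all(v1, v1, m1, m1)
        assert f1["ct_hist_entropy"] > f0["ct_hist_entropy"]

    def test_duplicate_ct_as_pet_gives_matching_statistics(self, phantom_pair):
        (v, m), _ = phantom_pair
        f = extract_all(v, v, m, m)
        # identical data: raw-intensity statistics agree exactly,
        # bin-based ones only up to the differing bin widths
        for name in ("hist_mean", "hist_RMS", "hist_percentile10",
                     "shape_volume", "shape_sphericity"):
            assert f[f"ct_{name}"] == pytest.approx(f[f"pet_{name}"])

    def test_deterministic_and_complete(self, phantom_pair):
        (v, m), _ = phantom_pair
        f1 = extract_all(v, v, m, m)
        f2 = extract_all(v, v, m, m)
        assert f1 == f2
        catalog = {c["name"] for c in feature_catalog()}
        assert {k[3:] for k in f1 if k.startswith("ct_")} == catalog
        assert all(np.isfinite(v) for v in f1.values())

    def test_below_volume_filter_rejected(self):
        params = PhantomParams(grid_shape=(16, 16, 16),
                               lesion_radius_mm=(4.5, 4.5, 4.5))
        v, m = generate_lesion_phantom(params, "CT")
        with pytest.raises(ValueError, match="volume filter"):
            extract_all(v, v, m, m)


def test_direction_classes_cover_13_unique_offsets():
    assert len(DIRECTIONS_3D) == 13
    seen = set()
    for d in DIRECTIONS_3D:
        neg = tuple(-x for x in d)
        assert neg not in seen
        seen.add(d)
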