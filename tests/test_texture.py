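import numpy as np
import pytest

from deltarad.texture import (
    CORE_FEATURES,
    discretize,
    extract_all,
    glcm_compute,
    glcm_features,
    global_features,
    glrlm_compute,
    glrlm_features,
    glszm_compute,
    glszm_features,
    ngtdm_compute,
    ngtdm_features,
)

import oracle
from conftest import droi_from_levels, mv_from_array, random_droi


class TestDiscretize:
    def test_fixed_width_anchored_levels(self):
        mv = mv_from_array(np.array([-1000.0, -500.0, 0.0]))
        d = discretize(mv, "fixed_bin_width", 500.0, range_low=-1000.0)
        np.testing.assert_array_equal(d.levels.ravel(), [1, 2, 3])

    def test_constant_roi_fixed_width_is_single_level(self):
        mv = mv_from_array(np.full((2, 2, 2), 40.0))
        d = discretize(mv, "fixed_bin_width", 25.0)
        assert d.ng == 1
        assert (d.levels == 1).all()

    def test_fixed_bin_count_equal_occupancy(self):
        mv = mv_from_array(np.arange(256.0))
        d = discretize(mv, "fixed_bin_count", 8)
        levels = d.levels.ravel()
        assert d.ng == 8
        counts = np.bincount(levels)[1:]
        np.testing.assert_array_equal(counts, [32] * 8)
        # each level holds 32 consecutive values
        for lv in range(1, 9):
            vals = np.flatnonzero(levels == lv)
            assert vals.max() - vals.min() == 31

    def test_constant_roi_fixed_bin_count_errors(self):
        mv = mv_from_array(np.full((2, 2), 7.0))
        with pytest.raises(ValueError, match="zero intensity range"):
            discretize(mv, "fixed_bin_count", 8)


class TestGlobalFeatures:
    def test_symmetric_triple(self):
        fv = global_features(np.array([-100.0, 0.0, 100.0]))
        assert fv["mean"] == 0
        assert fv["median"] == 0
        assert fv["variance"] == pytest.approx(6666.6667, rel=1e-4)

    def test_constant_values_flag_kurtosis(self):
        fv = global_features(np.array([5.0, 5.0, 5.0, 5.0]))
        assert fv["variance"] == 0
        assert fv["robust_mean_absolute_deviation"] == 0
        assert np.isnan(fv["kurtosis"]) and "kurtosis" in fv.flags

    def test_one_to_ten_percentile_and_kurtosis(self):
        # brute-force from the moment definitions: P10 = 1.9 (linear
        # interpolation), kurtosis = m4/m2^2 = 120.8625/8.25^2 = 1.7758
        fv = global_features(np.arange(1.0, 11.0))
        assert fv["percentile10"] == pytest.approx(1.9)
        assert fv["kurtosis"] == pytest.approx(1.77585, rel=1e-4)


class TestGLCM:
    def test_alternating_line(self):
        d = droi_from_levels(np.array([1, 2, 1, 2]))
        g = glcm_compute(d, distance=1, directions=[(0, 0, 1)])
        np.testing.assert_allclose(g.p, [[0, 0.5], [0.5, 0]])
        f = glcm_features(g)
        assert f["contrast"] == pytest.approx(1.0)
        assert f["joint_energy"] == pytest.approx(0.5)
        assert f["joint_entropy"] == pytest.approx(1.0)  # bits
        assert f["maximum_probability"] == pytest.approx(0.5)
        assert f["correlation"] == pytest.approx(-1.0)

    def test_constant_roi_degenerate(self):
        d = droi_from_levels(np.ones((2, 2, 2), dtype=int))
        f = glcm_features(glcm_compute(d))
        assert f["contrast"] == 0
        assert f["cluster_prominence"] == 0
        assert f["joint_energy"] == 1
        assert f["joint_entropy"] == 0
        assert f["maximum_probability"] == 1
        assert f["correlation"] == 1.0 and "correlation" in f.flags

    def test_single_voxel_errors(self):
        d = droi_from_levels(np.array([[[1]]]))
        with pytest.raises(ValueError, match="pair"):
            glcm_compute(d)

    @pytest.mark.parametrize("seed", range(20))
    def test_probabilities_sum_to_one_and_symmetric(self, seed):
        d = random_droi(np.random.default_rng(seed))
        g = glcm_compute(d)
        assert g.p.sum() == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(g.p, g.p.T, atol=1e-12)
        f = glcm_features(g)
        assert f["cluster_prominence"] >= 0
        assert f["contrast"] >= 0
        assert 0 < f["joint_energy"] <= 1


class TestGLRLM:
    def test_three_voxel_line_single_direction(self):
        d = droi_from_levels(np.array([1, 1, 2]))
        r = glrlm_compute(d, directions=[(0, 0, 1)])
        assert r.n_runs == 2
        f = glrlm_features(r)
        assert f["short_run_low_gray_level_emphasis"] == pytest.approx(0.25)
        assert f["long_run_low_gray_level_emphasis"] == pytest.approx(2.125)

    def test_constant_single_direction_closed_form(self):
        n = 5
        d = droi_from_levels(np.ones((1, 1, n), dtype=int))
        f = glrlm_features(glrlm_compute(d, directions=[(0, 0, 1)]))
        assert f["short_run_low_gray_level_emphasis"] == pytest.approx(1 / n**2)
        assert f["long_run_low_gray_level_emphasis"] == pytest.approx(n**2)

    def test_out_of_mask_breaks_runs(self):
        d = droi_from_levels(np.array([1, 1, 0, 1, 1]))
        r = glrlm_compute(d, directions=[(0, 0, 1)])
        assert r.n_runs == 2
        assert r.r[0, 1] == 2  # two runs of length 2


class TestGLSZM:
    def test_three_voxel_line(self):
        d = droi_from_levels(np.array([1, 1, 2]))
        s = glszm_compute(d)
        assert s.n_zones == 2
        f = glszm_features(s)
        assert f["zone_percentage"] == pytest.approx(2 / 3)
        assert f["small_area_emphasis"] == pytest.approx(0.625)
        assert f["large_area_emphasis"] == pytest.approx(2.5)

    def test_no_touching_equal_levels_gives_all_singleton_zones(self):
        # 8 pairwise-distinct levels in a 2x2x2 block: no two equal levels
        # touch, so every zone has size 1 and the zone percentage is 1
        d = droi_from_levels(np.arange(1, 9).reshape(2, 2, 2))
        f = glszm_features(glszm_compute(d))
        assert f["zone_percentage"] == pytest.approx(1.0)

    def test_constant_roi_single_zone(self):
        d = droi_from_levels(np.ones((2, 3, 4), dtype=int))
        f = glszm_features(glszm_compute(d))
        nv = 24
        assert f["zone_percentage"] == pytest.approx(1 / nv)
        assert f["large_area_emphasis"] == pytest.approx(nv**2)

    def test_zone_size_conservation(self):
        rng = np.random.default_rng(5)
        d = random_droi(rng)
        s = glszm_compute(d)
        j = np.arange(1, s.s.shape[1] + 1)
        assert (s.s * j).sum() == d.voxel_count


class TestNGTDM:
    def test_constant_roi_zero_contrast(self):
        d = droi_from_levels(np.ones((2, 2, 2), dtype=int))
        feats = ngtdm_features(ngtdm_compute(d))
        assert feats["ngtdm_contrast"] == 0
        assert feats["coarseness"] > 0

    def test_two_voxel_line_hand_enumeration(self):
        d = droi_from_levels(np.array([1, 2]))
        m = ngtdm_compute(d)
        np.testing.assert_allclose(m.s_i, [1.0, 1.0])  # |1-2| and |2-1|
        np.testing.assert_allclose(m.n_i, [1.0, 1.0])

    def test_isolated_voxel_errors(self):
        levels = np.zeros((1, 1, 3), dtype=int)
        levels[0, 0, 0] = 1
        with pytest.raises(ValueError, match="neighbor"):
            ngtdm_compute(droi_from_levels(levels, ng=1))


class TestOracleEquivalence:
    """All matrix features agree with the naive enumeration oracle."""

    @pytest.mark.parametrize("seed", range(25))
    def test_random_rois_match_brute_force(self, seed):
        rng = np.random.default_rng(1000 + seed)
        d = random_droi(rng)
        lv, ng = d.levels, d.ng

        p_ref = oracle.brute_glcm(lv, ng)
        g = glcm_compute(d)
        np.testing.assert_allclose(g.p, p_ref, atol=1e-12)
        got = glcm_features(g)
        for name, want in oracle.brute_glcm_features(p_ref).items():
            assert got[name] == pytest.approx(want, abs=1e-9), name

        r_ref = oracle.brute_glrlm(lv, ng)
        r = glrlm_compute(d)
        np.testing.assert_allclose(r.r, r_ref)
        got = glrlm_features(r)
        for name, want in oracle.brute_glrlm_features(r_ref).items():
            assert got[name] == pytest.approx(want, abs=1e-9), name

        s_ref = oracle.brute_glszm(lv, ng)
        s = glszm_compute(d)
        got = glszm_features(s)
        for name, want in oracle.brute_glszm_features(s_ref, d.voxel_count).items():
            assert got[name] == pytest.approx(want, abs=1e-9), name

        s_i, n_i = oracle.brute_ngtdm(lv, ng)
        m = ngtdm_compute(d)
        np.testing.assert_allclose(m.s_i, s_i, atol=1e-9)
        np.testing.assert_allclose(m.n_i, n_i, atol=1e-9)


class TestExtractAll:
    def test_heterogeneous_phantom_all_core_features_finite(self):
        rng = np.random.default_rng(0)
        arr = rng.normal(30, 40, size=(6, 10, 10))
        fv = extract_all(mv_from_array(arr), min_voxels=1)
        for name in CORE_FEATURES:
            assert np.isfinite(fv[name]), name
        assert fv.provenance["voxel_count"] == 600

    def test_constant_phantom_flags(self):
        fv = extract_all(mv_from_array(np.full((4, 4, 4), 42.0)), min_voxels=1)
        assert fv["mean"] == 42.0
        assert fv["contrast"] == 0.0
        assert np.isnan(fv["kurtosis"]) and "kurtosis" in fv.flags

    def test_determinism_same_volume(self):
        rng = np.random.default_rng(1)
        arr = rng.normal(0, 50, size=(5, 8, 8))
        f1 = extract_all(mv_from_array(arr), min_voxels=1)
        f2 = extract_all(mv_from_array(arr.copy()), min_voxels=1)
        assert f1.values == f2.values

    def test_translation_invariance(self):
        rng = np.random.default_rng(2)
        core = rng.normal(0, 60, size=(4, 5, 6))
        for shift in [(0, 0, 0), (3, 2, 1)]:
            big = np.full((12, 12, 12), -800.0)
            mask = np.zeros((12, 12, 12), dtype=bool)
            sl = tuple(slice(s, s + n) for s, n in zip(shift, core.shape))
            big[sl] = core
            mask[sl] = True
            fv = extract_all(mv_from_array(big, mask=mask), min_voxels=1)
            if shift == (0, 0, 0):
                ref = fv.values
            else:
                for name in CORE_FEATURES:
                    assert fv[name] == pytest.approx(ref[name], abs=1e-12), name

    def test_intensity_shift_behavior(self):
        rng = np.random.default_rng(3)
        arr = rng.normal(0, 50, size=(5, 8, 8))
        c = 70.0
        base = extract_all(mv_from_array(arr), scheme="fixed_bin_count", param=16,
                           min_voxels=1)
        shifted = extract_all(mv_from_array(arr + c), scheme="fixed_bin_count",
                              param=16, min_voxels=1)
        for name in ("mean", "median", "percentile10"):
            assert shifted[name] == pytest.approx(base[name] + c)
        assert shifted["variance"] == pytest.approx(base["variance"])
        # fixed_bin_count discretization is shift-invariant -> matrix
        # features unchanged
        for name in CORE_FEATURES[6:]:
            assert shifted[name] == pytest.approx(base[name], abs=1e-9), name


class TestMonotoneHeterogeneity:
    def test_contrast_and_entropy_rise_with_noise_amplitude(self):
        from scipy.stats import spearmanr

        amplitudes = [10.0, 25.0, 40.0, 60.0, 80.0]
        mean_contrast, mean_entropy = [], []
        for amp in amplitudes:
            cs, es = [], []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                arr = 30 + amp * rng.standard_normal((5, 10, 10))
                fv = extract_all(mv_from_array(arr), min_voxels=1,
                                 include_ngtdm=False)
                cs.append(fv["contrast"])
                es.append(fv["joint_entropy"])
            mean_contrast.append(np.mean(cs))
            mean_entropy.append(np.mean(es))
        assert spearmanr(amplitudes, mean_contrast).statistic > 0.9
        assert spearmanr(amplitudes, mean_entropy).statistic > 0.9
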