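"""Profile normalization, smoothing, curve features, embedding and clustering."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from peakshape.classify import (
    build_feature_matrix,
    classify_profiles,
    cluster_profiles,
    count_maxima,
    curve_features,
    embed_2d,
    flag_sharp,
    normalize_profile,
    smooth_profile,
)
from peakshape.simulate import ShapeSpec, expected_curve, generate_profile


class TestNormalizeProfile:
    def test_max_min_formula(self):
        np.testing.assert_allclose(normalize_profile([0, 5, 10]), [0, 0.5, 1])

    def test_constant_profile_maps_to_zeros(self):
        np.testing.assert_array_equal(normalize_profile([7, 7, 7]), [0, 0, 0])

    def test_unit_range_input_unchanged(self):
        x = np.array([0.0, 0.25, 1.0, 0.5])
        np.testing.assert_allclose(normalize_profile(x), x)

    def test_amplitude_invariance(self):
        depths, _ = generate_profile(ShapeSpec("unimodal-gaussian", 77, 50, 0.05, 3))
        a = normalize_profile(depths)
        b = normalize_profile(depths * 13)
        np.testing.assert_allclose(a, b)
        assert curve_features(smooth_profile(a)) == curve_features(smooth_profile(b))


class TestSmoothProfile:
    def test_constant_vector_reproduced(self):
        y = np.full(20, 0.4)
        np.testing.assert_allclose(smooth_profile(y), y, atol=1e-12)

    def test_noiseless_gaussian_nearly_interpolated(self):
        y = normalize_profile(expected_curve("unimodal-gaussian", 77, 100.0))
        assert np.abs(smooth_profile(y) - y).max() < 0.02

    def test_larger_factor_underfits_toward_fewer_maxima(self):
        depths, _ = generate_profile(ShapeSpec("bimodal-gaussian", 77, 100, 0.05, 3))
        y = normalize_profile(depths)
        n_default = count_maxima(smooth_profile(y, 1.0))
        n_strong = count_maxima(smooth_profile(y, 10.0))
        n_stronger = count_maxima(smooth_profile(y, 30.0))
        assert n_strong < n_default
        assert n_stronger <= n_strong <= 2

    def test_too_short_profile_returned_unsmoothed_with_warning(self):
        y = np.array([0.0, 1.0, 0.0])
        with pytest.warns(UserWarning, match="too short"):
            out = smooth_profile(y)
        np.testing.assert_array_equal(out, y)

    def test_output_non_negative(self):
        rng = np.random.default_rng(0)
        y = np.clip(rng.normal(0.05, 0.1, 50), 0, None)
        assert smooth_profile(y).min() >= 0


class TestCurveFeatures:
    def test_all_zero_profile(self):
        n = 9
        assert curve_features(np.zeros(n)) == (0, 0.0, float(n - 1))

    def test_triangle_geometry(self):
        n_max, auc, arc = curve_features(np.array([0.0, 1.0, 0.0]))
        assert n_max == 1
        assert auc == pytest.approx(1.0)
        assert arc == pytest.approx(2 * np.sqrt(2))

    def test_two_separated_spikes(self):
        assert count_maxima(np.array([0, 1, 0, 0, 1, 0.0])) == 2

    def test_plateau_run_counts_once(self):
        assert count_maxima(np.array([0, 1, 1, 1, 0.0])) == 1

    def test_boundary_maximum_eligible(self):
        assert count_maxima(np.linspace(0, 1, 12)) == 1


class TestBuildFeatureMatrix:
    def test_dimensions(self):
        profiles = [np.linspace(0, 1, 77) for _ in range(10)]
        assert build_feature_matrix(profiles).shape == (10, 80)

    def test_feature_columns_standardized(self):
        rng = np.random.default_rng(2)
        profiles = [normalize_profile(rng.poisson(20, 50)) for _ in range(25)]
        matrix = build_feature_matrix(profiles)
        np.testing.assert_allclose(matrix[:, -3:].mean(axis=0), 0, atol=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        profiles = [normalize_profile(rng.poisson(20, 40)) for _ in range(12)]
        matrix = build_feature_matrix(profiles)
        perm = rng.permutation(12)
        permuted = build_feature_matrix([profiles[i] for i in perm])
        np.testing.assert_allclose(permuted, matrix[perm])

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="unequal"):
            build_feature_matrix([np.zeros(5), np.zeros(6)])


class TestEmbed2D:
    def test_same_seed_gives_identical_coordinates(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 20))
        np.testing.assert_array_equal(embed_2d(X, seed=11), embed_2d(X, seed=11))

    def test_duplicate_rows_land_close(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 15))
        X[7] = X[3]
        coords = embed_2d(X, seed=0)
        spread = np.linalg.norm(coords - coords.mean(axis=0), axis=1).mean()
        assert np.linalg.norm(coords[7] - coords[3]) < 0.25 * spread

    def test_separated_families_stay_separated(self):
        rng = np.random.default_rng(6)
        sharp = np.exp(-0.5 * ((np.arange(50) - 25) / 2.0) ** 2)
        flat = np.full(50, 0.5)
        X = np.vstack(
            [sharp + rng.normal(0, 0.01, 50) for _ in range(25)]
            + [flat + rng.normal(0, 0.01, 50) for _ in range(25)]
        )
        coords = embed_2d(X, seed=1)
        centroid_a, centroid_b = coords[:25].mean(axis=0), coords[25:].mean(axis=0)
        within = np.mean(
            [
                np.linalg.norm(coords[:25] - centroid_a, axis=1).mean(),
                np.linalg.norm(coords[25:] - centroid_b, axis=1).mean(),
            ]
        )
        assert np.linalg.norm(centroid_a - centroid_b) > within

    def test_tiny_input_falls_back_to_pca(self):
        X = np.random.default_rng(7).normal(size=(4, 10))
        with pytest.warns(UserWarning, match="PCA"):
            coords = embed_2d(X, seed=0)
        assert coords.shape == (4, 2)


class TestClusterProfiles:
    @staticmethod
    def _blobs(c, per=25, spread=0.05, seed=0):
        rng = np.random.default_rng(seed)
        angles = 2 * np.pi * np.arange(c) / c
        centers = 10 * np.column_stack([np.cos(angles), np.sin(angles)])
        coords = np.vstack(
            [center + rng.normal(0, spread, size=(per, 2)) for center in centers]
        )
        labels = np.repeat(np.arange(c), per)
        return coords, labels

    def test_recovers_four_tight_blobs(self):
        coords, truth = self._blobs(4)
        result = cluster_profiles(coords, k_max=10, seed=0)
        assert result.k == 4
        assert adjusted_rand_score(truth, result.labels) == 1.0

    @pytest.mark.parametrize("c", [2, 3, 5])
    def test_k_selection_matches_blob_count(self, c):
        coords, _ = self._blobs(c, seed=c)
        assert cluster_profiles(coords, k_max=10, seed=0).k == c

    def test_forced_k_overrides_selection(self):
        coords, _ = self._blobs(5, seed=1)
        result = cluster_profiles(coords, k_forced=3, seed=0)
        assert result.forced and result.k == 3
        assert set(result.labels) == {1, 2, 3}

    def test_n_equals_k_puts_one_point_per_cluster(self):
        coords = np.array([[0.0, 0], [5, 5], [-4, 2], [3, -6]])
        result = cluster_profiles(coords, k_forced=4, seed=0)
        assert sorted(result.labels) == [1, 2, 3, 4]
        # WSS of singleton clusters is zero
        wss = sum(
            np.sum((coords[result.labels == c] - coords[result.labels == c].mean(0)) ** 2)
            for c in (1, 2, 3, 4)
        )
        assert wss == 0.0

    def test_k_larger_than_n_is_error(self):
        with pytest.raises(ValueError):
            cluster_profiles(np.zeros((3, 2)), k_forced=5)

    def test_wss_curve_non_increasing(self):
        coords, _ = self._blobs(3, spread=1.0, seed=9)
        result = cluster_profiles(coords, k_max=8, seed=0)
        wss = [result.wss_by_k[k] for k in sorted(result.wss_by_k)]
        assert all(a >= b - 1e-9 for a, b in zip(wss, wss[1:]))


class TestFlagSharp:
    def test_single_cluster_is_never_sharp(self):
        labels = np.ones(10, dtype=int)
        cvs = np.linspace(0.1, 2.0, 10)
        peak_sharp, cluster_sharp = flag_sharp(labels, cvs)
        assert not cluster_sharp[1]
        assert not peak_sharp.any()

    def test_high_cv_cluster_and_members_flagged(self):
        labels = np.array([1] * 10 + [2] * 10)
        cvs = np.array([0.05] * 10 + [1.0] * 10)
        peak_sharp, cluster_sharp = flag_sharp(labels, cvs)
        assert cluster_sharp == {1: False, 2: True}
        assert peak_sharp[10:].all() and not peak_sharp[:10].any()

    def test_low_cv_peak_in_sharp_cluster_stays_broad(self):
        labels = np.array([1] * 10 + [2] * 10)
        cvs = np.array([0.05] * 10 + [0.1] + [1.0] * 9)
        peak_sharp, cluster_sharp = flag_sharp(labels, cvs)
        assert cluster_sharp[2]
        assert not peak_sharp[10]  # CV 0.1 fails the CV > 0.2 requirement
        assert peak_sharp[11:].all()


class TestClassifyProfiles:
    def test_duplicate_profiles_share_a_cluster(self):
        rng = np.random.default_rng(8)
        profiles = [
            np.rint(expected_curve("unimodal-gaussian", 50, 40.0)) for _ in range(6)
        ] + [np.rint(expected_curve("plateau", 50, 40.0)) for _ in range(6)]
        assignments, result, _, _ = classify_profiles(
            profiles, smoothing=True, k_forced=2, seed=0
        )
        first_six = {a.cluster for a in assignments[:6]}
        last_six = {a.cluster for a in assignments[6:]}
        assert len(first_six) == 1 and len(last_six) == 1
        assert first_six != last_six
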