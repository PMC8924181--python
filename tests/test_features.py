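"""Histogram features, quantization, and co-occurrence texture features."""

import numpy as np
import pytest

import wmlseg as w
from wmlseg.detection import LesionCandidate
from wmlseg.features import (QuantizedPatch, compute_glcm, extract_features,
                             glcm_features, histogram_features, kmeans_quantize,
                             orientation_offset, quantile_quantize)

FULL = np.ones((4, 4), bool)


class TestHistogramFeatures:
    def test_constant_patch_degenerate_conventions(self):
        h = histogram_features(np.full((4, 4), 7.0), FULL)
        assert h.variance == 0 and h.energy == 1 and h.entropy == 0
        assert h.skewness == 0 and h.kurtosis == 0
        assert h.mean == 7.0

    def test_two_equiprobable_levels_closed_form(self):
        patch = np.array([[0.0, 6.0], [6.0, 0.0]])
        h = histogram_features(patch, np.ones((2, 2), bool))
        assert h.mean == pytest.approx(3.0)
        assert h.entropy == pytest.approx(1.0)     # one bit
        assert h.energy == pytest.approx(0.5)
        assert h.variance == pytest.approx(9.0)
        assert h.skewness == pytest.approx(0.0, abs=1e-12)
        assert h.kurtosis == pytest.approx(1.0)    # two-point distribution

    def test_moment_oracle_on_gaussian_draws(self):
        gen = np.random.default_rng(42)
        vals = np.rint(gen.normal(4000, 300, 100_000))
        h = histogram_features(vals.reshape(250, 400), np.ones((250, 400), bool))
        assert abs(h.skewness) < 0.05
        assert h.kurtosis == pytest.approx(3.0, abs=0.1)
        assert h.mean == pytest.approx(vals.mean())
        assert h.variance == pytest.approx(vals.var(), rel=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            histogram_features(np.zeros((3, 3)), np.zeros((3, 3), bool))


class TestQuantization:
    def test_exact_reconstruction_at_distinct_count(self):
        patch = np.array([[10.0, 20.0], [30.0, 20.0]])
        q = kmeans_quantize(patch, np.ones((2, 2), bool), L_clusters=3)
        assert np.array_equal(q.centers, [10, 20, 30])
        assert np.array_equal(q.reconstruct(), patch)

    def test_determinism(self, rng):
        patch = rng.integers(0, 8192, (12, 12)).astype(float)
        a = kmeans_quantize(patch, None, 5, seed=1)
        b = kmeans_quantize(patch, None, 5, seed=1)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.centers, b.centers)

    def test_two_tight_blobs_split_cleanly(self, rng):
        patch = np.where(rng.random((10, 10)) > 0.5,
                         rng.normal(1000, 5, (10, 10)),
                         rng.normal(7000, 5, (10, 10)))
        q = kmeans_quantize(patch, None, 2)
        assert np.all(q.labels[patch < 4000] == 0)
        assert np.all(q.labels[patch > 4000] == 1)

    def test_quantization_error_nonincreasing_in_L(self, rng):
        patch = rng.normal(4000, 800, (16, 16))
        errs = []
        for L in range(1, 8):
            q = kmeans_quantize(patch, None, L)
            errs.append(float(((q.reconstruct() - patch) ** 2).mean()))
        assert all(b <= a + 1e-9 for a, b in zip(errs, errs[1:]))

    def test_cluster_count_reduced_with_warning_on_few_distinct(self):
        patch = np.array([[1.0, 1.0, 2.0, 2.0]] * 4)
        q = kmeans_quantize(patch, None, L_clusters=4)
        assert q.L_clusters == 2

    def test_quantile_uniform_ramp_equal_bins(self):
        patch = np.arange(8192, dtype=float).reshape(64, 128)
        q = quantile_quantize(patch, None, 4)
        counts = np.bincount(q.labels.ravel())
        assert np.array_equal(counts, [2048, 2048, 2048, 2048])

    def test_quantile_constant_and_single_bin(self, rng):
        assert np.all(quantile_quantize(np.full((3, 3), 5.0), None, 4).labels == 0)
        patch = rng.random((5, 5))
        assert np.all(quantile_quantize(patch, None, 1).labels == 0)
        assert np.all(kmeans_quantize(patch, None, 1).labels == 0)


class TestGLCM:
    def test_two_by_two_worked_example(self):
        q = QuantizedPatch(np.array([[0, 0], [1, 1]]), np.array([0.0, 1.0]), 2, "manual")
        g = compute_glcm(q, orientation_offset(0), 0)
        expected = np.array([[0.5, 0.0], [0.0, 0.5]])
        assert np.allclose(g.probabilities, expected, atol=1e-15)
        f = glcm_features(g)
        assert f.contrast == pytest.approx(0.0)
        assert f.energy == pytest.approx(0.5)
        assert f.homogeneity == pytest.approx(1.0)
        assert f.correlation == pytest.approx(1.0)

    def test_constant_patch_single_cell(self):
        q = QuantizedPatch(np.zeros((3, 3), int), np.array([5.0]), 1, "manual")
        g = compute_glcm(q, (0, 1))
        assert g.probabilities[0, 0] == pytest.approx(1.0)

    @pytest.mark.parametrize("theta", [0, 45, 90, 135])
    def test_probability_mass_one_for_every_orientation_and_mask(self, rng, theta):
        for _ in range(5):
            labels = rng.integers(0, 5, (9, 9))
            mask = rng.random((9, 9)) > 0.3
            labels = np.where(mask, labels, -1)
            q = QuantizedPatch(labels, np.arange(5, dtype=float), 5, "manual")
            try:
                g = compute_glcm(q, orientation_offset(theta), theta)
            except ValueError:
                continue  # masks can leave no valid pair
            assert g.probabilities.sum() == pytest.approx(1.0, abs=1e-12)
            assert g.counts.sum() > 0

    def test_full_mask_normalizer_matches_formula(self, rng):
        labels = rng.integers(0, 4, (7, 11))
        q = QuantizedPatch(labels, np.arange(4, dtype=float), 4, "manual")
        g = compute_glcm(q, (0, 1))
        assert g.counts.sum() == 7 * (11 - 1)
        g = compute_glcm(q, (-1, 0))
        assert g.counts.sum() == (7 - 1) * 11

    def test_offset_larger_than_patch_rejected(self):
        q = QuantizedPatch(np.zeros((2, 2), int), np.array([0.0]), 1, "manual")
        with pytest.raises(ValueError):
            compute_glcm(q, (0, 2))


class TestGLCMFeatures:
    def test_diagonal_glcm_zero_contrast_full_homogeneity(self):
        P = np.diag([0.25, 0.5, 0.25])
        g = w.features.GLCM(np.rint(P * 4).astype(int), P, (0, 1), 0, (3, 3))
        f = glcm_features(g)
        assert f.contrast == 0 and f.homogeneity == pytest.approx(1.0)

    def test_uniform_glcm_energy_closed_form(self):
        for K in (2, 3, 5):
            P = np.full((K, K), 1.0 / K**2)
            g = w.features.GLCM((P * K**2).astype(int), P, (0, 1), 0, (K, K))
            assert glcm_features(g).energy == pytest.approx(1.0 / K**2)
            assert glcm_features(g).correlation == pytest.approx(0.0, abs=1e-12)

    def test_contrast_invariant_under_label_shift(self, rng):
        labels = rng.integers(0, 4, (8, 8))
        q1 = QuantizedPatch(labels, np.arange(4, dtype=float), 4, "manual")
        q2 = QuantizedPatch(labels + 2, np.arange(6, dtype=float), 6, "manual")
        f1 = glcm_features(compute_glcm(q1, (0, 1)))
        f2 = glcm_features(compute_glcm(q2, (0, 1)))
        assert f1.contrast == pytest.approx(f2.contrast, rel=1e-12)
        assert f1.correlation == pytest.approx(f2.correlation, rel=1e-9)


def _candidate_from_patch(patch, rng=None):
    patch = np.asarray(patch, dtype=np.int64)
    mask = np.ones(patch.shape, bool)
    return LesionCandidate(0, 0, (0, 0) + patch.shape, patch, mask,
                           np.ones(patch.shape, bool), (0, 0),
                           int(mask.sum()))


class TestExtractFeatures:
    def test_constant_candidate_degenerate_features(self):
        f = extract_features(_candidate_from_patch(np.full((6, 6), 900)))
        assert f.histogram.energy == 1.0
        assert f.glcm.contrast == 0.0

    def test_vector_has_ten_finite_entries(self, rng):
        patch = rng.integers(500, 8000, (10, 10))
        vec = extract_features(_candidate_from_patch(patch)).as_vector()
        assert vec.shape == (10,) and np.all(np.isfinite(vec))

    def test_deterministic_recomputation_from_saved_patch(self, rng):
        patch = rng.integers(500, 8000, (9, 9))
        a = extract_features(_candidate_from_patch(patch), seed=5).as_vector()
        b = extract_features(_candidate_from_patch(patch.copy()), seed=5).as_vector()
        assert np.array_equal(a, b)

    def test_mask_scope_differs_from_patch_scope(self, rng):
        patch = rng.integers(500, 8000, (9, 9)).astype(np.int64)
        cand = _candidate_from_patch(patch)
        cand.mask = np.zeros((9, 9), bool)
        cand.mask[3:6, 3:6] = True
        cand.area_px = 9
        full = extract_features(cand, glcm_scope="patch").as_vector()
        masked = extract_features(cand, glcm_scope="mask").as_vector()
        assert not np.array_equal(full[6:], masked[6:])
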