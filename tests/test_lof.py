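"""Local Outlier Factor chain against an independent brute-force oracle."""

import numpy as np
import pytest

import wmlseg as w
from wmlseg.detection import LesionCandidate
from wmlseg.lof import (LRD_CAP, LOFModel, fit_lof_model, k_distance,
                        local_reachability_density, lof_score, reach_dist,
                        refine_boundary)

# ---------------------------------------------------------------------------
# Brute-force oracle: a deliberately naive O(n^2) coding of the LOF chain,
# sharing only the convention that one coincident reference point is the
# query's own copy.
# ---------------------------------------------------------------------------

def brute_kdist(o, ref, k):
    d = sorted(abs(float(r) - float(o)) for r in ref)
    if d and d[0] == 0.0:
        d = d[1:]
    return d[k - 1]


def brute_neighborhood(o, ref, k):
    kd = brute_kdist(o, ref, k)
    neigh = [float(r) for r in ref if abs(float(r) - float(o)) <= kd]
    for i, r in enumerate(neigh):
        if r == float(o):
            del neigh[i]
            break
    return neigh


def brute_lrd(o, ref, k):
    neigh = brute_neighborhood(o, ref, k)
    reach = [max(brute_kdist(p, ref, k), abs(float(o) - p)) for p in neigh]
    mean = sum(reach) / len(reach)
    if mean == 0:
        return LRD_CAP
    return min(1.0 / mean, LRD_CAP)


def brute_lof(o, ref, k):
    neigh = brute_neighborhood(o, ref, k)
    lo = brute_lrd(o, ref, k)
    return sum(brute_lrd(p, ref, k) / lo for p in neigh) / len(neigh)


class TestKDistance:
    def test_coincident_query_excluded_once(self):
        assert k_distance(0.0, [0.0, 1.0, 2.0, 3.0], 1) == 1.0

    def test_query_among_duplicates(self):
        # k duplicates beside the query's own copy: k-distance is 0
        ref = [5.0, 5.0, 5.0, 9.0]
        assert k_distance(5.0, ref, 2) == 0.0

    def test_metric_homogeneity_under_scaling(self, rng):
        ref = rng.normal(0, 10, 50)
        o = 3.7
        for c in (2.0, 0.5, 10.0):
            assert k_distance(c * o, c * ref, 5) == pytest.approx(
                c * k_distance(o, ref, 5), rel=1e-12)

    def test_k_beyond_reference_rejected(self):
        with pytest.raises(ValueError):
            k_distance(0.0, [1.0, 2.0], 5)


class TestReachDist:
    def test_max_contract(self):
        ref = [0.0, 10.0, 20.0]
        assert reach_dist(11.0, 10.0, ref, 1) == 10.0  # max(kdist=10, d=1)
        assert reach_dist(50.0, 10.0, ref, 1) == 40.0  # d dominates

    def test_inside_neighborhood_returns_kdistance(self):
        ref = [0.0, 5.0, 6.0]
        kd = k_distance(5.0, ref, 2)  # distances {1, 5} -> 5
        assert reach_dist(5.5, 5.0, ref, 2) == kd


class TestLRD:
    def test_lattice_reciprocal_spacing_at_k1(self):
        ref = np.arange(50, dtype=float) * 2.0  # spacing 2
        assert local_reachability_density(24.0, ref, 1) == pytest.approx(0.5)

    def test_lattice_reciprocal_kdistance_general_k(self):
        ref = np.arange(50, dtype=float)
        for k in (1, 2, 3, 4):
            kd = k_distance(25.0, ref, k)
            assert local_reachability_density(25.0, ref, k) == pytest.approx(1 / kd)

    def test_duplicate_heavy_reference_caps(self):
        ref = [3.0] * 10 + [9.0]
        assert local_reachability_density(3.0, ref, 2) == LRD_CAP

    def test_decreases_away_from_reference_mass(self, rng):
        ref = np.sort(rng.normal(0, 1, 200))
        lrds = [local_reachability_density(x, ref, 10) for x in (0.0, 2.0, 5.0, 20.0)]
        assert all(b < a for a, b in zip(lrds, lrds[1:]))


class TestLOFScore:
    def test_uniform_interior_near_one(self):
        ref = np.arange(200, dtype=float)
        assert lof_score(100.0, ref, 5) == pytest.approx(1.0, abs=0.05)
        assert lof_score(100.5, ref, 5) == pytest.approx(1.0, abs=0.25)

    def test_far_outlier_scores_much_greater_than_ten(self, rng):
        cluster = rng.normal(0, 0.05, 100)  # spread ~0.05, point at 5 = 100x
        assert lof_score(5.0, cluster, 2) > 10

    @pytest.mark.parametrize("seed", range(10))
    def test_brute_force_oracle_equivalence(self, seed):
        gen = np.random.default_rng(seed)
        n = int(gen.integers(30, 500))
        ref = gen.normal(0, 100, n)
        if seed % 3 == 0:
            ref = np.rint(ref)  # integer-valued: exercise ties/duplicates
        queries = np.concatenate([
            gen.choice(ref, 3),                   # coincident queries
            gen.normal(0, 150, 5),                # interior / tail queries
            [ref.max() + 500.0],                  # far outlier
        ])
        k = int(gen.integers(2, 12))
        for o in queries:
            assert lof_score(float(o), ref, k) == pytest.approx(
                brute_lof(float(o), ref, k), abs=1e-9)

    def test_shift_and_scale_invariance(self, rng):
        ref = rng.normal(50, 5, 150)
        o = 61.0
        base = lof_score(o, ref, 8)
        assert lof_score(o + 1000, ref + 1000, 8) == pytest.approx(base, rel=1e-9)
        assert lof_score(o * 3, ref * 3, 8) == pytest.approx(base, rel=1e-9)

    def test_sklearn_cross_check_on_novel_queries(self, rng):
        from sklearn.neighbors import LocalOutlierFactor

        ref = rng.normal(0, 10, 300)
        queries = rng.normal(0, 25, 20)
        queries = queries[np.all(queries[:, None] != ref[None, :], axis=1)]
        k = 15
        skl = LocalOutlierFactor(n_neighbors=k, novelty=True).fit(ref[:, None])
        expected = -skl.score_samples(queries[:, None])
        ours = [lof_score(float(q), ref, k) for q in queries]
        assert ours == pytest.approx(expected, rel=1e-9)


class TestLOFModel:
    def test_fast_path_matches_scalar_chain(self, rng):
        ref = np.rint(rng.normal(4000, 300, 400))
        model = LOFModel(ref, min_pts=12)
        queries = np.concatenate([rng.choice(ref, 5), rng.normal(4000, 900, 10)])
        fast = model.score(queries)
        slow = [lof_score(float(q), model.reference, 12) for q in queries]
        assert fast == pytest.approx(slow, rel=1e-12)

    def test_stratified_downsampling_is_seeded_and_bounded(self, rng):
        vals = rng.normal(0, 1, 5000)
        a = fit_lof_model(vals, max_reference=500, seed=4)
        b = fit_lof_model(vals, max_reference=500, seed=4)
        assert a.reference.size == 500
        assert np.array_equal(a.reference, b.reference)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            LOFModel(np.array([1.0]), min_pts=1)
        with pytest.raises(ValueError):
            LOFModel(np.arange(10.0), min_pts=10)


def _candidate(patch, brain=None):
    patch = np.asarray(patch, dtype=np.int64)
    brain = np.ones(patch.shape, bool) if brain is None else brain
    return LesionCandidate(0, 0, (0, 0) + patch.shape, patch,
                           np.ones(patch.shape, bool), brain, (0, 0),
                           patch.size)


class TestRefineBoundary:
    def test_reference_drawn_patch_fully_kept(self, rng):
        ref = np.rint(rng.normal(5000, 200, 2000))
        model = fit_lof_model(ref, min_pts=20, threshold=1.5)
        patch = rng.choice(ref, (8, 8))
        out = refine_boundary(_candidate(patch), model)
        assert out.refined_mask.all() and not out.dropped

    def test_bimodal_patch_keeps_reference_half(self, rng):
        ref = np.rint(rng.normal(5000, 100, 2000))
        model = fit_lof_model(ref, min_pts=20, threshold=1.5)
        patch = np.empty((10, 10))
        left = rng.choice(ref, (10, 5))
        patch[:, :5] = left
        patch[:, 5:] = 0.0  # 50 sigma away
        out = refine_boundary(_candidate(patch), model)
        expected = np.zeros((10, 10), bool)
        expected[:, :5] = True
        agreement = (out.refined_mask == expected).mean()
        assert agreement >= 0.95

    def test_infinite_threshold_keeps_whole_patch(self, rng):
        ref = np.rint(rng.normal(5000, 100, 500))
        model = fit_lof_model(ref, min_pts=10)
        patch = rng.integers(0, 9000, (6, 6))
        out = refine_boundary(_candidate(patch), model, threshold=np.inf)
        assert out.refined_mask.all()

    def test_monotone_in_threshold(self, rng):
        ref = np.rint(rng.normal(5000, 100, 1000))
        model = fit_lof_model(ref, min_pts=10)
        patch = rng.integers(3000, 7000, (8, 8))
        prev = None
        for tau in (1.0, 1.5, 3.0, 10.0):
            cur = refine_boundary(_candidate(patch), model, threshold=tau).refined_mask
            if prev is not None:
                assert np.all(prev <= cur)
            prev = cur

    def test_brain_mask_restricts_refinement(self, rng):
        ref = np.rint(rng.normal(5000, 100, 500))
        model = fit_lof_model(ref, min_pts=10)
        patch = rng.choice(ref, (6, 6))
        brain = np.zeros((6, 6), bool)
        brain[:3] = True
        out = refine_boundary(_candidate(patch, brain), model)
        assert not out.refined_mask[3:].any()
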