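"""Local Outlier Factor boundary refinement.

After the forest accepts a candidate, its boundary is re-drawn voxel by
voxel: every voxel in the candidate patch is scored with the Local Outlier
Factor (Breunig et al.) against a reference set of standardized lesion
intensities collected from the training ground truth ("the WML intensity
model"). Voxels whose LOF stays at or below a threshold tau are density
inliers of that model — their intensity sits inside the lesion intensity
distribution — and form the refined mask; background voxels fall in the
sparse outskirts of the model and score well above 1.

The feature space is the scalar standardized intensity with |a - b| distance
(an optional 3-feature variant adds the 3x3 local mean and std). The LOF
chain is the classical one:

* ``k-distance(o)``: distance to the k-th nearest reference intensity. One
  coincident (distance-0) reference point is treated as the query's own copy
  and excluded, so a reference member scores against the *other* members as
  in the original in-dataset definition.
* ``reach-dist_k(p, o) = max(k-distance(o), d(p, o))``.
* ``lrd(o)``: reciprocal mean reach-dist from ``o`` to its neighborhood
  (every reference point within k-distance — ties may make it larger than k).
* ``LOF(o)``: mean of ``lrd(p) / lrd(o)`` over the neighborhood; about 1
  inside uniform density, well above 1 far outside it.

A duplicate-heavy reference can drive all reach-dists to 0; the reciprocal is
then capped at ``LRD_CAP`` so ratios of two capped densities stay at 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .detection import LesionCandidate

__all__ = [
    "LOFModel",
    "VoxelLOFScores",
    "LRD_CAP",
    "k_distance",
    "reach_dist",
    "local_reachability_density",
    "lof_score",
    "fit_lof_model",
    "refine_boundary",
]

log = logging.getLogger(__name__)

LRD_CAP = 1e12


def _distances(o: float, ref: np.ndarray, exclude_coincident: bool) -> np.ndarray:
    d = np.abs(np.asarray(ref, dtype=float) - float(o))
    if exclude_coincident:
        zero = np.flatnonzero(d == 0)
        if zero.size:
            d = np.delete(d, zero[0])  # drop one copy: the query itself
    return d


def k_distance(o: float, ref, k: int, exclude_coincident: bool = True) -> float:
    """Distance from ``o`` to the k-th nearest reference intensity."""
    d = _distances(o, ref, exclude_coincident)
    if not 1 <= k <= d.size:
        raise ValueError(f"k={k} outside [1, {d.size}]")
    return float(np.partition(d, k - 1)[k - 1])


def reach_dist(p: float, o: float, ref, k: int) -> float:
    """max(k-distance(o), d(p, o))."""
    return max(k_distance(o, ref, k), abs(float(p) - float(o)))


def _neighborhood(o: float, ref: np.ndarray, k: int) -> np.ndarray:
    """Reference points within k-distance of ``o`` (one coincident copy dropped)."""
    ref = np.asarray(ref, dtype=float)
    d = np.abs(ref - float(o))
    kd = k_distance(o, ref, k)
    idx = np.flatnonzero(d <= kd)
    zero = np.flatnonzero(d[idx] == 0)
    if zero.size:
        idx = np.delete(idx, zero[0])
    return ref[idx]


def local_reachability_density(o: float, ref, min_pts: int) -> float:
    """Reciprocal mean reach-dist from ``o`` to its MinPts-neighborhood."""
    neigh = _neighborhood(o, ref, min_pts)
    reach = np.array([reach_dist(o, p, ref, min_pts) for p in neigh])
    mean_reach = reach.mean()
    if mean_reach == 0:
        return LRD_CAP
    return min(1.0 / mean_reach, LRD_CAP)


def lof_score(o: float, ref, min_pts: int) -> float:
    """Mean lrd(p) / lrd(o) over o's MinPts-neighborhood."""
    neigh = _neighborhood(o, ref, min_pts)
    lrd_o = local_reachability_density(o, ref, min_pts)
    lrd_p = np.array([local_reachability_density(p, ref, min_pts) for p in neigh])
    return float((lrd_p / lrd_o).mean())


# ---------------------------------------------------------------------------
# Fitted model with fast 1-D scoring
# ---------------------------------------------------------------------------

@dataclass
class LOFModel:
    """Sorted reference intensities with precomputed densities.

    ``reference`` holds (a stratified subsample of) the standardized lesion
    intensities from training ground truth; ``min_pts`` the neighborhood size
    and ``threshold`` the inlier cut tau.
    """

    reference: np.ndarray
    min_pts: int = 20
    threshold: float = 1.5
    _ref_kdist: np.ndarray = field(default=None, repr=False)
    _ref_lrd: np.ndarray = field(default=None, repr=False)

    def __post_init__(self) -> None:
        ref = np.sort(np.asarray(self.reference, dtype=float).ravel())
        if ref.size < 2:
            raise ValueError("reference set must hold at least 2 intensities")
        if not 1 <= self.min_pts <= ref.size - 1:
            raise ValueError("min_pts must be in [1, len(reference) - 1]")
        if self.threshold < 0:
            raise ValueError("threshold must be non-negative")
        self.reference = ref
        self._ref_kdist = self._all_kdistances(ref, self.min_pts)
        self._ref_lrd = self._all_lrd(ref, self._ref_kdist)

    @staticmethod
    def _all_kdistances(ref: np.ndarray, k: int) -> np.ndarray:
        """k-distance of every reference point to the other reference points.

        In sorted order the k nearest other points lie within k positions on
        either side, so a (n, 2k) lagged-difference window suffices.
        """
        n = ref.size
        d = np.full((n, 2 * k), np.inf)
        for j in range(1, k + 1):
            lag = ref[j:] - ref[:-j]
            d[j:, j - 1] = lag        # j-th neighbor to the left
            d[:-j, k + j - 1] = lag   # j-th neighbor to the right
        return np.partition(d, k - 1, axis=1)[:, k - 1]

    def _all_lrd(self, ref: np.ndarray, kdist: np.ndarray) -> np.ndarray:
        n = ref.size
        lrd = np.empty(n)
        for i in range(n):
            kd = kdist[i]
            lo = np.searchsorted(ref, ref[i] - kd, side="left")
            hi = np.searchsorted(ref, ref[i] + kd, side="right")
            idx = np.arange(lo, hi)
            idx = idx[idx != i]  # drop the point's own copy, keep duplicates
            reach = np.maximum(kdist[idx], np.abs(ref[idx] - ref[i]))
            mean_reach = reach.mean()
            lrd[i] = LRD_CAP if mean_reach == 0 else min(1.0 / mean_reach, LRD_CAP)
        return lrd

    def score(self, values: np.ndarray) -> np.ndarray:
        """LOF of each value against the reference model."""
        flat = np.asarray(values, dtype=float).ravel()
        out = np.array([self._score_one(v) for v in flat])
        return out.reshape(np.shape(values))

    def _score_one(self, o: float) -> float:
        ref = self.reference
        d = np.abs(ref - o)
        kd = k_distance(o, ref, self.min_pts)
        idx = np.flatnonzero(d <= kd)
        zero = np.flatnonzero(d[idx] == 0)
        if zero.size:
            idx = np.delete(idx, zero[0])
        reach = np.maximum(self._ref_kdist[idx], d[idx])
        mean_reach = reach.mean()
        lrd_o = LRD_CAP if mean_reach == 0 else min(1.0 / mean_reach, LRD_CAP)
        return float((self._ref_lrd[idx] / lrd_o).mean())


def _stratified_subsample(values: np.ndarray, n_max: int, seed: int) -> np.ndarray:
    """Seeded stratified downsampling: one draw per sorted stratum."""
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if v.size <= n_max:
        return v
    rng = np.random.default_rng(seed)
    edges = np.linspace(0, v.size, n_max + 1).astype(int)
    picks = [rng.integers(lo, hi) for lo, hi in zip(edges[:-1], edges[1:])]
    return v[np.array(picks)]


def fit_lof_model(
    reference_intensities,
    min_pts: int = 20,
    threshold: float = 1.5,
    max_reference: int = 10000,
    seed: int = 0,
) -> LOFModel:
    """Build the WML intensity model from training lesion voxels."""
    ref = _stratified_subsample(np.asarray(reference_intensities, float),
                                max_reference, seed)
    return LOFModel(ref, min_pts=min_pts, threshold=threshold)


@dataclass
class VoxelLOFScores:
    scores: np.ndarray         # per-voxel LOF over the candidate patch
    refined_mask: np.ndarray   # LOF <= tau, within brain
    dropped: bool              # refinement emptied the candidate


def _local_features(patch: np.ndarray) -> np.ndarray:
    mean = ndimage.uniform_filter(patch.astype(float), size=3, mode="nearest")
    sq = ndimage.uniform_filter(patch.astype(float) ** 2, size=3, mode="nearest")
    std = np.sqrt(np.maximum(sq - mean**2, 0.0))
    return np.stack([patch.astype(float), mean, std], axis=-1)


def refine_boundary(
    candidate: LesionCandidate,
    model: LOFModel,
    threshold: float | None = None,
    feature_space: str = "intensity",
) -> VoxelLOFScores:
    """Score every patch voxel against the WML intensity model.

    The refined mask keeps voxels with ``LOF <= tau`` inside the brain; an
    empty result flags the candidate for dropping (logged). The optional
    ``feature_space='local'`` variant scores the scalar intensity but only on
    voxels whose 3x3 neighborhood is brain, an experimentation hook.
    """
    tau = model.threshold if threshold is None else threshold
    patch = candidate.patch.astype(float)
    scores = model.score(patch)
    refined = (scores <= tau) & candidate.brain_patch
    if feature_space == "local":
        interior = ndimage.binary_erosion(candidate.brain_patch,
                                          structure=np.ones((3, 3), bool))
        refined &= interior | candidate.mask
    dropped = not refined.any()
    if dropped:
        log.info("candidate %d: refinement produced an empty mask, dropping",
                 candidate.id)
    return VoxelLOFScores(scores, refined, dropped)
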