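"""Intensity standardization and fuzzy C-means tissue segmentation.

MR intensities are scanner-dependent; texture and brightness are only
comparable across scans after mapping each volume onto a common gray scale.
The mapping here is a percentile-landmark piecewise-linear transform: the
source landmarks are percentiles of the brain intensities (default p1, the
deciles, and p99) and the targets live on a fixed standardized scale of
``L_std = 8192`` levels. Values beyond the outermost landmarks follow the
slope of the adjacent segment (so hyperintense lesions brighter than p99 keep
their contrast) and are finally clipped to ``[0, L_std - 1]`` and rounded.

Tissue is partitioned into CSF/GM/WM by fuzzy C-means on scalar intensities;
the centers are sorted ascending so the class order is the intensity order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .imaging import BinaryMask, GrayVolume

__all__ = [
    "LandmarkMap",
    "TissueMap",
    "fit_landmark_map",
    "fit_standard_scale",
    "standardize",
    "standardize_array",
    "fcm_tissue_segmentation",
]

log = logging.getLogger(__name__)

DEFAULT_PERCENTILES = (1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 99)


@dataclass(frozen=True)
class LandmarkMap:
    """Piecewise-linear percentile-landmark intensity map."""

    source_landmarks: np.ndarray
    target_landmarks: np.ndarray
    L_std: int = 8192

    def __post_init__(self) -> None:
        src = np.asarray(self.source_landmarks, dtype=float)
        tgt = np.asarray(self.target_landmarks, dtype=float)
        if src.size != tgt.size or src.size < 2:
            raise ValueError("landmark sequences must have equal length >= 2")
        if np.any(np.diff(src) <= 0) or np.any(np.diff(tgt) <= 0):
            raise ValueError("landmark sequences must be strictly increasing")
        object.__setattr__(self, "source_landmarks", src)
        object.__setattr__(self, "target_landmarks", tgt)


def _collapse_degenerate(src: np.ndarray, tgt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Drop landmarks that tie with their predecessor (flat histogram stretches)."""
    keep = np.concatenate(([True], np.diff(src) > 0))
    if not keep.all():
        log.warning("collapsed %d degenerate landmark(s)", int((~keep).sum()))
    return src[keep], tgt[keep]


def fit_landmark_map(
    volume: GrayVolume | np.ndarray,
    brain: BinaryMask | np.ndarray,
    percentiles=DEFAULT_PERCENTILES,
    target_scale: int = 8192,
    target_landmarks: np.ndarray | None = None,
    headroom: float = 0.8,
) -> LandmarkMap:
    """Fit the landmark map for one volume.

    ``target_landmarks`` normally come from :func:`fit_standard_scale` on a
    training cohort; without them the defaults anchor the first landmark at 0
    and the last at ``headroom * (target_scale - 1)``, placing the remaining
    landmarks by linear rescaling of the source (a single-volume fallback that
    is exactly affine-invariant).
    """
    vox = volume.voxels if isinstance(volume, GrayVolume) else np.asarray(volume)
    msk = brain.voxels if isinstance(brain, BinaryMask) else np.asarray(brain, bool)
    values = vox[msk].astype(float)
    if values.size == 0:
        raise ValueError("brain mask is empty")
    if values.min() == values.max():
        raise ValueError("brain region is constant: no dynamic range to standardize")
    pct = np.asarray(percentiles, dtype=float)
    if np.any(pct <= 0) or np.any(pct >= 100) or np.any(np.diff(pct) <= 0):
        raise ValueError("percentiles must be increasing within (0, 100)")
    # linear interpolation between closest ranks ("type 7"), numpy's default
    src = np.percentile(values, pct)
    if target_landmarks is not None:
        tgt = np.asarray(target_landmarks, dtype=float)
        if tgt.size != src.size:
            raise ValueError("target landmark count must match percentile count")
    else:
        top = headroom * (target_scale - 1)
        tgt = (src - src[0]) / (src[-1] - src[0]) * top
    src, tgt = _collapse_degenerate(src, tgt)
    if src.size < 2:
        raise ValueError("fewer than two distinct landmarks")
    return LandmarkMap(src, tgt, L_std=target_scale)


def fit_standard_scale(
    volumes,
    brains,
    percentiles=DEFAULT_PERCENTILES,
    target_scale: int = 8192,
    headroom: float = 0.8,
) -> np.ndarray:
    """Learn target landmarks from a training cohort.

    Each volume's source landmarks are rescaled onto ``[0, headroom*(L-1)]``
    anchored at the outermost landmarks; the standard scale is their mean.
    """
    rescaled = []
    top = headroom * (target_scale - 1)
    for vol, brn in zip(volumes, brains):
        m = fit_landmark_map(vol, brn, percentiles, target_scale, headroom=headroom)
        src = m.source_landmarks
        rescaled.append((src - src[0]) / (src[-1] - src[0]) * top)
    tgt = np.mean(rescaled, axis=0)
    return tgt


def standardize_array(values: np.ndarray, lmap: LandmarkMap) -> np.ndarray:
    """Apply the map to a float array, without rounding or clipping."""
    x = np.asarray(values, dtype=float)
    src, tgt = lmap.source_landmarks, lmap.target_landmarks
    out = np.interp(x, src, tgt)
    # np.interp clamps outside the landmark range; extrapolate the end segments
    lo = x < src[0]
    hi = x > src[-1]
    if lo.any():
        slope = (tgt[1] - tgt[0]) / (src[1] - src[0])
        out[lo] = tgt[0] + (x[lo] - src[0]) * slope
    if hi.any():
        slope = (tgt[-1] - tgt[-2]) / (src[-1] - src[-2])
        out[hi] = tgt[-1] + (x[hi] - src[-1]) * slope
    return out


def standardize(volume: GrayVolume, lmap: LandmarkMap) -> GrayVolume:
    """Map a volume onto the standardized scale: integers in [0, L_std - 1]."""
    out = standardize_array(volume.voxels, lmap)
    out = np.clip(np.rint(out), 0, lmap.L_std - 1).astype(np.int64)
    return GrayVolume(out, volume.geometry, scale_max=lmap.L_std - 1)


# ---------------------------------------------------------------------------
# Fuzzy C-means tissue segmentation
# ---------------------------------------------------------------------------

TISSUE_NAMES = ("CSF", "GM", "WM")


@dataclass
class TissueMap:
    """Fuzzy memberships and hard labels for CSF/GM/WM within the brain."""

    memberships: np.ndarray          # (n_classes, slice, row, col), 0 outside brain
    hard_labels: np.ndarray          # (slice, row, col) int, -1 outside brain
    class_centers: np.ndarray        # ascending: CSF < GM < WM
    objective_history: np.ndarray = field(default_factory=lambda: np.empty(0))


def fcm_tissue_segmentation(
    volume: GrayVolume | np.ndarray,
    brain: BinaryMask | np.ndarray,
    n_classes: int = 3,
    fuzzifier: float = 2.0,
    tol: float = 1e-5,
    max_iter: int = 300,
    seed: int | None = None,
    init: str = "percentile",
) -> TissueMap:
    """Fuzzy C-means on scalar intensities inside the brain mask.

    Deterministic by default: centers start at the masked-intensity
    percentiles equally spaced in (0, 100) (10/50/90 for three classes);
    ``init='random'`` draws them from the data with ``seed``.
    """
    vox = volume.voxels if isinstance(volume, GrayVolume) else np.asarray(volume)
    msk = brain.voxels if isinstance(brain, BinaryMask) else np.asarray(brain, bool)
    x = vox[msk].astype(float)
    if x.size == 0:
        raise ValueError("brain mask is empty")
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must be > 1")
    if np.unique(x).size < n_classes:
        raise ValueError("fewer distinct intensities than classes")

    if init == "random":
        rng = np.random.default_rng(seed)
        centers = np.sort(rng.choice(np.unique(x), size=n_classes, replace=False).astype(float))
    else:
        pct = np.linspace(0, 100, n_classes + 2)[1:-1]
        centers = np.sort(np.percentile(x, pct))

    m = fuzzifier
    power = 2.0 / (m - 1.0)
    history = []
    for _ in range(max_iter):
        d2 = (x[None, :] - centers[:, None]) ** 2          # (k, n)
        d2 = np.maximum(d2, 1e-12)
        inv = d2 ** (-1.0 / (m - 1.0) * 1.0)
        u = inv / inv.sum(axis=0, keepdims=True)           # memberships
        um = u**m
        history.append(float((um * d2).sum()))
        new_centers = (um * x[None, :]).sum(axis=1) / um.sum(axis=1)
        shift = np.max(np.abs(new_centers - centers))
        centers = new_centers
        if shift < tol:
            break
    # final memberships for the converged centers, sorted ascending
    order = np.argsort(centers)
    centers = centers[order]
    d2 = np.maximum((x[None, :] - centers[:, None]) ** 2, 1e-12)
    inv = d2 ** (-power / 2.0)
    u = inv / inv.sum(axis=0, keepdims=True)

    memberships = np.zeros((n_classes,) + vox.shape, dtype=float)
    for c in range(n_classes):
        memberships[c][msk] = u[c]
    hard = np.full(vox.shape, -1, dtype=np.int8)
    hard[msk] = np.argmax(u, axis=0)
    return TissueMap(memberships, hard, centers, np.asarray(history))
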