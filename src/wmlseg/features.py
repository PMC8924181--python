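"""Classifier inputs: intensity-histogram and GLCM texture descriptors.

Each candidate contributes ten scalars. Six come from the first-order
intensity histogram of the standardized patch (mean, variance, skewness,
kurtosis, energy, Shannon entropy in bits). Four are Haralick-style texture
features (contrast, energy, correlation, homogeneity) of a gray-level
co-occurrence matrix built not on linearly rescaled intensities but on a
k-means quantization of the patch ("embedded clustering"): 1-D k-means groups
the patch intensities into ``L`` clusters (default 5) whose ascending centers
define the gray levels, which preserves the lesion's internal texture far
better than equal-count binning when the dynamic range is dominated by the
lesion/background split.

Conventions
-----------
* Skewness/kurtosis are the moment-standardized forms ``m3 / sigma^3`` and
  ``m4 / sigma^4`` (kurtosis is non-excess: Gaussian ~ 3); a constant patch
  returns 0 for both by convention.
* The co-occurrence count ``CM[n, m]`` tallies ordered pairs
  ``(current=n, displaced=m)`` with a positive displacement and no
  symmetrization. Relative to a definition displacing by ``(-dx, -dy)`` this
  transposes CM, which leaves contrast/energy/homogeneity unchanged and does
  not affect correlation through the symmetric marginals.
* Probabilities divide by the number of valid pairs: pairs with either pixel
  outside the quantization mask are skipped and the normalizer shrinks
  accordingly, so ``sum(P) == 1`` for every mask configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .detection import LesionCandidate

__all__ = [
    "HistogramFeatures",
    "QuantizedPatch",
    "GLCM",
    "GLCMFeatures",
    "CandidateFeatures",
    "FEATURE_NAMES",
    "histogram_features",
    "kmeans_quantize",
    "quantile_quantize",
    "compute_glcm",
    "glcm_features",
    "extract_features",
    "orientation_offset",
    "features_frame",
]

log = logging.getLogger(__name__)

SENTINEL = -1  # label value for pixels excluded from co-occurrence pairs

FEATURE_NAMES = (
    "hist_mean",
    "hist_variance",
    "hist_skewness",
    "hist_kurtosis",
    "hist_energy",
    "hist_entropy",
    "glcm_contrast",
    "glcm_energy",
    "glcm_correlation",
    "glcm_homogeneity",
)


@dataclass(frozen=True)
class HistogramFeatures:
    mean: float
    variance: float
    skewness: float
    kurtosis: float
    energy: float
    entropy: float
    levels: np.ndarray | None = None         # observed gray levels
    probabilities: np.ndarray | None = None  # p(g) over the observed levels

    def as_tuple(self) -> tuple[float, ...]:
        return (self.mean, self.variance, self.skewness, self.kurtosis,
                self.energy, self.entropy)


@dataclass
class QuantizedPatch:
    labels: np.ndarray       # 2D int, SENTINEL outside the mask
    centers: np.ndarray      # ascending
    L_clusters: int
    method: str

    def reconstruct(self) -> np.ndarray:
        out = np.zeros(self.labels.shape, dtype=float)
        inside = self.labels != SENTINEL
        out[inside] = self.centers[self.labels[inside]]
        return out


@dataclass
class GLCM:
    counts: np.ndarray         # (L, L) ints
    probabilities: np.ndarray  # (L, L) floats, sums to 1
    offset: tuple[int, int]    # (d_row, d_col)
    orientation_deg: int
    patch_shape: tuple[int, int]


@dataclass(frozen=True)
class GLCMFeatures:
    contrast: float
    energy: float
    correlation: float
    homogeneity: float

    def as_tuple(self) -> tuple[float, ...]:
        return (self.contrast, self.energy, self.correlation, self.homogeneity)


@dataclass(frozen=True)
class CandidateFeatures:
    candidate_id: int
    histogram: HistogramFeatures
    glcm: GLCMFeatures

    def as_vector(self) -> np.ndarray:
        vec = np.array(self.histogram.as_tuple() + self.glcm.as_tuple())
        if not np.all(np.isfinite(vec)):
            raise ValueError("non-finite feature value")
        return vec


# ---------------------------------------------------------------------------
# First-order histogram features
# ---------------------------------------------------------------------------

def histogram_features(patch: np.ndarray, mask: np.ndarray) -> HistogramFeatures:
    """Table of first-order statistics of the masked standardized intensities."""
    values = np.asarray(patch, dtype=float)[np.asarray(mask, bool)]
    if values.size == 0:
        raise ValueError("empty mask")
    levels, counts = np.unique(values, return_counts=True)
    p = counts / counts.sum()
    mu = float((levels * p).sum())
    var = float((((levels - mu) ** 2) * p).sum())
    if var > 0:
        m3 = float((((levels - mu) ** 3) * p).sum())
        m4 = float((((levels - mu) ** 4) * p).sum())
        skew = m3 / var**1.5
        kurt = m4 / var**2
    else:
        skew = kurt = 0.0  # degenerate convention for a constant patch
    energy = float((p**2).sum())
    entropy = float(-(p * np.log2(p)).sum())  # p > 0 on the observed support
    return HistogramFeatures(mu, var, skew, kurt, energy, entropy, levels, p)


# ---------------------------------------------------------------------------
# Quantization
# ---------------------------------------------------------------------------

def _finalize_quantized(
    labels_flat: np.ndarray, centers: np.ndarray, mask: np.ndarray,
    L: int, method: str,
) -> QuantizedPatch:
    order = np.argsort(centers, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(order.size)
    labels = np.full(mask.shape, SENTINEL, dtype=np.int64)
    labels[mask] = rank[labels_flat]
    return QuantizedPatch(labels, np.asarray(centers, float)[order], L, method)


def kmeans_quantize(
    patch: np.ndarray,
    mask: np.ndarray | None = None,
    L_clusters: int = 5,
    seed: int | None = None,
    max_iter: int = 100,
) -> QuantizedPatch:
    """1-D k-means quantization of the masked patch intensities.

    Deterministic: centers start at ``L`` equally spaced quantiles of the
    masked intensities (``seed`` is accepted for interface symmetry but the
    default init does not consume randomness). Ties between centers assign
    the lower label. If the patch holds fewer distinct intensities than
    clusters, ``L`` is reduced to the distinct count with a warning.
    """
    patch = np.asarray(patch, dtype=float)
    mask = np.ones(patch.shape, bool) if mask is None else np.asarray(mask, bool)
    x = patch[mask]
    if L_clusters < 1:
        raise ValueError("L_clusters must be >= 1")
    if x.size < L_clusters:
        raise ValueError("fewer masked voxels than clusters")
    distinct = np.unique(x)
    L = L_clusters
    if distinct.size < L:
        log.warning("reducing L_clusters from %d to %d distinct intensities",
                    L, distinct.size)
        L = distinct.size
    if L == distinct.size:
        centers = distinct.astype(float)
        labels = np.searchsorted(distinct, x)
        return _finalize_quantized(labels, centers, mask, L, "kmeans")
    centers = np.percentile(x, np.linspace(0, 100, 2 * L + 1)[1::2])
    for _ in range(max_iter):
        d = np.abs(x[None, :] - centers[:, None])
        labels = np.argmin(d, axis=0)  # tie -> lower label
        new = centers.copy()
        for c in range(L):
            sel = labels == c
            if sel.any():
                new[c] = x[sel].mean()
        if np.array_equal(new, centers):
            break
        centers = new
    labels = np.argmin(np.abs(x[None, :] - centers[:, None]), axis=0)
    return _finalize_quantized(labels, centers, mask, L, "kmeans")


def quantile_quantize(
    patch: np.ndarray,
    mask: np.ndarray | None = None,
    L_clusters: int = 5,
) -> QuantizedPatch:
    """Equal-count (quantile) binning: the linear-scaling comparison baseline."""
    patch = np.asarray(patch, dtype=float)
    mask = np.ones(patch.shape, bool) if mask is None else np.asarray(mask, bool)
    x = patch[mask]
    if L_clusters < 1:
        raise ValueError("L_clusters must be >= 1")
    if x.size < L_clusters:
        raise ValueError("fewer masked voxels than clusters")
    edges = np.percentile(x, np.linspace(0, 100, L_clusters + 1))
    edges = np.unique(edges)
    L = edges.size - 1
    if L < 1:  # constant patch
        labels = np.zeros(x.size, dtype=np.int64)
        return _finalize_quantized(labels, np.array([x[0]]), mask, 1, "quantile")
    if L < L_clusters:
        log.warning("reducing quantile bins from %d to %d", L_clusters, L)
    labels = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, L - 1)
    centers = np.array([x[labels == c].mean() if (labels == c).any()
                        else 0.5 * (edges[c] + edges[c + 1]) for c in range(L)])
    return _finalize_quantized(labels, centers, mask, L, "quantile")


# ---------------------------------------------------------------------------
# Co-occurrence matrix and its features
# ---------------------------------------------------------------------------

def orientation_offset(orientation_deg: int, distance: int = 1) -> tuple[int, int]:
    """Map an orientation to a (d_row, d_col) displacement (Haralick convention)."""
    table = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
    if orientation_deg not in table:
        raise ValueError("orientation must be one of 0, 45, 90, 135 degrees")
    dr, dc = table[orientation_deg]
    return (dr * distance, dc * distance)


def compute_glcm(q: QuantizedPatch, offset: tuple[int, int],
                 orientation_deg: int | None = None) -> GLCM:
    """Co-occurrence counts and probabilities for one displacement.

    ``CM[n, m]`` counts positions where the current pixel holds level ``n``
    and the pixel displaced by ``offset`` holds ``m``; pairs touching a
    sentinel (unmasked) pixel are skipped and the normalizer is the number of
    valid pairs, so the probabilities always sum to 1.
    """
    dr, dc = offset
    labels = q.labels
    n_rows, n_cols = labels.shape
    if abs(dr) >= n_rows or abs(dc) >= n_cols:
        raise ValueError("patch smaller than the requested offset")
    r0, r1 = max(0, -dr), min(n_rows, n_rows - dr)
    c0, c1 = max(0, -dc), min(n_cols, n_cols - dc)
    cur = labels[r0:r1, c0:c1]
    nbr = labels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    valid = (cur != SENTINEL) & (nbr != SENTINEL)
    n_pairs = int(valid.sum())
    if n_pairs == 0:
        raise ValueError("no valid pixel pairs for this offset")
    L = q.L_clusters
    counts = np.zeros((L, L), dtype=np.int64)
    np.add.at(counts, (cur[valid], nbr[valid]), 1)
    return GLCM(counts, counts / n_pairs, (dr, dc),
                orientation_deg if orientation_deg is not None else -1,
                (n_rows, n_cols))


def glcm_features(g: GLCM) -> GLCMFeatures:
    """Contrast, energy, correlation, and homogeneity of a GLCM."""
    P = g.probabilities
    L = P.shape[0]
    i = np.arange(L)[:, None]
    j = np.arange(L)[None, :]
    contrast = float(((i - j) ** 2 * P).sum())
    energy = float((P**2).sum())
    homogeneity = float((P / (1.0 + np.abs(i - j))).sum())
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    idx = np.arange(L)
    mu_x = float((idx * px).sum())
    mu_y = float((idx * py).sum())
    sig_x = float(np.sqrt(((idx - mu_x) ** 2 * px).sum()))
    sig_y = float(np.sqrt(((idx - mu_y) ** 2 * py).sum()))
    if sig_x * sig_y > 0:
        correlation = float(((i * j * P).sum() - mu_x * mu_y) / (sig_x * sig_y))
    else:
        correlation = 0.0  # degenerate convention
    return GLCMFeatures(contrast, energy, correlation, homogeneity)


# ---------------------------------------------------------------------------
# Candidate-level extraction
# ---------------------------------------------------------------------------

def extract_features(
    candidate: LesionCandidate,
    n_clusters: int = 5,
    orientation_deg: int = 0,
    distance: int = 1,
    quantizer: str = "kmeans",
    glcm_scope: str = "patch",
    seed: int | None = None,
) -> CandidateFeatures:
    """The ten feature scalars for one candidate.

    Histogram features use the standardized intensities inside the candidate
    mask; GLCM features use the quantized margin-dilated patch restricted to
    brain (``glcm_scope='patch'``, the default: the texture context around the
    lesion is what separates mimics) or to the candidate mask
    (``glcm_scope='mask'``).
    """
    hist = histogram_features(candidate.patch, candidate.mask)
    if glcm_scope == "patch":
        qmask = candidate.brain_patch
    elif glcm_scope == "mask":
        qmask = candidate.mask
    else:
        raise ValueError("glcm_scope must be 'patch' or 'mask'")
    if quantizer == "kmeans":
        q = kmeans_quantize(candidate.patch, qmask, n_clusters, seed=seed)
    elif quantizer == "quantile":
        q = quantile_quantize(candidate.patch, qmask, n_clusters)
    else:
        raise ValueError("quantizer must be 'kmeans' or 'quantile'")
    glcm = compute_glcm(q, orientation_offset(orientation_deg, distance),
                        orientation_deg)
    feats = CandidateFeatures(candidate.id, hist, glcm_features(glcm))
    feats.as_vector()  # validates finiteness
    return feats


def features_frame(features, labels=None, slices=None):
    """Feature rows as a pandas DataFrame (the CSV export schema)."""
    import pandas as pd

    rows = []
    for k, f in enumerate(features):
        row = {"candidate_id": f.candidate_id}
        if slices is not None:
            row["slice_index"] = slices[k]
        row.update(dict(zip(FEATURE_NAMES, f.as_vector())))
        if labels is not None:
            row["label"] = labels[k]
        rows.append(row)
    return pd.DataFrame(rows)
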