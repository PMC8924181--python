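"""Trimmed-mean / boxplot candidate detection (TMOD stage).

Lesions on FLAIR are hyperintense, so each 2D slice is screened for extreme
upper outliers of its own brain-intensity distribution: the distribution is
symmetrically trimmed to estimate the normal-tissue bulk, quartiles of the
trimmed values give a Tukey fence ``q3 + k * IQR`` (``k = 3``, the "extreme
outlier" fence), and voxels strictly above the fence form the candidate map.
8-connected in-plane components at least ``min_area`` pixels large become
:class:`LesionCandidate` patches (bounding box dilated by a small margin for
texture context).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imaging import BinaryMask, GrayVolume

__all__ = [
    "SliceThreshold",
    "LesionCandidate",
    "trimmed_mean",
    "trim_values",
    "slice_threshold",
    "detect_candidates",
]

EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SliceThreshold:
    """Per-slice trimmed statistics and the extreme-outlier fence."""

    slice_index: int
    trimmed_mean: float
    q1: float
    q3: float
    iqr: float
    extreme_threshold: float
    has_wml: bool


@dataclass
class LesionCandidate:
    """A connected hyperintense component with its intensity patch.

    ``patch`` is the standardized-intensity crop of the margin-dilated bounding
    box; ``mask`` marks the component's pixels within the patch and
    ``brain_patch`` the in-brain pixels. ``bbox`` is the tight half-open
    component box in slice coordinates; ``patch_origin`` locates ``patch``.
    """

    id: int
    slice_index: int
    bbox: tuple[int, int, int, int]          # (row0, col0, row1, col1), half-open
    patch: np.ndarray
    mask: np.ndarray
    brain_patch: np.ndarray
    patch_origin: tuple[int, int]
    area_px: int


def trim_values(values: np.ndarray, trim_fraction: float) -> np.ndarray:
    """Sorted values with the lowest and highest ``trim_fraction`` removed.

    The discarded count per tail is ``floor(trim_fraction * n)``.
    """
    v = np.sort(np.asarray(values, dtype=float).ravel())
    if v.size == 0:
        raise ValueError("empty input")
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    k = int(np.floor(trim_fraction * v.size))
    return v[k : v.size - k] if k else v


def trimmed_mean(values, trim_fraction: float) -> float:
    """Mean after discarding the extreme ``trim_fraction`` of each tail."""
    return float(trim_values(values, trim_fraction).mean())


def slice_threshold(
    slice_intensities: np.ndarray,
    brain: np.ndarray,
    trim_fraction: float = 0.2,
    k_extreme: float = 3.0,
    slice_index: int = 0,
) -> SliceThreshold:
    """Boxplot fence of the trimmed brain-intensity distribution of one slice."""
    values = np.asarray(slice_intensities, dtype=float)[np.asarray(brain, bool)]
    if values.size == 0:
        raise ValueError("brain region is empty on this slice")
    trimmed = trim_values(values, trim_fraction)
    q1, q3 = np.percentile(trimmed, [25, 75])
    iqr = q3 - q1
    fence = q3 + k_extreme * iqr
    return SliceThreshold(
        slice_index=slice_index,
        trimmed_mean=float(trimmed.mean()),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        extreme_threshold=float(fence),
        has_wml=bool((values > fence).any()),
    )


def detect_candidates(
    volume: GrayVolume,
    brain: BinaryMask,
    trim_fraction: float = 0.2,
    k_extreme: float = 3.0,
    min_area: int = 3,
    margin_px: int = 2,
) -> tuple[list[LesionCandidate], BinaryMask, list[SliceThreshold]]:
    """Per-slice extreme-outlier thresholding and component extraction.

    Returns the candidates (ids slice-major, then top-left of the bounding
    box), the union mask of all retained components, and the per-slice
    thresholds. Voxels must be *strictly* above the fence to count.
    """
    vox = volume.voxels
    brn = brain.voxels
    if vox.shape != brn.shape:
        raise ValueError("volume and brain mask shapes differ")
    union = np.zeros(vox.shape, dtype=bool)
    thresholds: list[SliceThreshold] = []
    candidates: list[LesionCandidate] = []
    next_id = 0
    n_rows, n_cols = vox.shape[1:]
    for z in range(vox.shape[0]):
        img = vox[z].astype(float)
        msk = brn[z]
        if not msk.any():
            continue
        thr = slice_threshold(img, msk, trim_fraction, k_extreme, slice_index=z)
        thresholds.append(thr)
        binary = (img > thr.extreme_threshold) & msk
        if not binary.any():
            continue
        labels, n_comp = ndimage.label(binary, structure=EIGHT_CONNECTED)
        slices = ndimage.find_objects(labels)
        comps = []
        for lab, sl in enumerate(slices, start=1):
            area = int((labels[sl] == lab).sum())
            if area < min_area:
                continue
            comps.append((sl[0].start, sl[1].start, lab, sl, area))
        comps.sort(key=lambda t: (t[0], t[1]))
        for r0, c0, lab, sl, area in comps:
            r1, c1 = sl[0].stop, sl[1].stop
            pr0, pc0 = max(0, r0 - margin_px), max(0, c0 - margin_px)
            pr1, pc1 = min(n_rows, r1 + margin_px), min(n_cols, c1 + margin_px)
            patch = vox[z, pr0:pr1, pc0:pc1].copy()
            comp_mask = labels[pr0:pr1, pc0:pc1] == lab
            union[z][labels == lab] = True
            candidates.append(
                LesionCandidate(
                    id=next_id,
                    slice_index=z,
                    bbox=(r0, c0, r1, c1),
                    patch=patch,
                    mask=comp_mask,
                    brain_patch=msk[pr0:pr1, pc0:pc1].copy(),
                    patch_origin=(pr0, pc0),
                    area_px=area,
                )
            )
            next_id += 1
    return candidates, BinaryMask(union), thresholds
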