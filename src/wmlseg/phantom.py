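"""Synthetic FLAIR-like brain phantoms with known ground truth.

Real FLAIR data with neuroradiologist annotations are not distributable, so
every pipeline stage is exercised on multi-slice phantoms that emulate the
features the method actually depends on:

* an elliptical skull-stripped brain per axial slice with three tissue
  plateaus CSF < GM < WM on a 16-bit scale (the parenchyma is WM-dominated,
  as on real FLAIR, so the 20%-trimmed slice distribution isolates the WM
  mode);
* a smooth multiplicative bias field of small amplitude (inputs are nominally
  inhomogeneity-corrected; a residual is realistic) and additive Gaussian
  noise, optionally Rician;
* hyperintense lesions: steep-edged blobs (super-Gaussian radial profile,
  exponent 4) with correlated internal texture; ground truth is the region
  where the noiseless lesion contribution exceeds half its peak contrast;
* hyperintense false-positive mimics whose *texture* separates them from
  lesions — thin high-contrast streaks (flow artefacts), bright rim fragments
  at the brain edge (residual skull), and speckled punctate blobs (noise
  clusters) — because texture is precisely the discriminative axis the
  classifier is supposed to exploit.

All randomness flows from the single PhantomSpec seed; regeneration is
bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .imaging import BinaryMask, GrayVolume, VolumeGeometry

__all__ = [
    "LesionSpec",
    "MimicSpec",
    "PhantomSpec",
    "PhantomBundle",
    "generate_phantom",
    "generate_cohort",
    "generate_training_set",
]

log = logging.getLogger(__name__)

LESION_EDGE_EXPONENT = 8  # super-Gaussian: flat core, ~1 px partial-volume rim
HALF_PEAK = 0.5
# radius of the half-peak contour in units of the profile scale sigma_r
_R_HALF = (np.log(1.0 / HALF_PEAK)) ** (1.0 / LESION_EDGE_EXPONENT)


@dataclass(frozen=True)
class LesionSpec:
    slice_index: int
    center: tuple[float, float]      # (row, col)
    radius_px: float                 # half-peak radius
    contrast: float                  # peak intensity above local tissue
    texture_sigma: float = 0.0       # internal correlated-texture amplitude


@dataclass(frozen=True)
class MimicSpec:
    kind: str                        # streak | rim_fragment | punctate_noise
    slice_index: int
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class PhantomSpec:
    n_slices: int = 10
    slice_dims: tuple[int, int] = (128, 128)
    tissue_means: tuple[float, float, float] = (3000.0, 9000.0, 12000.0)
    noise_sigma: float = 500.0
    bias_amplitude: float = 0.05
    lesions: tuple[LesionSpec, ...] = ()
    fp_mimics: tuple[MimicSpec, ...] = ()
    seed: int = 0
    rician: bool = False
    geometry: VolumeGeometry = field(default_factory=VolumeGeometry)

    def __post_init__(self) -> None:
        csf, gm, wm = self.tissue_means
        if not csf < gm < wm:
            raise ValueError("tissue means must be strictly increasing (CSF<GM<WM)")
        for les in self.lesions:
            if les.contrast <= 0:
                raise ValueError("lesions must be hyperintense (contrast > 0)")
            if not (0 <= les.slice_index < self.n_slices):
                raise ValueError("lesion slice outside the volume")
            r, c = les.center
            if not (0 <= r < self.slice_dims[0] and 0 <= c < self.slice_dims[1]):
                raise ValueError("lesion center outside slice bounds")


@dataclass
class PhantomBundle:
    flair: GrayVolume
    brain: BinaryMask
    gt_lesions: BinaryMask
    gt_tissue: np.ndarray            # -1 outside brain; 0 CSF, 1 GM, 2 WM
    spec: PhantomSpec


# ---------------------------------------------------------------------------
# Geometry helpers
# ---------------------------------------------------------------------------

def _slice_anatomy(spec: PhantomSpec, z: int) -> tuple[np.ndarray, np.ndarray]:
    """Brain mask and tissue labels (0 CSF, 1 GM, 2 WM; -1 outside) for slice z."""
    rows, cols = spec.slice_dims
    rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    # head-shaped taper towards the first/last slice
    zc = (spec.n_slices - 1) / 2.0
    taper = np.sqrt(max(0.35, 1.0 - ((z - zc) / (0.75 * spec.n_slices)) ** 2))
    a, b = 0.42 * rows * taper, 0.45 * cols * taper
    rho = np.sqrt(((rr - cy) / a) ** 2 + ((cc - cx) / b) ** 2)
    brain = rho <= 1.0
    labels = np.full((rows, cols), -1, dtype=np.int8)
    labels[brain] = 2                                   # WM bulk
    labels[brain & (rho > 0.87)] = 1                    # thin cortical GM ribbon
    # two ventricular CSF ellipses near the center
    for sign in (-1.0, 1.0):
        vr = ((rr - cy - 0.02 * rows) / (0.10 * rows * taper)) ** 2 + (
            (cc - cx + sign * 0.10 * cols) / (0.045 * cols * taper)) ** 2
        labels[brain & (vr <= 1.0)] = 0
    return brain, labels


def _bias_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field in [1 - amplitude, 1 + amplitude]."""
    if amplitude == 0:
        return np.ones(shape)
    raw = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(raw, sigma=min(shape) / 4.0)
    span = np.abs(smooth).max()
    if span == 0:
        return np.ones(shape)
    return 1.0 + amplitude * smooth / span


def _lesion_profile(shape, center, radius_px: float) -> np.ndarray:
    """Noiseless radial profile in [0, 1]; 0.5 contour at radius_px."""
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    d = np.sqrt((rr - center[0]) ** 2 + (cc - center[1]) ** 2)
    sigma_r = radius_px / _R_HALF
    return np.exp(-((d / sigma_r) ** LESION_EDGE_EXPONENT))


def _paint_mimic(img: np.ndarray, brain: np.ndarray, mimic: MimicSpec,
                 wm_mean: float, noise_sigma: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Add one false-positive mimic in place; returns its footprint mask."""
    rows, cols = img.shape
    p = mimic.params
    footprint = np.zeros(img.shape, dtype=bool)
    base = wm_mean + p.get("contrast", 6.0) * noise_sigma
    if mimic.kind == "streak":
        # thin flow-artefact line with alternating bright/dim texture
        r0, c0 = p["start"]
        angle = p.get("angle", 0.0)
        length = int(p.get("length", 14))
        width = int(p.get("width", 2))
        dr, dc = np.sin(angle), np.cos(angle)
        for t in range(length):
            r = int(round(r0 + t * dr))
            c = int(round(c0 + t * dc))
            for w in range(width):
                rw = min(max(r + int(round(w * dc)), 0), rows - 1)
                cw = min(max(c - int(round(w * dr)), 0), cols - 1)
                if brain[rw, cw]:
                    wobble = 3.0 * noise_sigma * (1 if (t + w) % 2 == 0 else -1)
                    img[rw, cw] = base + wobble
                    footprint[rw, cw] = True
    elif mimic.kind == "rim_fragment":
        # bright arc hugging the brain boundary (incomplete skull stripping)
        edge = brain & ~ndimage.binary_erosion(brain, iterations=int(p.get("depth", 2)))
        rr, cc = np.mgrid[0:rows, 0:cols]
        theta = np.arctan2(rr - (rows - 1) / 2.0, cc - (cols - 1) / 2.0)
        t0 = p.get("theta0", 0.0)
        span = p.get("span", 0.5)
        arc = edge & (np.abs(np.angle(np.exp(1j * (theta - t0)))) < span / 2.0)
        speckle = rng.standard_normal(img.shape) > 0  # bimodal rim intensities
        img[arc] = np.where(speckle, base + 2.5 * noise_sigma,
                            base - 2.5 * noise_sigma)[arc]
        footprint |= arc
    elif mimic.kind == "punctate_noise":
        # small speckled cluster: bright but with lesion-unlike rough texture
        r0, c0 = p["center"]
        radius = float(p.get("radius", 2.5))
        rr, cc = np.mgrid[0:rows, 0:cols].astype(float)
        blob = (np.sqrt((rr - r0) ** 2 + (cc - c0) ** 2) <= radius) & brain
        rough = rng.standard_normal(img.shape) * 3.0 * noise_sigma
        img[blob] = base + rough[blob]
        footprint |= blob
    else:
        raise ValueError(f"unknown mimic kind: {mimic.kind}")
    return footprint


def generate_phantom(spec: PhantomSpec) -> PhantomBundle:
    """Render the phantom volume, brain mask, tissue labels, and lesion GT."""
    rows, cols = spec.slice_dims
    rng = np.random.default_rng(spec.seed)
    csf, gm, wm = spec.tissue_means
    means = np.array([csf, gm, wm])
    flair = np.zeros((spec.n_slices, rows, cols), dtype=float)
    brain = np.zeros((spec.n_slices, rows, cols), dtype=bool)
    gt = np.zeros((spec.n_slices, rows, cols), dtype=bool)
    tissue = np.full((spec.n_slices, rows, cols), -1, dtype=np.int8)

    lesions_by_slice: dict[int, list[LesionSpec]] = {}
    for les in spec.lesions:
        lesions_by_slice.setdefault(les.slice_index, []).append(les)
    mimics_by_slice: dict[int, list[MimicSpec]] = {}
    for mim in spec.fp_mimics:
        mimics_by_slice.setdefault(mim.slice_index, []).append(mim)

    for z in range(spec.n_slices):
        bmask, labels = _slice_anatomy(spec, z)
        brain[z] = bmask
        tissue[z] = labels
        img = np.zeros((rows, cols), dtype=float)
        img[bmask] = means[labels[bmask]]

        slice_gt = np.zeros((rows, cols), dtype=bool)
        for les in lesions_by_slice.get(z, []):
            profile = _lesion_profile((rows, cols), les.center, les.radius_px)
            contribution = les.contrast * profile
            if les.texture_sigma > 0:
                texture = ndimage.gaussian_filter(
                    rng.standard_normal((rows, cols)), sigma=1.2)
                texture *= les.texture_sigma / max(texture.std(), 1e-12)
                contribution += texture * (profile > 0.05)
            img += np.where(bmask, contribution, 0.0)
            slice_gt |= (les.contrast * profile > HALF_PEAK * les.contrast) & bmask

        mimic_fp = np.zeros((rows, cols), dtype=bool)
        for mim in mimics_by_slice.get(z, []):
            mimic_fp |= _paint_mimic(img, bmask, mim, wm, spec.noise_sigma, rng)
        collision = mimic_fp & slice_gt
        if collision.any():
            # lesions win: re-deposit their intensity over the mimic
            log.info("slice %d: %d colliding voxels resolved to lesions",
                     z, int(collision.sum()))
            for les in lesions_by_slice.get(z, []):
                profile = _lesion_profile((rows, cols), les.center, les.radius_px)
                inside = (profile > HALF_PEAK) & collision
                img[inside] = means[2] + les.contrast * profile[inside]

        gt[z] = slice_gt
        img *= _bias_field((rows, cols), spec.bias_amplitude, rng)
        if spec.rician:
            n1 = rng.normal(0, spec.noise_sigma, (rows, cols))
            n2 = rng.normal(0, spec.noise_sigma, (rows, cols))
            img = np.sqrt((img + n1) ** 2 + n2**2)
        else:
            img = img + rng.normal(0, spec.noise_sigma, (rows, cols))
        img[~bmask] = 0.0
        flair[z] = img

    voxels = np.clip(np.rint(flair), 0, 65535).astype(np.int64)
    return PhantomBundle(
        flair=GrayVolume(voxels, spec.geometry, scale_max=65535),
        brain=BinaryMask(brain),
        gt_lesions=BinaryMask(gt),
        gt_tissue=tissue,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

_PROFILES = {
    # lesion count range, half-peak radius range (px), slices spanned per lesion
    "mild": {"n_lesions": (4, 8), "radius": (2.0, 4.0), "span": (1, 1)},
    "moderate": {"n_lesions": (12, 16), "radius": (6.0, 9.0), "span": (3, 4)},
    "severe": {"n_lesions": (16, 20), "radius": (11.0, 15.0), "span": (5, 7)},
}
_LOAD_BOUNDS = {"mild": (0.0, 5.0), "moderate": (5.0, 15.0),
                "severe": (15.0, float("inf"))}


def _sample_spec(profile: str, rng: np.random.Generator, seed: int,
                 n_mimics=(5, 8), **overrides) -> PhantomSpec:
    base = PhantomSpec(seed=seed, **overrides)
    prof = _PROFILES[profile]
    rows, cols = base.slice_dims
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    n_lesions = int(rng.integers(prof["n_lesions"][0], prof["n_lesions"][1] + 1))
    lesions: list[LesionSpec] = []
    for _ in range(n_lesions):
        # place within the WM bulk: elliptical radius below the GM ribbon
        while True:
            r = rng.uniform(0.15 * rows, 0.85 * rows)
            c = rng.uniform(0.15 * cols, 0.85 * cols)
            rho = np.sqrt(((r - cy) / (0.42 * rows)) ** 2
                          + ((c - cx) / (0.45 * cols)) ** 2)
            ventricle = abs(c - cx) < 0.16 * cols and abs(r - cy) < 0.14 * rows
            if rho < 0.72 and not ventricle:
                break
        radius = rng.uniform(*prof["radius"])
        contrast = rng.uniform(10.0, 14.0) * base.noise_sigma
        texture = rng.uniform(0.3, 0.7) * base.noise_sigma
        span = int(rng.integers(prof["span"][0], prof["span"][1] + 1))
        z0 = int(rng.integers(1, max(2, base.n_slices - span)))
        for dz in range(span):
            shrink = 1.0 - 0.25 * dz / max(1, span - 1) if span > 1 else 1.0
            lesions.append(LesionSpec(z0 + dz, (r, c), radius * shrink,
                                      contrast, texture))
    mimics: list[MimicSpec] = []
    n_mim = int(rng.integers(n_mimics[0], n_mimics[1] + 1))
    kinds = ["streak", "rim_fragment", "punctate_noise"]
    for _ in range(n_mim):
        kind = kinds[int(rng.integers(0, 3))]
        z = int(rng.integers(0, base.n_slices))
        if kind == "streak":
            params = {"start": (float(rng.uniform(0.3 * rows, 0.7 * rows)),
                                float(rng.uniform(0.25 * cols, 0.6 * cols))),
                      "angle": float(rng.uniform(0, np.pi)),
                      "length": int(rng.integers(10, 18)),
                      "width": 2,
                      "contrast": float(rng.uniform(5.5, 8.0))}
        elif kind == "rim_fragment":
            params = {"theta0": float(rng.uniform(-np.pi, np.pi)),
                      "span": float(rng.uniform(0.4, 0.9)),
                      "depth": 2,
                      "contrast": float(rng.uniform(5.5, 8.0))}
        else:
            while True:
                r = rng.uniform(0.2 * rows, 0.8 * rows)
                c = rng.uniform(0.2 * cols, 0.8 * cols)
                rho = np.sqrt(((r - cy) / (0.42 * rows)) ** 2
                              + ((c - cx) / (0.45 * cols)) ** 2)
                if rho < 0.72:
                    break
            params = {"center": (float(r), float(c)),
                      "radius": float(rng.uniform(2.0, 3.0)),
                      "contrast": float(rng.uniform(5.5, 8.0))}
        mimics.append(MimicSpec(kind, z, params))
    return replace(base, lesions=tuple(lesions), fp_mimics=tuple(mimics))


def generate_cohort(
    n_subjects: int,
    load_profile: str = "mild",
    seed: int = 0,
    max_resample: int = 25,
    **spec_overrides,
) -> list[PhantomBundle]:
    """Phantom subjects whose GT loads fall inside the requested stratum.

    ``load_profile`` is mild, moderate, severe, or mixed; out-of-stratum draws
    are rejection-resampled (the load is verified on the rendered GT mask).
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    bundles = []
    for s in range(n_subjects):
        profile = (load_profile if load_profile != "mixed"
                   else ["mild", "moderate", "severe"][int(rng.integers(0, 3))])
        lo, hi = _LOAD_BOUNDS[profile]
        for attempt in range(max_resample):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            spec = _sample_spec(profile, rng, sub_seed, **spec_overrides)
            bundle = generate_phantom(spec)
            load = (bundle.gt_lesions.count()
                    * spec.geometry.voxel_volume_mm3 / 1000.0)
            if lo <= load < hi or (profile == "severe" and load >= lo):
                bundles.append(bundle)
                break
        else:
            raise RuntimeError(
                f"could not draw a {profile} phantom within {max_resample} tries")
    return bundles


def generate_training_set(
    cohort,
    imbalance_ratio: float = 7.4,
    config: dict | None = None,
    seed: int = 0,
):
    """Detection + feature extraction + GT labelling over a cohort.

    Returns ``(TrainingSet, DataFrame)``; the class imbalance (non-WML per
    WML) is matched to ``imbalance_ratio`` by seeded subsampling of the
    over-represented class. Raises if either class is missing.
    """
    from .classifier import NON_WML, WML, TrainingSet, overlap_fraction
    from .config import DEFAULTS, merge_config
    from .detection import detect_candidates
    from .features import extract_features, features_frame
    from .pipeline import standardize_cohort

    cfg = merge_config(DEFAULTS, config or {})
    det = cfg["detection"]
    feat = cfg["features"]
    std_volumes, _ = standardize_cohort(cohort, cfg)
    rows_X, rows_y, rows_id, rows_slice = [], [], [], []
    for bundle, std in zip(cohort, std_volumes):
        cands, _, _ = detect_candidates(
            std, bundle.brain, trim_fraction=det["trim_fraction"],
            k_extreme=det["k_extreme"], min_area=det["min_area"],
            margin_px=det["margin_px"])
        for cand in cands:
            f = extract_features(
                cand, n_clusters=feat["n_clusters"],
                orientation_deg=feat["orientation_deg"],
                distance=feat["distance"], quantizer=feat["quantizer"],
                glcm_scope=feat["glcm_scope"], seed=seed)
            frac = overlap_fraction(cand, bundle.gt_lesions.voxels[cand.slice_index])
            rows_X.append(f.as_vector())
            rows_y.append(WML if frac > 0 else NON_WML)
            rows_id.append(cand.id)
            rows_slice.append(cand.slice_index)
    if not rows_X:
        raise ValueError("cohort produced no candidates")
    X = np.vstack(rows_X)
    y = np.array(rows_y)
    ids = np.array(rows_id)
    n_wml = int((y == WML).sum())
    n_non = int((y == NON_WML).sum())
    if n_wml == 0 or n_non == 0:
        raise ValueError(
            f"cohort yielded a single class (WML={n_wml}, non-WML={n_non}); "
            "add mimics or lesions")
    rng = np.random.default_rng(seed)
    keep = np.ones(y.size, dtype=bool)
    if not np.isfinite(imbalance_ratio):
        pass  # keep every candidate: the detector's own output ratio
    elif n_non > imbalance_ratio * n_wml:
        target = max(1, int(round(imbalance_ratio * n_wml)))
        drop = rng.choice(np.flatnonzero(y == NON_WML), n_non - target,
                          replace=False)
        keep[drop] = False
    elif n_wml > n_non / imbalance_ratio:
        target = max(1, int(round(n_non / imbalance_ratio)))
        drop = rng.choice(np.flatnonzero(y == WML), n_wml - target,
                          replace=False)
        keep[drop] = False
    ts = TrainingSet(X[keep], y[keep], ids[keep])
    frame = features_frame_from_arrays(X[keep], ids[keep],
                                       np.array(rows_slice)[keep], y[keep])
    return ts, frame


def features_frame_from_arrays(X, ids, slices, labels):
    import pandas as pd

    from .features import FEATURE_NAMES

    frame = pd.DataFrame(X, columns=list(FEATURE_NAMES))
    frame.insert(0, "slice_index", slices)
    frame.insert(0, "candidate_id", ids)
    frame["label"] = labels
    return frame
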