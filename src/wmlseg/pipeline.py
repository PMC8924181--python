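"""End-to-end orchestration: standardize -> detect -> classify -> refine.

``fit_pipeline`` learns everything the segmentation stage needs from a
training cohort with ground truth:

1. the standard intensity scale (cohort-average landmarks),
2. the random-forest candidate classifier, and
3. the LOF intensity model (standardized intensities of GT lesion voxels).

``segment_volume`` then runs the full chain on a new volume and returns the
final refined mask along with the intermediate TMOD union mask and
per-candidate decisions, so callers can audit each stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .classifier import WML, RFConfig, TrainedModel, TrainingSet, train
from .config import DEFAULTS, merge_config
from .detection import detect_candidates
from .features import extract_features
from .imaging import BinaryMask, GrayVolume
from .lof import LOFModel, fit_lof_model, refine_boundary
from .preprocess import fit_landmark_map, fit_standard_scale, standardize

__all__ = ["PipelineModel", "fit_pipeline", "segment_volume", "standardize_cohort"]

log = logging.getLogger(__name__)

PIPELINE_FORMAT_VERSION = 1


def standardize_cohort(bundles, config: dict, target_landmarks=None):
    """Standardize every bundle; targets learned from the cohort if absent."""
    std_cfg = config["standardization"]
    volumes = [b.flair for b in bundles]
    brains = [b.brain for b in bundles]
    if target_landmarks is None:
        target_landmarks = fit_standard_scale(
            volumes, brains, percentiles=std_cfg["percentiles"],
            target_scale=std_cfg["target_levels"], headroom=std_cfg["headroom"])
    out = []
    for vol, brn in zip(volumes, brains):
        lmap = fit_landmark_map(
            vol, brn, percentiles=std_cfg["percentiles"],
            target_scale=std_cfg["target_levels"],
            target_landmarks=target_landmarks, headroom=std_cfg["headroom"])
        out.append(standardize(vol, lmap))
    return out, np.asarray(target_landmarks, dtype=float)


@dataclass
class PipelineModel:
    """Everything segmentation needs, serializable to a single JSON file."""

    target_landmarks: np.ndarray
    forest: TrainedModel
    lof_reference: np.ndarray
    config: dict

    def lof_model(self, threshold: float | None = None) -> LOFModel:
        lof_cfg = self.config["lof"]
        return LOFModel(
            self.lof_reference,
            min_pts=min(lof_cfg["min_pts"], self.lof_reference.size - 1),
            threshold=lof_cfg["threshold"] if threshold is None else threshold,
        )

    def save(self, path: str | Path) -> None:
        doc = {
            "format_version": PIPELINE_FORMAT_VERSION,
            "target_landmarks": np.asarray(self.target_landmarks).tolist(),
            "forest": json.loads(self.forest.to_json()),
            "lof_reference": np.asarray(self.lof_reference).tolist(),
            "config": self.config,
        }
        Path(path).write_text(json.dumps(doc, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineModel":
        doc = json.loads(Path(path).read_text())
        if doc.get("format_version") != PIPELINE_FORMAT_VERSION:
            raise ValueError("unsupported pipeline model version")
        return cls(
            target_landmarks=np.asarray(doc["target_landmarks"], float),
            forest=TrainedModel.from_json(json.dumps(doc["forest"])),
            lof_reference=np.asarray(doc["lof_reference"], float),
            config=doc["config"],
        )


def fit_pipeline(train_bundles, config: dict | None = None, seed: int = 0
                 ) -> PipelineModel:
    """Learn scale, classifier, and LOF intensity model from a labelled cohort."""
    from .phantom import generate_training_set  # circular-safe local import

    cfg = merge_config(DEFAULTS, config or {})
    std_volumes, targets = standardize_cohort(train_bundles, cfg)

    # training set straight from the cohort (no imbalance adjustment: the
    # detector's own output ratio is the training distribution)
    ts, _ = generate_training_set(train_bundles, imbalance_ratio=float("inf"),
                                  config=cfg, seed=seed)
    rf_cfg = RFConfig(
        n_trees=cfg["rf"]["n_trees"], max_depth=cfg["rf"]["max_depth"],
        n_folds=cfg["rf"]["n_folds"], seed=seed,
        decision_threshold=cfg["rf"]["decision_threshold"],
        class_weight=cfg["rf"]["class_weight"])
    forest = train(ts, rf_cfg)

    reference = np.concatenate([
        std.voxels[b.gt_lesions.voxels]
        for std, b in zip(std_volumes, train_bundles)
        if b.gt_lesions.voxels.any()
    ]).astype(float)
    if reference.size < 2:
        raise ValueError("training cohort has no ground-truth lesion voxels")
    lof_cfg = cfg["lof"]
    lof = fit_lof_model(reference, min_pts=lof_cfg["min_pts"],
                        threshold=lof_cfg["threshold"],
                        max_reference=lof_cfg["max_reference"], seed=seed)
    return PipelineModel(targets, forest, lof.reference, cfg)


@dataclass
class SegmentationResult:
    final_mask: BinaryMask
    tmod_mask: BinaryMask
    standardized: GrayVolume
    candidates: list
    accepted: np.ndarray      # bool per candidate
    scores: np.ndarray        # RF vote fraction per candidate


def segment_volume(
    flair: GrayVolume,
    brain: BinaryMask,
    model: PipelineModel,
    lof_threshold: float | None = None,
    seed: int = 0,
) -> SegmentationResult:
    """Full segmentation of one volume with a fitted pipeline model."""
    cfg = model.config
    std_cfg = cfg["standardization"]
    det = cfg["detection"]
    feat = cfg["features"]
    lmap = fit_landmark_map(
        flair, brain, percentiles=std_cfg["percentiles"],
        target_scale=std_cfg["target_levels"],
        target_landmarks=model.target_landmarks, headroom=std_cfg["headroom"])
    std = standardize(flair, lmap)
    cands, tmod_mask, _ = detect_candidates(
        std, brain, trim_fraction=det["trim_fraction"],
        k_extreme=det["k_extreme"], min_area=det["min_area"],
        margin_px=det["margin_px"])
    final = np.zeros(std.voxels.shape, dtype=bool)
    accepted = np.zeros(len(cands), dtype=bool)
    scores = np.zeros(len(cands))
    if cands:
        feats = [
            extract_features(
                c, n_clusters=feat["n_clusters"],
                orientation_deg=feat["orientation_deg"],
                distance=feat["distance"], quantizer=feat["quantizer"],
                glcm_scope=feat["glcm_scope"], seed=seed)
            for c in cands
        ]
        from .classifier import classify

        labels, scores = classify(model.forest, feats)
        lof = model.lof_model(lof_threshold)
        for k, cand in enumerate(cands):
            if labels[k] != WML:
                continue
            accepted[k] = True
            refined = refine_boundary(cand, lof)
            if refined.dropped:
                continue
            r0, c0 = cand.patch_origin
            h, w = refined.refined_mask.shape
            final[cand.slice_index, r0 : r0 + h, c0 : c0 + w] |= refined.refined_mask
    final &= brain.voxels
    return SegmentationResult(
        final_mask=BinaryMask(final),
        tmod_mask=tmod_mask,
        standardized=std,
        candidates=cands,
        accepted=accepted,
        scores=np.asarray(scores, dtype=float),
    )
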