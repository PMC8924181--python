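"""Shared fixtures: small constructed volumes and the synthetic benchmark.

The mild-load benchmark (10 training / 10 held-out phantoms, full pipeline)
is expensive enough to share: it is computed once per session and reused by
the pipeline and acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

import wmlseg as w
from wmlseg.classifier import classify, overlap_fraction
from wmlseg.evaluation import confusion, evaluate_masks
from wmlseg.features import extract_features
from wmlseg.pipeline import fit_pipeline, segment_volume


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture()
def flat_brain():
    """A 3-slice all-brain volume of WM-like noise, for detection tests."""
    gen = np.random.default_rng(7)
    vox = np.clip(np.rint(gen.normal(5000, 80, (3, 48, 48))), 0, None)
    return w.GrayVolume(vox.astype(np.int64), scale_max=8191), w.BinaryMask(
        np.ones((3, 48, 48), bool))


@dataclass
class BenchmarkRun:
    model: object
    train_bundles: list
    test_bundles: list
    results: list       # SegmentationResult per test phantom
    reports: list       # EvaluationReport per test phantom
    tmod_counts: list   # ConfusionCounts of the TMOD-only mask
    holdout_truth: np.ndarray
    holdout_pred: np.ndarray


@pytest.fixture(scope="session")
def mild_benchmark() -> BenchmarkRun:
    """Seeded mild-load cohorts, fitted pipeline, and per-phantom evaluations."""
    train = w.generate_cohort(10, "mild", seed=11)
    test = w.generate_cohort(10, "mild", seed=99)
    model = fit_pipeline(train, seed=0)
    results, reports, tmod_counts = [], [], []
    truths, preds = [], []
    for bundle in test:
        res = segment_volume(bundle.flair, bundle.brain, model)
        results.append(res)
        reports.append(evaluate_masks(res.final_mask, bundle.gt_lesions,
                                      bundle.brain, bundle.flair.geometry))
        tmod_counts.append(confusion(res.tmod_mask, bundle.gt_lesions,
                                     bundle.brain))
        if res.candidates:
            feats = [extract_features(c) for c in res.candidates]
            labels, _ = classify(model.forest, feats)
            gt = bundle.gt_lesions.voxels
            truth = np.array([
                w.WML if overlap_fraction(c, gt[c.slice_index]) > 0 else w.NON_WML
                for c in res.candidates])
            truths.append(truth)
            preds.append(labels)
    return BenchmarkRun(
        model=model, train_bundles=train, test_bundles=test,
        results=results, reports=reports, tmod_counts=tmod_counts,
        holdout_truth=np.concatenate(truths),
        holdout_pred=np.concatenate(preds),
    )
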