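"""Random-forest lesion / non-lesion classification of candidates.

The forest (default 25 trees of depth at most 25, Gini splits, bootstrap
sampling) separates true lesions from hyperintense mimics using the ten
histogram + GLCM features. Training labels come from overlap with ground
truth; by default any overlap marks a candidate as WML, mirroring the
match/non-match dichotomy used to build the original training set, and the
class imbalance is left as-is.

Trained models serialize to a versioned JSON document that stores every tree
explicitly (children, split feature, threshold, leaf class counts); predictions
are always served by traversing the stored arrays, so a reloaded model is
bit-identical to the freshly trained one regardless of library version.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold

from .features import FEATURE_NAMES

__all__ = [
    "RFConfig",
    "TrainingSet",
    "TrainedModel",
    "WML",
    "NON_WML",
    "build_training_set",
    "train",
    "cross_validate",
    "classify",
]

WML = "WML"
NON_WML = "non-WML"

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class RFConfig:
    n_trees: int = 25
    max_depth: int = 25
    n_folds: int = 10
    seed: int = 0
    decision_threshold: float = 0.5
    class_weight: str | None = None

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.max_depth < 1 or self.n_folds < 2:
            raise ValueError("invalid forest configuration")


@dataclass
class TrainingSet:
    features: np.ndarray              # (n, 10)
    labels: np.ndarray                # array of WML / NON_WML strings
    candidate_ids: np.ndarray
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if not np.all(np.isfinite(self.features)):
            raise ValueError("non-finite feature rows")
        for cls in (WML, NON_WML):
            if not (self.labels == cls).any():
                raise ValueError(f"training set has no {cls} samples")

    @property
    def class_counts(self) -> dict[str, int]:
        return {cls: int((self.labels == cls).sum()) for cls in (WML, NON_WML)}


def overlap_fraction(candidate, gt_slice: np.ndarray) -> float:
    """Fraction of the candidate's component pixels lying on ground truth."""
    r0, c0 = candidate.patch_origin
    h, w = candidate.mask.shape
    gt_patch = gt_slice[r0 : r0 + h, c0 : c0 + w]
    inter = int((candidate.mask & gt_patch).sum())
    return inter / candidate.area_px


def build_training_set(candidates, gt_mask, features, overlap_rule: float = 0.0
                       ) -> TrainingSet:
    """Label candidates by ground-truth overlap and bundle their features.

    A candidate is WML when the overlapping fraction of its pixels exceeds
    ``overlap_rule`` (default 0: any overlap counts).
    """
    if not candidates:
        raise ValueError("no candidates to label")
    gt = gt_mask.voxels if hasattr(gt_mask, "voxels") else np.asarray(gt_mask, bool)
    labels = []
    for cand in candidates:
        frac = overlap_fraction(cand, gt[cand.slice_index])
        is_wml = frac > 0 if overlap_rule <= 0 else frac >= overlap_rule
        labels.append(WML if is_wml else NON_WML)
    X = np.vstack([f.as_vector() for f in features])
    ids = np.array([c.id for c in candidates])
    return TrainingSet(X, np.array(labels), ids)


# ---------------------------------------------------------------------------
# Portable forest serialization
# ---------------------------------------------------------------------------

def _extract_trees(forest: RandomForestClassifier, class_order) -> list[dict]:
    # sklearn's classes_ are sorted; map leaf count columns onto (NON_WML, WML)
    col = {cls: k for k, cls in enumerate(forest.classes_)}
    trees = []
    for est in forest.estimators_:
        t = est.tree_
        value = t.value.reshape(t.node_count, -1)
        counts = np.zeros((t.node_count, 2))
        for k, cls in enumerate(class_order):
            counts[:, k] = value[:, col[cls]]
        trees.append({
            "children_left": t.children_left.tolist(),
            "children_right": t.children_right.tolist(),
            "feature": t.feature.tolist(),
            "threshold": t.threshold.tolist(),
            "class_counts": counts.tolist(),
        })
    return trees


@dataclass
class TrainedModel:
    """A serialized forest plus its feature-order contract."""

    trees: list[dict]
    feature_names: tuple[str, ...]
    config: RFConfig
    class_order: tuple[str, str] = (NON_WML, WML)
    cv_accuracy: float | None = None
    format_version: int = MODEL_FORMAT_VERSION
    _tree_arrays: list | None = field(default=None, repr=False)

    def _arrays(self):
        if self._tree_arrays is None:
            self._tree_arrays = [
                (
                    np.asarray(t["children_left"], dtype=np.int64),
                    np.asarray(t["children_right"], dtype=np.int64),
                    np.asarray(t["feature"], dtype=np.int64),
                    np.asarray(t["threshold"], dtype=float),
                    np.asarray(t["class_counts"], dtype=float),
                )
                for t in self.trees
            ]
        return self._tree_arrays

    def vote_scores(self, X: np.ndarray) -> np.ndarray:
        """Fraction of trees voting WML for each row of X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != len(self.feature_names):
            raise ValueError("feature order/length does not match the model contract")
        votes = np.zeros(X.shape[0])
        for left, right, feat, thr, counts in self._arrays():
            node = np.zeros(X.shape[0], dtype=np.int64)
            active = left[node] != -1
            while active.any():
                f = feat[node[active]]
                go_left = X[active, f] <= thr[node[active]]
                nxt = np.where(go_left, left[node[active]], right[node[active]])
                node[active] = nxt
                active = left[node] != -1
            leaf_counts = counts[node]
            # per-tree hard vote; ties resolve to the first class (non-WML)
            votes += leaf_counts[:, 1] > leaf_counts[:, 0]
        return votes / len(self.trees)

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "format_version": self.format_version,
            "model": "random_forest",
            "class_order": list(self.class_order),
            "feature_names": list(self.feature_names),
            "config": {
                "n_trees": self.config.n_trees,
                "max_depth": self.config.max_depth,
                "n_folds": self.config.n_folds,
                "seed": self.config.seed,
                "decision_threshold": self.config.decision_threshold,
                "class_weight": self.config.class_weight,
            },
            "cv_accuracy": self.cv_accuracy,
            "trees": self.trees,
        }
        text = json.dumps(doc, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TrainedModel":
        s = str(source)
        if isinstance(source, Path) or (len(s) < 4096 and Path(s).exists()):
            text = Path(s).read_text()
        else:
            text = s
        doc = json.loads(text)
        if doc.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        cfg = RFConfig(**doc["config"])
        return cls(
            trees=doc["trees"],
            feature_names=tuple(doc["feature_names"]),
            config=cfg,
            class_order=tuple(doc["class_order"]),
            cv_accuracy=doc.get("cv_accuracy"),
        )


def train(ts: TrainingSet, cfg: RFConfig = RFConfig()) -> TrainedModel:
    """Fit the forest; deterministic given ``cfg.seed``."""
    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_depth=cfg.max_depth,
        criterion="gini",
        max_features=int(np.ceil(np.sqrt(len(ts.feature_names)))),
        bootstrap=True,
        class_weight=cfg.class_weight,
        random_state=cfg.seed,
        n_jobs=1,
    )
    forest.fit(ts.features, ts.labels)
    class_order = (NON_WML, WML)
    return TrainedModel(
        trees=_extract_trees(forest, class_order),
        feature_names=tuple(ts.feature_names),
        config=cfg,
        class_order=class_order,
    )


def classify(model: TrainedModel, features) -> tuple[np.ndarray, np.ndarray]:
    """Labels and vote-fraction scores for candidate feature rows.

    ``features`` may be a (n, 10) array, a single CandidateFeatures, or a list
    of them. The label is WML when score >= the model's decision threshold.
    """
    if hasattr(features, "as_vector"):
        X = features.as_vector()[None, :]
    elif isinstance(features, (list, tuple)) and features and hasattr(features[0], "as_vector"):
        X = np.vstack([f.as_vector() for f in features])
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
    scores = model.vote_scores(X)
    labels = np.where(scores >= model.config.decision_threshold, WML, NON_WML)
    return labels, scores


# ---------------------------------------------------------------------------
# Cross-validation harness
# ---------------------------------------------------------------------------

def stratified_fold_accuracy(X, y, cfg: RFConfig) -> float:
    """Mean accuracy over stratified folds, fold assignment seeded by cfg.seed."""
    skf = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    accs = []
    for train_idx, test_idx in skf.split(X, y):
        if np.unique(y[train_idx]).size < 2:
            raise ValueError("a training fold contains a single class")
        ts = TrainingSet(X[train_idx], y[train_idx],
                         candidate_ids=np.asarray(train_idx))
        model = train(ts, cfg)
        pred, _ = classify(model, X[test_idx])
        accs.append(float((pred == y[test_idx]).mean()))
    return float(np.mean(accs))


def cross_validate(
    candidates,
    labels,
    cfg: RFConfig = RFConfig(),
    param_grid=None,
    glcm_scope: str = "patch",
):
    """Stratified k-fold accuracy over a feature-parameter grid.

    For each grid point (``n_clusters``, ``orientation_deg``, ``quantizer``)
    the ten features are re-extracted from the raw candidate patches with
    those parameters, then the forest is scored by stratified cross-validation
    and the mean fold accuracy recorded. Returns a pandas DataFrame.
    """
    import pandas as pd

    from .features import extract_features

    if param_grid is None:
        param_grid = {"n_clusters": [5], "orientation_deg": [0],
                      "quantizer": ["kmeans"]}
    y = np.asarray(labels)
    rows = []
    for quant in param_grid.get("quantizer", ["kmeans"]):
        for L in param_grid.get("n_clusters", [5]):
            for theta in param_grid.get("orientation_deg", [0]):
                X = np.vstack([
                    extract_features(c, n_clusters=L, orientation_deg=theta,
                                     quantizer=quant, glcm_scope=glcm_scope,
                                     seed=cfg.seed).as_vector()
                    for c in candidates
                ])
                acc = stratified_fold_accuracy(X, y, cfg)
                rows.append({"quantizer": quant, "n_clusters": L,
                             "orientation_deg": theta, "mean_accuracy": acc})
    return pd.DataFrame(rows)
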