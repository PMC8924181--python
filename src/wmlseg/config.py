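"""Pipeline configuration: defaults plus YAML overrides.

The configuration is a plain nested dict so it serialises trivially and the CLI
can pass it around; :func:`load_config` deep-merges a YAML file over the
defaults. Keys mirror the pipeline stages.
"""

from __future__ import annotations

import copy
import logging
import sys
from pathlib import Path
from typing import Any

import yaml

__all__ = ["DEFAULTS", "load_config", "merge_config", "setup_logging"]

DEFAULTS: dict[str, Any] = {
    "geometry": {
        "in_plane_spacing_mm": [0.4297, 0.4297],
        "slice_thickness_mm": 5.0,
        "inter_slice_gap_mm": 1.0,
    },
    "standardization": {
        # p1, deciles, p99 landmark set; target scale anchored with headroom so
        # hyperintensities above p99 extrapolate instead of saturating.
        "percentiles": [1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 99],
        "target_levels": 8192,
        "headroom": 0.8,
    },
    "fcm": {
        "n_classes": 3,
        "fuzzifier": 2.0,
        "tol": 1e-5,
        "max_iter": 300,
        "init": "percentile",  # deterministic init at percentiles {10, 50, 90}
    },
    "detection": {
        "trim_fraction": 0.2,
        "k_extreme": 3.0,   # Tukey extreme fence: q3 + 3 * IQR
        "min_area": 3,
        "margin_px": 2,
    },
    "features": {
        "n_clusters": 5,
        "orientation_deg": 0,
        "distance": 1,
        "quantizer": "kmeans",     # or "quantile"
        "glcm_scope": "patch",     # or "mask": restrict GLCM to candidate mask
    },
    "rf": {
        "n_trees": 25,
        "max_depth": 25,
        "n_folds": 10,
        "decision_threshold": 0.5,
        "class_weight": None,       # train on the detector's natural imbalance
        "overlap_rule": 0.0,        # any overlap with ground truth labels WML
    },
    "lof": {
        "min_pts": 20,
        "threshold": 1.5,
        "feature_space": "intensity",  # or "local": (intensity, 3x3 mean, 3x3 std)
        "max_reference": 10000,
    },
}


def merge_config(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = merge_config(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None) -> dict:
    """Defaults, optionally overridden by a YAML file."""
    if path is None:
        return copy.deepcopy(DEFAULTS)
    with open(path) as fh:
        override = yaml.safe_load(fh) or {}
    if not isinstance(override, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return merge_config(DEFAULTS, override)


def setup_logging(verbose: bool = False) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s: %(message)s",
    )
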