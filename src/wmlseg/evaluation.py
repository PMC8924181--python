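"""Segmentation metrics, volumetrics, and agreement statistics.

Voxelwise confusion counts within the brain mask feed six metrics: Dice (DI),
Jaccard (JI), true-positive rate, false-positive rate, positive predictive
value, and signed volume difference. Two conventions deserve emphasis:

* ``FPR = FP / (TP + TN)`` — this is the definition used in the MICCAI MS
  lesion challenge tables this toolkit mirrors, *not* the conventional
  ``FP / (FP + TN)``; the conventional form is exposed separately as
  ``fpr_conventional`` to avoid silent ambiguity.
* ``VD = (Vol(auto) - Vol(GT)) / Vol(GT)`` is signed, so undersegmentation is
  negative; a completely missed segmentation gives VD = -1.

Subject-level lesion loads are stratified as mild (< 5 mL), moderate
(5-15 mL, boundaries inclusive), and severe (> 15 mL). Agreement between two
volume series uses the two-way random-effects, single-measure, absolute
agreement intraclass correlation ICC(2,1) with an F-based 95% CI, plus
Pearson/Spearman correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .imaging import BinaryMask, VolumeGeometry

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "confusion",
    "metrics",
    "evaluate_masks",
    "icc_absolute_agreement",
    "correlations",
    "stratify_load",
    "paired_tests_bonferroni",
]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class EvaluationReport:
    DI: float
    JI: float
    TPR: float
    FPR: float
    PPV: float
    VD: float
    fpr_conventional: float
    vol_auto_ml: float
    vol_gt_ml: float
    load_group: str
    counts: ConfusionCounts
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "DI": self.DI, "JI": self.JI, "TPR": self.TPR, "FPR": self.FPR,
            "PPV": self.PPV, "VD": self.VD,
            "fpr_conventional": self.fpr_conventional,
            "vol_auto_ml": self.vol_auto_ml, "vol_gt_ml": self.vol_gt_ml,
            "load_group": self.load_group,
            "counts": {"TP": self.counts.TP, "FP": self.counts.FP,
                       "FN": self.counts.FN, "TN": self.counts.TN},
            "notes": list(self.notes),
        }


def confusion(pred: BinaryMask, truth: BinaryMask, brain: BinaryMask
              ) -> ConfusionCounts:
    """Voxelwise confusion counts restricted to the brain mask."""
    p, t, b = pred.voxels, truth.voxels, brain.voxels
    if not (p.shape == t.shape == b.shape):
        raise ValueError("mask shapes differ")
    p = p & b
    t = t & b
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    fn = int((~p & t).sum())
    tn = int(b.sum()) - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: float, den: float, notes: list[str], name: str) -> float:
    if den == 0:
        notes.append(f"{name} undefined: zero denominator")
        return float("nan")
    return num / den


def metrics(c: ConfusionCounts, geometry: VolumeGeometry = VolumeGeometry()
            ) -> EvaluationReport:
    """The six segmentation metrics plus volumes in mL."""
    notes: list[str] = []
    tp, fp, fn, tn = c.TP, c.FP, c.FN, c.TN
    di = _ratio(2 * tp, 2 * tp + fp + fn, notes, "DI")
    ji = _ratio(tp, tp + fp + fn, notes, "JI")
    tpr = _ratio(tp, tp + fn, notes, "TPR")
    fpr = _ratio(fp, tp + tn, notes, "FPR")
    ppv = _ratio(tp, tp + fp, notes, "PPV")
    vox_ml = geometry.voxel_volume_mm3 / 1000.0
    vol_auto = (tp + fp) * vox_ml
    vol_gt = (tp + fn) * vox_ml
    if vol_gt > 0:
        vd = (vol_auto - vol_gt) / vol_gt
    elif vol_auto > 0:
        vd = float("inf")
        notes.append("VD infinite: empty ground truth with non-empty prediction")
    else:
        vd = float("nan")
        notes.append("VD undefined: both volumes empty")
    fpr_conv = _ratio(fp, fp + tn, notes, "fpr_conventional")
    return EvaluationReport(
        DI=di, JI=ji, TPR=tpr, FPR=fpr, PPV=ppv, VD=vd,
        fpr_conventional=fpr_conv,
        vol_auto_ml=vol_auto, vol_gt_ml=vol_gt,
        load_group=stratify_load(vol_gt),
        counts=c, notes=tuple(notes),
    )


def evaluate_masks(pred: BinaryMask, truth: BinaryMask, brain: BinaryMask,
                   geometry: VolumeGeometry = VolumeGeometry()) -> EvaluationReport:
    """Convenience wrapper: confusion + metrics in one call."""
    return metrics(confusion(pred, truth, brain), geometry)


def stratify_load(gt_volume_ml: float) -> str:
    """mild < 5 mL; moderate 5-15 mL (boundaries inclusive); severe > 15 mL."""
    if gt_volume_ml < 0:
        raise ValueError("volume must be non-negative")
    if gt_volume_ml < 5.0:
        return "mild"
    if gt_volume_ml <= 15.0:
        return "moderate"
    return "severe"


# ---------------------------------------------------------------------------
# Agreement statistics
# ---------------------------------------------------------------------------

def icc_absolute_agreement(rater_a, rater_b, alpha: float = 0.05
                           ) -> tuple[float, tuple[float, float]]:
    """ICC(2,1): two-way random effects, single measure, absolute agreement.

    Computed from the two-way ANOVA mean squares with the McGraw & Wong
    F-based confidence interval. Returns ``(icc, (ci_low, ci_high))``.
    """
    a = np.asarray(rater_a, dtype=float)
    b = np.asarray(rater_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("rater series must be equal-length 1-D")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    data = np.column_stack([a, b])
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ValueError("zero variance in both raters: ICC undefined")
    icc = (msr - mse) / denom

    # McGraw & Wong (1996) CI for ICC(A,1)
    if mse == 0:
        return float(icc), (float("nan"), float("nan"))
    fj = msc / mse
    vn = (k - 1) * (n - 1) * (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2
    vd = (n - 1) * k**2 * icc**2 * fj**2 + (n * (1 + (k - 1) * icc) - k * icc) ** 2
    v = vn / vd
    f_low = stats.f.ppf(1 - alpha / 2, n - 1, v)
    f_up = stats.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_low * mse) / (
        f_low * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_up * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_up * msr)
    return float(icc), (float(lower), float(upper))


def correlations(a, b) -> dict:
    """Pearson r with t-based p-value, and Spearman rho (average ranks on ties)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size or a.size < 3:
        raise ValueError("need two equal-length series with n >= 3")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("zero variance: correlation undefined")
    pear = stats.pearsonr(a, b)
    spear = stats.spearmanr(a, b)
    return {
        "pearson_r": float(pear.statistic),
        "pearson_p": float(pear.pvalue),
        "spearman_rho": float(spear.statistic),
        "spearman_p": float(spear.pvalue),
    }


def paired_tests_bonferroni(reference, others: dict, n_comparisons: int | None = None
                            ) -> dict:
    """Two-sided paired t-tests of ``reference`` against each series in
    ``others``, Bonferroni-corrected (default: multiplied by len(others))."""
    ref = np.asarray(reference, dtype=float)
    m = n_comparisons if n_comparisons is not None else len(others)
    out = {}
    for name, series in others.items():
        res = stats.ttest_rel(ref, np.asarray(series, dtype=float))
        out[name] = {
            "t": float(res.statistic),
            "p_corrected": float(min(1.0, res.pvalue * m)),
        }
    return out
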