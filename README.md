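# wmlseg

Segmentation of white-matter lesions (WML) in FLAIR MRI, aimed at the regime
where it is hardest: **mild lesion loads (< 5 mL)**, where the lesions are
punctate, boundaries are fuzzy, and naïve hyperintensity thresholds drown in
false positives from flow artefacts, residual skull, and noise.

`wmlseg` is a library plus a thin `wmlseg` CLI implementing a four-stage
pipeline for neuroimaging researchers who need reproducible lesion-load
measurements (e.g. for longitudinal studies of age-related white-matter
disease):

1. **Intensity standardization** — percentile-landmark piecewise-linear
   mapping of each scan onto a fixed scale of L = 8192 gray levels, so
   texture and brightness are comparable across scans and scanners.
2. **Candidate detection (TMOD)** — per axial slice, the normal-tissue
   intensity bulk is estimated with a symmetric 20% trimmed mean; quartiles
   of the trimmed distribution define a Tukey *extreme outlier* fence
   `q3 + 3·IQR`, and 8-connected components above the fence become lesion
   candidates.
3. **False-positive removal** — each candidate patch yields 10 features: six
   intensity-histogram statistics (μ, σ², skewness, kurtosis, energy,
   Shannon entropy) and four gray-level co-occurrence matrix (GLCM) texture
   features (contrast, energy, correlation, homogeneity) computed with an
   *embedded clustering* strategy: patch intensities are quantized by 1-D
   k-means (default L = 5 clusters) rather than equal-count binning before
   the co-occurrence matrix at offset d = (1, 0), θ = 0° is formed. A random
   forest (T = 25 trees, depth ≤ 25) classifies candidates as WML vs
   non-WML.
4. **Boundary refinement (LOF)** — voxels of each accepted candidate patch
   are scored with the Local Outlier Factor against a reference model of
   standardized lesion intensities from training ground truth; density
   inliers (LOF ≤ τ, default 1.5) form the final mask, which sharpens
   boundaries adaptively to the local neighborhood.

Evaluation mirrors the standard MS-lesion-challenge metrics — Dice and
Jaccard indices, TPR, PPV, FPR = FP/(TP+TN), signed volume difference
VD = (Vol(auto) − Vol(GT))/Vol(GT) — plus subject-level agreement statistics:
ICC(2,1) (two-way random effects, single measure, absolute agreement, with
F-based 95% CI), Pearson and Spearman correlations, and lesion-load
stratification (mild < 5 mL, moderate 5–15 mL, severe > 15 mL).

Because annotated clinical FLAIR data cannot be redistributed, the package
ships a **synthetic phantom generator** (`wmlseg.phantom`): multi-slice
FLAIR-like brains with CSF/GM/WM plateaus, residual bias field, noise,
steep-edged hyperintense lesions with controllable texture, and
false-positive mimics (streaks, rim fragments, speckled blobs). Every stage
is tested end-to-end against the known ground truth.

## Worked example

```python
import wmlseg as w
from wmlseg.pipeline import fit_pipeline, segment_volume
from wmlseg.evaluation import evaluate_masks, confusion

train = w.generate_cohort(6, "mild", seed=101)   # phantoms with ground truth
test  = w.generate_cohort(2, "mild", seed=202)

model = fit_pipeline(train, seed=0)
bundle = test[0]
res = segment_volume(bundle.flair, bundle.brain, model)
rep = evaluate_masks(res.final_mask, bundle.gt_lesions, bundle.brain,
                     bundle.flair.geometry)
tmod = confusion(res.tmod_mask, bundle.gt_lesions, bundle.brain)
print(rep.DI, rep.VD, tmod.FP, rep.counts.FP)
```

Running `python examples/03_full_pipeline.py` (the same computation) prints:

```
subject 0: 22 candidates, 5 kept by RF
  DI=0.813  JI=0.685  TPR=0.796 PPV=0.831  FPR=0.0004  VD=-0.043
  FP voxels: 178 (TMOD only) -> 30 (RF + LOF)
  volume: auto 0.164 mL vs GT 0.172 mL (mild load)
```

Reading: of 22 hyperintense candidates the forest kept 5 (the rest were
mimics or noise), the final mask overlaps ground truth with Dice 0.81, the
automated lesion load is within 5% of truth (VD −0.043), and the RF + LOF
stages cut false-positive voxels about sixfold relative to thresholding
alone — which is the pipeline's reason to exist.

The other scripts in `examples/` walk through phantom simulation and the
per-slice fences (`01`), the texture features that separate lesions from
mimics (`02`), and volume-agreement statistics (`04`).

## CLI

```bash
wmlseg simulate --profile mild --subjects 10 --seed 42 --out cohort/
wmlseg fit      --data cohort/ --out model.json --seed 0
wmlseg detect   --flair s.nii --brain-mask b.nii --out cand.nii --json cand.json
wmlseg segment  --flair s.nii --brain-mask b.nii --model model.json --out mask.nii
wmlseg evaluate --pred mask.nii --truth gt.nii --brain b.nii --report report.json
wmlseg train    --features feats.csv --out rf.json --cv   # RF only, from CSV
wmlseg classify --features feats.csv --model rf.json --out labels.csv
```

All commands are seeded; repeated runs are byte-identical.

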