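"""Generate one mild-load FLAIR phantom and look at its detection statistics.

Builds a 10-slice phantom with punctate hyperintense lesions and
false-positive mimics, standardizes it, and prints the per-slice boxplot
fences the TMOD stage derives: slices containing a lesion or mimic flag
`has_wml`, and the extreme threshold sits a few noise SD above the trimmed
white-matter bulk.
"""

import wmlseg as w

bundle = w.generate_cohort(1, "mild", seed=42)[0]
load = w.mask_volume_ml(bundle.gt_lesions, bundle.flair.geometry)
print(f"phantom: {bundle.flair.n_slices} slices {bundle.flair.shape[1:]}, "
      f"GT lesion load {load:.3f} mL ({bundle.gt_lesions.count()} voxels)")

lmap = w.fit_landmark_map(bundle.flair, bundle.brain)
std = w.standardize(bundle.flair, lmap)
candidates, union, thresholds = w.detect_candidates(std, bundle.brain)

print(f"\n{len(candidates)} candidates, union {union.count()} voxels")
print("slice  trimmed_mean      q3   fence  has_wml")
for t in thresholds:
    print(f"{t.slice_index:>5} {t.trimmed_mean:>13.1f} {t.q3:>7.1f} "
          f"{t.extreme_threshold:>7.1f}  {t.has_wml}")
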