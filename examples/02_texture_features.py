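"""Why texture separates true lesions from hyperintense mimics.

Extracts the ten classifier features (six intensity-histogram scalars, four
GLCM scalars on the k-means-quantized patch) for every candidate of one
phantom and prints them grouped by ground-truth label. True lesions are
smooth bright blobs: concentrated histograms (high energy, low entropy) and
homogeneous co-occurrence structure. Streak/speckle mimics are just as
bright but rough at fine scale: broader histograms and higher GLCM contrast.
That gap is what the random forest learns.
"""

import numpy as np

import wmlseg as w
from wmlseg.classifier import overlap_fraction
from wmlseg.features import FEATURE_NAMES

bundle = w.generate_cohort(1, "mild", seed=7)[0]
std = w.standardize(bundle.flair, w.fit_landmark_map(bundle.flair, bundle.brain))
candidates, _, _ = w.detect_candidates(std, bundle.brain)

rows = {"lesion": [], "mimic": []}
for cand in candidates:
    vec = w.extract_features(cand).as_vector()
    is_lesion = overlap_fraction(cand, bundle.gt_lesions.voxels[cand.slice_index]) > 0
    rows["lesion" if is_lesion else "mimic"].append(vec)

print(f"{len(rows['lesion'])} lesion candidates, {len(rows['mimic'])} mimic candidates\n")
print(f"{'feature':<18}{'lesion mean':>14}{'mimic mean':>14}")
for k, name in enumerate(FEATURE_NAMES):
    les = np.mean([v[k] for v in rows["lesion"]])
    mim = np.mean([v[k] for v in rows["mimic"]])
    print(f"{name:<18}{les:>14.3f}{mim:>14.3f}")
print("\nhist_variance/energy/entropy and glcm_contrast are the separating "
      "axes: mimics are bright like lesions but rough where lesions are smooth.")
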