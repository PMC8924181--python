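# Methods

This note records the models, conventions, and numerical choices behind
`wmlseg`, and what the synthetic benchmark does and does not demonstrate.

## Intensity standardization

MR intensity is scanner- and session-dependent, so raw FLAIR gray values are
not comparable across scans; every later stage (boxplot fences, histogram
features, the LOF intensity model) presumes a common scale. We use a
percentile-landmark piecewise-linear map in the Nyúl tradition:

- **Landmarks**: p1, the deciles p10…p90, and p99 of the brain-masked
  intensities (configurable, `standardization.percentiles`). Quantiles use
  linear interpolation between closest ranks (the "type 7" rule, numpy's
  default); this is fixed and documented because every later threshold
  depends on it.
- **Standard scale**: L = 8192 levels. The target landmarks are learned from
  a training cohort: each volume's source landmarks are anchored to
  [0, 0.8·(L−1)] and averaged. The 20% headroom is deliberate: intensities
  above p99 — which on FLAIR are exactly the hyperintense lesions — are
  mapped by linear extrapolation of the last landmark segment instead of
  saturating, and only clipped at the scale bound L−1. Without a cohort, a
  single-volume fallback places targets by linear rescaling of the source
  landmarks (an exactly affine-invariant map).
- Outputs are rounded to integers in [0, L−1]. The map is monotone
  non-decreasing; adjacent landmarks that tie (flat histogram stretches)
  are collapsed with a warning.
- Standardization is invariant under positive affine transforms of the
  input, and re-standardizing an already standardized volume against itself
  is the identity up to one gray level of rounding.

Inputs are assumed bias-corrected, skull-stripped, and co-registered;
inhomogeneity correction and registration are out of scope and the phantom
generator produces data in that state directly.

## Tissue segmentation

Fuzzy C-means on scalar intensities partitions the brain into CSF/GM/WM
(fuzzifier m = 2, tolerance 1e-5 on the center shift, ≤ 300 iterations).
Initialization is deterministic at the masked-intensity percentiles
{10, 50, 90}; converged centers are sorted ascending and labeled CSF < GM <
WM by intensity. The objective Σ uᵐ d² is non-increasing across iterations
(asserted in tests). Tissue maps are exposed for downstream use (e.g.
anatomical false-positive rules) but the default classification path does
not consume them.

## Candidate detection (TMOD)

Per 2D axial slice: sort the brain-masked standardized intensities, discard
the lowest and highest 20% (`detection.trim_fraction`, count floored), and
take quartiles of the remainder. The detection fence is the Tukey *extreme*
fence `q3 + 3·IQR` (`detection.k_extreme`); voxels **strictly above** the
fence, 8-connected in-plane, with area ≥ 3 px (`min_area`) become
candidates. Each candidate carries the crop of its bounding box dilated by
2 px (`margin_px`) for texture context. Candidate ids are slice-major, then
top-left. Detection is per-slice by construction, so slice order cannot
affect per-slice results.

The trim fraction and fence multiplier are conventions, not fitted values:
20% per tail is the common trimmed-mean choice, and k = 3 is Tukey's
"extreme outlier" multiplier (k = 1.5 flags ordinary outliers). Both are
config keys because their provenance is convention.

## Features

Ten scalars per candidate, fixed order
(`wmlseg.features.FEATURE_NAMES`):

- **Histogram (6)**, over standardized intensities inside the candidate
  mask: mean, variance, skewness m₃/σ³, kurtosis m₄/σ⁴ (non-excess:
  Gaussian ≈ 3), energy Σp², Shannon entropy −Σp log₂p in bits (0·log 0 := 0).
  A constant patch returns skewness = kurtosis = 0 by convention.
- **GLCM (4)**, on the margin-dilated patch restricted to brain
  (`features.glcm_scope = "patch"`; the texture *context* is what separates
  mimics — a switch restricts to the candidate mask): contrast Σ(i−j)²P,
  energy ΣP², homogeneity ΣP/(1+|i−j|), and Haralick correlation
  (Σ ijP − μxμy)/(σxσy) with marginal means/standard deviations, defined 0
  when σxσy = 0.

The co-occurrence matrix counts ordered pairs (current = n, displaced = m)
at one displacement with no symmetrization; orientations map to (row, col)
offsets 0°→(0,1), 45°→(−1,1), 90°→(−1,0), 135°→(−1,−1), distance 1 (small
patches make longer displacements unreliable). Pairs touching an unmasked
pixel are skipped and the normalizer is the count of valid pairs, so the
probability mass is exactly 1 for every mask configuration. Counting with
the opposite displacement sign would transpose the matrix, which leaves
contrast/energy/homogeneity unchanged and correlation unchanged through the
symmetric marginals — we fix one unambiguous convention.

**Embedded clustering**: before the GLCM, patch intensities are quantized by
1-D k-means with L = 5 clusters (default; `features.n_clusters`), centers
initialized at L equally spaced quantiles (deterministic), ≤ 100 iterations,
ties to the lower label, centers relabeled ascending. Against equal-count
("quantile") binning — provided as the comparison baseline — k-means places
cut points at the natural intensity modes of the patch, so a bright lesion
core is not shredded across bins and fine texture survives the 16-bit→3-bit
reduction. If a patch holds fewer distinct intensities than clusters, L is
reduced with a warning; at L = number of distinct intensities the
quantization is exact.

## Classification

A random forest with T = 25 trees, depth ≤ 25, Gini splits, ⌈√10⌉ = 4
features per split, bootstrap sampling, seeded. Candidates are labeled WML
when they overlap ground truth (`rf.overlap_rule`: default any overlap > 0,
a fraction ≥ r otherwise); the class imbalance of the detector's output is
left as-is (class weighting is available behind `rf.class_weight`). The
decision is a hard per-tree vote; the score is the WML vote fraction and the
label threshold is 0.5.

Parameter selection uses tenfold stratified cross-validation over a grid of
(cluster count 1–7, orientation, quantizer), re-extracting features at each
grid point and averaging fold accuracies. At L = 1 every GLCM feature is
constant (contrast 0, energy 1), so texture information exists only for
L ≥ 2 — a structural sanity check the tests exploit.

Models serialize to versioned JSON storing every tree explicitly (children,
split features, thresholds, leaf class counts). Predictions are always
served by traversing the stored arrays, so a reloaded model is bit-identical
to the freshly trained one and independent of the training library's
internals.

## LOF boundary refinement

The reference ("lesion intensity model") is the set of standardized
intensities at training ground-truth lesion voxels, down-sampled to at most
10⁴ values by seeded stratified sampling (one draw per sorted stratum;
`lof.max_reference`, exact mode by raising it). Scoring is the classical
LOF chain on scalar intensity with |a−b| distance:

- k-distance(o): distance to the k-th nearest reference value. One
  coincident (distance 0) reference point is treated as the query's own copy
  and excluded — a reference member scores against the *other* members, as
  in the original in-dataset definition; additional duplicates count as
  genuine neighbors.
- reach-distₖ(p,o) = max(k-distance(o), d(p,o)); lrd(o) = reciprocal mean
  reach-dist over the neighborhood (every reference point within
  k-distance — ties can make it larger than k); LOF(o) = mean lrd(p)/lrd(o).
- Degenerate duplicate-heavy references drive mean reach-dist to 0; lrd is
  then capped at 10¹² so ratios of capped densities stay at 1.

Every voxel of an accepted candidate's patch is scored; voxels with
LOF ≤ τ (default τ = 1.5) inside the brain form the refined mask, and a
candidate whose refinement is empty is dropped and logged. MinPts defaults
to 20 (the working range recommended by the LOF authors). Both τ and MinPts
are prominent config keys (`lof.threshold`, `lof.min_pts`) because they are
genuine free parameters of the approach. The decision orientation — lesion
voxels are density *inliers of the lesion model* — is our reading; scoring
outlierness against a normal-tissue model would be the converse design. An
optional 3-feature variant (intensity, 3×3 mean, 3×3 std) sits behind
`lof.feature_space` for experimentation.

The model precomputes reference k-distances and lrds with sorted-array
windows (exact; the k nearest neighbors of a sorted scalar lie within k
positions), so fitting is O(n·k) rather than O(n²); scalar scoring is exact
and matches a brute-force O(n²) implementation to 1e-9 (asserted in tests).

## Evaluation

Voxelwise confusion within the brain mask. DI = 2TP/(2TP+FP+FN),
JI = TP/(TP+FP+FN) (so DI = 2JI/(1+JI) identically), TPR = TP/(TP+FN),
PPV = TP/(TP+FP), and **FPR = FP/(TP+TN)** — the definition used by the
MS-lesion-challenge tables this toolkit mirrors, kept verbatim to make
numbers comparable; the conventional FP/(FP+TN) is exposed as
`fpr_conventional` under a distinct name to avoid silent ambiguity.
VD = (Vol(auto)−Vol(GT))/Vol(GT) is signed (missed segmentation → −1; +∞
only when GT is empty and the prediction is not). Undefined denominators
yield NaN with an explanatory note, never a silent 0.

Volumes use count × voxel volume, with voxel volume = in-plane spacing² ×
slice thickness (0.4297 × 0.4297 × 5 mm by default). The 1 mm inter-slice
gap is recorded in the geometry but deliberately **not** added to the
per-voxel volume: the voxel is the imaged slab; tissue in the gap is simply
unobserved. Load strata: mild < 5 mL, moderate 5–15 mL (both boundaries
inclusive — the printed convention "5–15" is ambiguous, so we fix closed
boundaries), severe > 15 mL.

ICC(2,1) — two-way random effects, single measure, absolute agreement — is
computed from the two-way ANOVA mean squares,
(MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n), with the McGraw–Wong F-based
95% CI; it matches `pingouin.intraclass_corr`'s ICC(A,1) to 1e-9 in tests.
Pearson/Spearman come from scipy. Metric comparisons between methods use
two-sided paired t-tests with Bonferroni correction (one-sided would be the
alternative; two-sided is the conservative default).

## Synthetic phantoms

The generator emulates the data regime the pipeline targets — multi-slice
2D-axial FLAIR, 0.4297 × 0.4297 × 5 mm voxels with a 1 mm gap, mild loads
dominated by punctate lesions — at a desk-scale problem size: 128 × 128
slices, 10 per subject (the clinical protocol is 512² × ~21; the smaller
grids keep the full benchmark in seconds while leaving ≥ 10⁴ brain voxels
per slice, enough for stable quantiles).

Defaults, chosen once as the study conditions:

- **Anatomy**: elliptical brain per slice with head-shaped taper; WM bulk,
  a thin cortical GM ribbon, two ventricular CSF ellipses. GM + CSF ≤ ~20%
  of brain, as on real FLAIR where WM dominates the parenchyma — which is
  also why the 20% trim isolates the WM mode.
- **Intensities** (16-bit): CSF 3000 < GM 9000 < WM 12000; additive Gaussian
  noise σ = 500 (~4% of WM, typical FLAIR SNR; Rician optional);
  multiplicative bias field of amplitude 0.05 (inputs are nominally
  N3-corrected, a small residual is realistic), smoothed to quarter-slice
  scale.
- **Lesions**: radial super-Gaussian profile exp(−(r/σᵣ)⁸) — a flat
  hyperintense core with a ~1 px partial-volume rim, matching how punctate
  WML appear at this in-plane resolution — with peak contrast 10–14 noise
  SD and correlated internal texture (Gaussian-filtered noise). Ground
  truth is the half-peak contour of the noiseless profile, the natural
  full-width-half-maximum reading of lesion extent. Mild subjects carry 4–8
  punctate lesions (half-peak radius 2–4 px); moderate/severe profiles use
  larger, multi-slice lesions, and cohort loads are verified on the
  rendered mask with rejection resampling.
- **Mimics**: painted brighter than WM (5.5–8 noise SD) so the TMOD fence
  finds them, but with texture and shape statistics unlike lesions — thin
  alternating-intensity streaks (flow artefacts), bimodal rim arcs at the
  brain edge (residual skull), speckled punctate blobs (noise clusters);
  5–8 per mild subject, echoing the mimic-dominated false-positive regime
  of mild loads. Lesion/mimic collisions resolve in favor of lesions, with
  a log entry.

All randomness flows from the single spec seed; regeneration is
bit-identical, and phantom intensities always pass through the real
standardization stage — the pipeline is never short-circuited in tests.

**What the benchmark shows, and what it does not.** Lesions and mimics are
separable *by construction* along the texture axis the classifier uses, so
the benchmark demonstrates that the pipeline's machinery is correct and
that each stage contributes (the forest removes mimics, LOF tightens
boundaries, false-positive voxels drop severalfold) — not that these
accuracies transfer to clinical data. Real FLAIR has anatomy-dependent
intensity structure (high-density fiber regions with low lesion contrast),
partial-volume and flow effects the phantoms only caricature, and
neuroradiologist ground truth with its own variability; reported clinical
Dice for mild loads is in the 0.25–0.30 range, versus ~0.85 here. The
phantom numbers are upper bounds under idealized, known-truth conditions.

## Numerical conventions and degenerate inputs

- Threshold comparisons are strictly greater-than; ties stay background.
- Quantile rule is type 7 everywhere (trimming, landmarks, k-means init).
- k-means ties assign the lower label; empty clusters keep their center.
- Constant patches: histogram skewness/kurtosis 0, energy 1, entropy 0;
  GLCM correlation 0 when a marginal is degenerate.
- FCM requires at least as many distinct intensities as classes; landmark
  fitting requires a non-constant brain region.
- All seeds derive from explicit arguments; no global random state.

## Known limitations

- 2D per-slice detection: a lesion spanning slices is segmented
  independently per slice (matching the 5 mm / 1 mm-gap acquisition, where
  through-plane continuity is weak).
- The LOF intensity model is global per training cohort; lesions dimmer
  than anything in training are invisible to refinement.
- Phantom anatomy is schematic (no cortical folding, no periventricular
  caps), and mimic realism is limited to intensity/texture statistics.
- N3 correction, skull stripping, and T1↔FLAIR registration are assumed
  done upstream.
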