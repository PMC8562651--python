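# Methods

This note documents the models, parameters and design choices behind
`osteostage`, and what the synthetic phantom cohort does and does not
establish about behaviour on real CT data.

## The classification problem

Input: a CT volume, a 3D segmentation mask per lesion, and per-lesion
annotations (benign/malignant label plus one of 13 subcategories — 10
benign kinds and 3 malignant kinds: osteoblastic, osteolytic, mixed).
Output: a benign/malignant probability per lesion and a metastatic
decision per patient. Training happens at patch (or sub-volume) level;
lesion and patient decisions are rule-based reductions of patch scores.

## Synthetic phantom cohort

The clinical dataset the pipeline was designed around is private, so the
package generates a phantom cohort with the same statistical skeleton:

* **Cohort scale.** 114 patients, ~25.3 lesions/patient, 53.5% of
  lesions malignant. Per-patient lesion counts are zero-truncated
  negative binomial (dispersion r = 0.8), giving the strong right skew
  of real per-patient lesion burdens while keeping zero-lesion patients
  out; the clinical per-patient spread is heavier-tailed still, and no
  claim is made to match it beyond mean and skew direction.
* **Subcategories.** A skewed 13-category prevalence with two rare
  benign kinds (fibrous dysplasia, lipoma; ≈ 7 expected lesions each in
  a 2,880-lesion cohort) so the rare-subcategory training rule is
  exercised. The label side is drawn first from the malignant fraction,
  then the subcategory from the prevalence renormalised within that
  side, so the two configuration fields cannot conflict. Published
  per-subcategory counts are not available; the defaults are package
  choices, stated in `CohortConfig` and not claimed to match any
  dataset.
* **Geometry.** Lesions are axis-aligned ellipsoids with log-normal
  per-axis diameters (benign median 19 × 19 × 9.5 mm, σ = 0.35;
  malignant 34 × 34 × 15 mm, σ = 0.45 — pooled means reproduce a
  ~29 × 29 × 13 mm average bounding box and the observation that
  malignant lesions run larger and less isotropic). Placement is
  rejection-sampled to keep masks disjoint and connected; crowded
  volumes shrink a lesion stepwise rather than fail.
* **Intensity.** Piecewise-constant background: soft tissue ≈ 40 HU with
  three cortical "bone" columns ≈ 700 HU, Gaussian noise (σ = 25 HU).
  Lesion offsets relative to bone: blastic +300, lytic −300, mixed half
  and half, benign +120. Benign centres are confined to the midline
  column (echoing vertebral clustering of degenerative disease);
  malignant centres fall uniformly over all bone, giving the
  location-bearing strategies (B, D, G) signal.
* **Default grid.** 128 × 128 × 32 voxels at 1.4 × 1.4 × 1.0 mm. Volumes
  at the full 714 × 714 × 39 conformed grid are exercised per-case in
  tests; generating whole cohorts at that size serves no statistical
  purpose and is avoided.
* **`separable_config`.** A high-contrast (blastic +450, benign +60),
  low-noise (σ = 5 HU) variant in which mean ROI intensity separates the
  classes perfectly. It exists so end-to-end training tests have an
  oracle: a mean-intensity threshold fit on the training lesions.

What passing tests on phantoms shows: the plumbing, geometry, voting and
optimisation layers are correct, deterministic and learnable-from. What
it does not show: classification performance on real bone lesions, whose
texture, transition zones and anatomy the phantom deliberately omits.

## Preprocessing

Resampling uses `scipy.ndimage.zoom` (trilinear for images, nearest for
masks — label sets survive exactly). Extent conforming pads/crops
symmetrically; an odd remainder goes to the high-index side, a fixed
convention chosen for reproducibility. The bone window is unspecified in
the source description ("a bone-window"); the package defaults to level
400 HU, width 1800 HU — a standard bone window — and exposes both.
Quantization clips to the window, maps affinely to [0, 255] and rounds
half-up (the window centre maps to 128). The order resample → conform →
quantize is a package decision; quantization is monotone and per-voxel,
so the order relative to resampling only affects interpolation in
clipped regions. Preprocessing is idempotent on conformed cases.

## Stratification

The published description fixes four rules (patient level; similar
benign:malignant ratio per split; rare subcategories — strictly fewer
than 20 lesions cohort-wide — to training only; similar subcategory
distribution per split) but not the algorithm (its equations are only in
an illegible figure). The package implements the rules' observable
constraints directly: largest-remainder apportionment of patient counts
(114 → 85/14/15 exactly), hard confinement of rare-lesion patients to
train, and minimisation of an L1 divergence objective (subcategory term
plus λ-weighted class-balance term, λ = 1 by default; empty splits score
+∞) by seeded random restarts with greedy pairwise swaps. On cohorts
small enough to enumerate, the search provably reaches the optimum
(tested); at scale it is a heuristic with a monotone refinement stage.

## Extraction strategies

See the table in `osteostage/extract.py`. Choices where the source
material is ambiguous or inconsistent:

* **Strategy I** is extracted *unmasked* (a 145 × 145 × full-z crop):
  its factor table marks morphology only, but the running text calls it
  "texture lesions" and the figure shows an unmasked crop; the package
  follows text/figure. Same for **J** (masked, hence carrying texture,
  per "original masked lesion").
* **Strategy K** windows are unmasked crops like I. Window starts
  advance by 2 slices (depth 7, overlap 5) across the lesion's z extent,
  with the final window flush to the lesion end when the extent minus 7
  is odd, and edge replication pads lesions thinner than 7 slices. A
  39-slice lesion yields exactly (39−7)/2 + 1 = 17 windows. Each
  window's weight is the fraction of lesion voxels it contains
  (duplicated edge slices count in both numerator and denominator, so a
  single padded window weighs exactly 1).
* **Strategy G** zeroes the full canvas outside a 173 × 173 window
  centred on the lesion centroid: it keeps size + texture + location
  while matching the published figure's appearance.
* **Strategy H** emits the tight rectangular crop; the aspect-ratio
  distortion implied by its "texture*" annotation happens at the loader,
  which bilinearly resizes to the square network input.
* **2.5D boundary slices** replicate the edge slice for the missing
  neighbour rather than fabricating tissue. 2D (primed) samples are
  replicated to 3 channels at load time so one architecture serves both.
* **Centroids** are voxel-coordinate means rounded half-up. The fixed
  canvas sides 173 px (99th percentile patch dimension) and 145 px (95th
  percentile lesion dimension) are constants of the design, configurable
  per call since phantom volumes are smaller.

## Augmentation

Order is fixed (horizontal flip → z flip → rotation → zoom) so a
recorded generator state reproduces a sample bit-for-bit. Rotation is
in-plane about the patch centre (bilinear, zero fill); zoom re-crops or
pads back to the original shape — whether the original recipe re-cropped
or resized is unstated, and re-cropping preserves pixel scale. Unfocused
extraction shifts the ROI centre by up to 15% of the bounding-box side
per in-plane axis and dilates/erodes masked delineations by up to ±2
voxels (Euclidean ball element); the published description fixes the
mechanism, not magnitudes, so these are package defaults, configurable.
Erosion that would annihilate a mask falls back to the original and
logs. Augmentation applies to training samples only, enforced at the
pipeline layer.

## Classifiers and training

The four architectures keep their canonical topology: 2D ResNet-50
(bottleneck 3-4-6-3, 7×7 stem), ResNeXt-50 with cardinality 32 and base
width 4 (grouped 3×3 convolutions), 3D ResNet-18 (basic blocks 2-2-2-2)
and 3D ResNet-50, both 3D nets with a 3×3×3 first convolution, stride 2.
All end in global average pooling and a 2-way dense head; "binary
cross-entropy" with a dual probability vector is implemented as 2-class
cross-entropy over softmax. Published schedules are preserved:
SGD, weight decay 2e-4; 2D experiments lr0 1e-3 dropping ×0.8 every 7
epochs for 100 epochs; 3D lr0 3e-3 (5e-3 for sliding windows) dropping
×0.85 every 5 epochs with early stopping after 10 stale epochs. The LR
schedule is exactly `lr0 · γ^⌊epoch/k⌋` (tested against its closed
form). Initialisation is seeded He-normal; no pretraining (none is
specified in the source recipe, and none is available here).

The backend is a numpy implementation written for this package: grouped
2D/3D convolution via kernel-offset im2col and BLAS matmuls, batch norm
with running statistics, overlapping max pooling, manual backprop
(verified against central finite differences with losses linear in the
layer output, which makes the comparison exact up to float32 roundoff).
Training is single-threaded CPU and fully deterministic for a fixed
seed. Desk-scale runs use `width_mult < 1` (channel counts scaled,
depth and topology unchanged) and smaller loader canvases; full-width
forward passes at the published input sizes are exercised in tests, and
the shipped `configs/exp*.yaml` presets document the full-scale settings
without pretending they are quick CPU runs.

## Aggregation and decision rules

Lesion scores: arithmetic mean of patch malignant probabilities (the
inference-time description), or majority vote of slice labels (the
evaluation-section description) — both are implemented because the two
published descriptions differ and are never reconciled; the pipeline
defaults to average voting, majority selectable. Sliding-window lesions
use the weight-normalised mean. The ensemble mixes p = (p2D + 2·p3D)/3
for lesions with z extent < 5 mm and returns p2D unchanged otherwise.
Decision threshold is 0.5 with ties resolved toward malignant, and the
patient rule's boundaries (exactly 3 lesions, exactly 20%) are
inclusive — in both ambiguities the package favours sensitivity, the
clinically safer error direction. The patient rule is monotone in its
inputs (tested exhaustively at 6 lesions).

## Metric layer and the published-row fixture

Accuracy and F1 (malignant positive) are reported as percentages rounded
half-up to one decimal, matching published precision. The package ships
`data/reference_confusions.json`: every published confusion-matrix row,
with each printed accuracy/F1 cell marked verified when the counts
reproduce it to 0.1. 138 cells verify; the rest are listed under
`excluded` with both the computed and printed values. The largest block
of exclusions is consistent with a validation/test row swap in the
published 2D-experiment lesion-level confusions; others (e.g. the
ensemble test accuracy: counts give 92.1, table prints 92.2) are
sub-0.1 printing discrepancies. The fixture never overrides arithmetic:
excluded cells are simply not asserted.

## Problem sizes

Tests and the acceptance script run phantom cohorts of 5–8 patients,
width-multiplier 0.125–0.25 networks and 24–48 px loader canvases, with
one full-width forward-pass contract test per 2D/3D architecture at the
published input sizes (173 × 173 and 145 × 145 × 39). The 30-epoch
end-to-end run trains on a few hundred patches. These sizes were chosen
so the whole suite is a coffee-break CPU run while still exercising
every code path at full architectural depth.

## Known limitations

* The phantom has no trabecular texture, transition zones, periosteal
  reaction or anatomy; results on it bound nothing about clinical
  accuracy.
* The stratifier is exact only where enumeration is feasible.
* BatchNorm statistics make slice scores weakly batch-dependent during
  training; inference uses running statistics and is batch-invariant to
  float32 precision.
* DICOM ingestion, detection (lesion finding), ROC analysis and
  probability calibration are out of scope.
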