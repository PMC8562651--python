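# osteostage

Staging bone lesions from CT as benign or malignant is a core step in
managing metastatic prostate cancer: osteoblastic metastases appear
hyperdense, osteolytic ones translucent, and a long tail of benign
mimics (degenerative joint disease, Schmorl's nodules, bone islands,
fibrous dysplasia, ...) overlaps both in appearance. `osteostage` is a
tested re-implementation of a deep-learning staging pipeline for this
problem, aimed at researchers who want to study *how* such a pipeline
behaves — the data stratification, the ROI definition, the voting rules —
without access to protected patient data. A seeded synthetic CT phantom
cohort stands in for the clinical dataset.

The pipeline:

1. **Preprocessing** — volumes resampled to 0.7 × 0.7 × 1.0 mm voxels,
   symmetrically zero-padded/cropped to 714 × 714 × 39, bone-window
   clipped and mapped to 8-bit.
2. **Lesion-aware stratification** — patients are apportioned 75/12/13%
   to train/valid/test by largest remainder (114 patients → 85/14/15),
   rare subcategories (< 20 lesions cohort-wide) are confined to
   training, and an L1 objective
   `Σ_s Σ_c |p(c|s) − p(c)| + λ Σ_s |m(s) − m|`
   over subcategory proportions *p* and malignant fractions *m* is
   minimised by seeded restarts with greedy swaps.
3. **ROI extraction** — 12 strategies isolating lesion morphology,
   texture, size and location: 2.5D patches A–H (three adjacent slices
   as RGB channels), their 2D counterparts A′–H′, and volumetric I/J/K/L
   including 145 × 145 × 7 sliding windows with overlap 5 (strategy K).
4. **Augmentation** — seeded flips, ±15° rotation, [0.75, 1.25] zoom, and
   *unfocused* extraction (ROI centre shift, mask dilation/erosion) that
   mimics imperfect lesion delineation.
5. **Classifiers** — 2D ResNet-50 / ResNeXt-50 (cardinality 32) and 3D
   ResNet-18 / ResNet-50 with a 3×3×3 stem, trained with SGD,
   2-class cross-entropy, stepwise LR decay (`lr0 · γ^⌊e/k⌋`) and L2
   regularisation. The networks run on a numpy backend written for this
   package (grouped im2col convolutions with manual backprop), with a
   width multiplier for desk-scale experiments.
6. **Aggregation** — lesion-level average voting over patch
   probabilities, weighted voting over sliding windows, a z-extent
   policy ensemble (1 : 2 credit for 2D : 3D below 5 mm, 2D alone
   otherwise), and a patient rule (≥ 3 or ≥ 20% malignant lesions ⇒
   metastatic patient).
7. **Evaluation** — confusion matrices and accuracy/F1 (malignant
   positive) at slice, lesion and patient level, rounded half-up to one
   decimal.

## Worked example

An end-to-end run on an 8-patient high-contrast phantom cohort
(width-reduced 2D ResNet-50, masked-texture patches, 30 epochs):

```python
from osteostage.pipeline import load_config, run_pipeline

cfg = load_config("configs/toy_2d_C.yaml",
                  overrides={"cohort": {"n_patients": 8, "seed": 5},
                             "train": {"max_epochs": 30}})
manifest = run_pipeline(cfg, "runs/demo")
print(manifest["metrics"])
```

prints (seed 5):

```
level  tn  fn  tp  fp  accuracy    f1
   SL  60   7  54   4      91.2  90.8
   LL   7   0   6   0     100.0 100.0
   PL   0   0   1   0     100.0 100.0
```

Slice-level (SL) rows score each axial patch independently; lesion-level
(LL) rows follow average voting over the patches of each lesion — voting
repairs the slice-level errors here, which is exactly the behaviour the
aggregation layer exists to capture; the patient-level (PL) row applies
the ≥3-or-≥20%-malignant rule. The run directory contains `split.csv`,
`lesion_predictions.csv`, `metrics.csv` and `manifest.json`.

The same thing from a shell:

```sh
osteostage run --config configs/toy_2d_C.yaml --out-dir runs/demo --seed 5
```

`configs/` also ships presets mirroring the six published experiment
families (`exp1_C.yaml` … `exp6_ensemble.yaml`); at full width and canvas
these are multi-hour CPU runs and are provided as configuration
documentation, not as quick demos.

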