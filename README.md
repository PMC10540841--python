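# nutriface

Screening for nutritional risk from a face photograph.

Malnutrition screening normally requires a structured assessment such as
NRS-2002 (Nutritional Risk Screening 2002, a 0–5 score where ≥ 3 flags
nutritional risk).  Facial fat loss — particularly in the sub-orbital
("orbital fat pad") region — is one of the physical signs clinicians look
for.  `nutriface` implements a complete image-analysis pipeline that turns a
face photograph with 68-point landmarks into a binary NRS-2002 risk class:

1. **Alignment** — eye centers are the centroids of landmarks 36–41 / 42–47;
   the image is rotated about the inter-eye midpoint by −θ, where
   θ = atan2(Δy, Δx) is the interocular angle, so the eye line becomes
   horizontal.
2. **Cropping** — a single similarity transform maps the face into a
   300 × 300 frame: the face midline goes to x = 150, the eye center to
   y = 0.30 · 300 = 90 and the mouth centroid to y = 300 − 0.35 · 300 = 195.
3. **Segmentation** — a U-net (encoder–decoder with skip connections,
   implemented in NumPy with hand-derived gradients) marks the orbital
   fat-pad pixels; training uses binary cross-entropy with RMSProp
   (batch 1, lr 10⁻⁵, weight decay 10⁻⁸, momentum 0.9, 50 epochs by
   default).  Masks are {0, 255} PNG rasters; Dice and per-class IoU
   quantify overlap.
4. **Features** — the masked grayscale ROI is described with dense HOG:
   8×8-px cells, 2×2-cell blocks at 1-cell stride, 9 unsigned orientation
   bins at i·π/9, L2-Hys block normalization.  A 300 × 300 image gives
   37 cells → 36 blocks per axis → 36 · 36 · 36 = **46,656** features,
   z-scored with training-set statistics and reduced to 100 principal
   components.
5. **Classification** — a soft-margin SVM with RBF kernel
   K(x, y) = exp(−γ‖x − y‖²), C = 50, γ = 10⁻⁵, positive class =
   NRS-2002 < 3.  Accuracy, precision, recall and F1 follow the standard
   confusion-matrix definitions.
6. **Cohort statistics** — per-subgroup (age / gender / site) accuracy
   tables with Yates-corrected 2×2 chi-square homogeneity tests.

Because clinical photographs cannot be redistributed, the package ships a
synthetic-cohort generator (`nutriface.synthetic`) that renders schematic
faces with consistent 68-point landmarks, ground-truth fat-pad masks, and a
controllable class signal, so every stage is exercisable end to end with no
external data.

## Worked example

```bash
nutriface synth --n 100 --out cohort --seed 7 --prevalence 0.239
nutriface run-all --metadata cohort/metadata.csv --out run --use-true-masks --seed 7
```

prints (numbers from this exact invocation):

```
{"accuracy": 0.9, "precision": 0.8181818181818182, "recall": 1.0, "f1": 0.9}
```

i.e. on the 20-subject held-out split of a 100-subject synthetic cohort the
SVM recovers the fat-pad signal with 90% accuracy; `run/report.json` also
carries the confusion counts (TP 9, TN 9, FP 2, FN 0) and the three
subgroup tables with their chi-square p-values, and `run/manifest.json`
lists a SHA-256 hash for every artifact so reruns can be verified
bit-for-bit.  Replace `--use-true-masks` with `--train-unet` to train the
segmentation network instead of using the rendered ground truth.

The same experiment is available as a library call:

```python
from nutriface import CohortSpec, run_synthetic_experiment
report = run_synthetic_experiment(CohortSpec(n_subjects=300, effect_size=2.0, seed=0))
print(report["metrics"])
```

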