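# octcalc

Automated coronary calcium mapping for intravascular optical coherence
tomography (OCT).

During percutaneous coronary intervention, heavily calcified plaque
predicts stent under-expansion, and interventionalists grade it from OCT
pullbacks by measuring, per calcified plaque, its **arc** (degrees around
the lumen centre), **thickness** (mm on the cross-section) and **length**
(mm along the pullback), summarised in the 0–4 **OCT-calcium score**:

```
score = 1·[max thickness > 0.5 mm] + 2·[max arc > 180°] + 1·[length > 5 mm]
```

with strict inequalities; scores 3–4 indicate severe calcification.
Doing this manually frame-by-frame takes tens of minutes per pullback.
`octcalc` implements the full automated alternative at desk scale:

- **`octcalc.phantom`** — a seeded generator of synthetic polar OCT
  pullbacks with ground-truth label maps over 10 pixel classes
  (background, catheter, lumen, lumen border, wall tissue, calcium,
  lipid, fibrous, guidewire, guidewire shadow). Tissue follows the
  round-trip attenuation model `I(z) = I₀·exp(−2μz)` with
  gamma-distributed speckle; calcium renders signal-poor with sharp
  borders and low μ, lipid signal-poor with diffuse borders and high μ,
  fibrous tissue signal-rich.
- **`octcalc.preprocess`** — the two-channel network input: log-compressed
  intensity plus a per-pixel depth-resolved attenuation-coefficient
  channel `μ̂[i] = I[i] / (2Δr·Σ_{j>i} I[j])`, both normalized to [−1, 1]
  by the exact affine map `(x − 127.5)/127.5` (`PolarPreprocessor`, an
  sklearn-style transformer).
- **`octcalc.augment`** — training-time artifact simulation: non-uniform
  rotational distortion (NURD) as a smooth angular displacement field,
  radial motion shifts, and multiple-reflection ghosts, all applied
  identically to image and labels.
- **`octcalc.segnet`** — a UNet-like 10-class pixel segmenter written in
  pure numpy (im2col convolutions, analytic backprop, Adam): four
  encoder blocks of two 3×3 convolutions + ReLU with 16 filters doubling
  per block (16, 32, 64, 128), max-pooling and dropout; nearest-neighbour
  upsampling with skip concatenation in the decoder; trained with a
  class-weighted mix of cross-entropy and soft-Dice loss.
  `UNetSegmenter` follows the sklearn fit/predict contract and enforces
  pullback-level train/validation splits.
- **`octcalc.quantify`** — calcium plaque extraction (angular connected
  components with 0/360° wrap-around), arc/thickness/length measurement,
  the OCT-calcium score and its severe/non-severe dichotomization.
- **`octcalc.evaluate`** — per-class ROC/AUC with Youden operating
  thresholds, the 3×3 plaque confusion matrix (precision/recall/F1,
  overall accuracy), the 1D angular Dice coefficient, and
  Pearson/Spearman/ICC(2,1) agreement statistics.

Clinical pullbacks, vendor formats and trained clinical weights are out
of scope; everything runs on synthetic phantoms with exact ground truth.

## Worked example

```python
import numpy as np
from octcalc import (PhantomConfig, PlaqueSpec, generate_pullback,
                     summarize_lesions, dichotomize)

cfg = PhantomConfig(
    n_frames=30, n_alines=480, n_samples=512, frame_spacing_mm=0.2,
    plaque_specs=(PlaqueSpec("calcium", arc_deg=200.0, thickness_mm=0.8,
                             start_frame=2, n_frames=26, center_deg=180.0),),
    seed=7,
)
image, labels = generate_pullback(cfg)
lesions, _ = summarize_lesions(labels.classes, cfg.radial_res_mm,
                               cfg.frame_spacing_mm)
lesion = lesions[0]
print(f"arc {lesion.max_arc_deg:.2f} deg, thickness {lesion.max_thickness_mm:.2f} mm,"
      f" length {lesion.length_mm:.1f} mm -> score {lesion.score} ({lesion.severity})")
```

prints

```
arc 200.25 deg, thickness 0.80 mm, length 5.2 mm -> score 4 (severe)
```

arc 200.25° is the requested 200° snapped to the 0.75° angular grid (it
still exceeds the 180° threshold, 2 points), thickness 0.80 mm exceeds
0.5 mm (1 point), and 26 frames at 0.2 mm spacing give a 5.2 mm lesion,
exceeding 5 mm (1 point) — total score 4, severe calcification.

To train and apply the segmenter instead of using ground-truth labels,
see the CLI verbs `octcalc phantom | preprocess | train | segment |
quantify | evaluate | pipeline` (`octcalc --help`), or the
`UNetSegmenter` example in `tests/test_acceptance.py`.

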