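# Methods

This note documents the models, estimators and design choices behind
`octcalc`, in the order data flows through the pipeline.

## Phantom signal model

A polar OCT frame is rendered per A-line as a piecewise signal:

- **catheter ring** for radii below `catheter_radius_mm` (default
  0.06 mm), bright;
- **lumen interior** up to the lumen border, near-zero signal (blood is
  assumed cleared, as in an analyzable clinical pullback);
- **lumen border**, a thin bright line of width `border_mm` (0.03 mm),
  modelling the strong backscatter at the blood/intima interface;
- **vessel wall and plaques** beyond the border, with round-trip
  exponential attenuation `I(z) = I₀·exp(−2μz)`, `z` the depth into the
  region. The factor 2 is the reflected-intensity convention: light
  traverses the tissue twice. Each region restarts at its own entry
  brightness `I₀` (backscatter is class-specific) while depth is counted
  from the region entry;
- **background** where the noiseless wall signal falls below
  `background_threshold` (3 of 255) — the effective penetration limit;
- **guidewire**, a bright 20° arc inside the lumen whose radial
  **shadow** overrides every class behind it, as the metal wire blocks
  the beam.

Default optical parameters (entry brightness / attenuation):

| class   | I₀ (8-bit) | μ (mm⁻¹) | appearance                      |
|---------|-----------:|---------:|---------------------------------|
| wall    | 200        | 2.0      | signal-rich, medium decay       |
| calcium | 70         | 0.6      | signal-poor, sharp border, slow decay |
| lipid   | 170        | 5.0      | bright cap, very fast decay, diffuse border |
| fibrous | 235        | 1.8      | signal-rich, homogeneous        |

μ values sit in the ranges reported for atherosclerotic tissue by
depth-resolved attenuation studies (calcium ≲ 1 mm⁻¹, fibrous ≈ 2 mm⁻¹,
lipid ≥ 4 mm⁻¹); the contrast that matters for the pipeline is ordinal
(μ_lipid > μ_wall > μ_calcium), not the absolute numbers. Lipid borders
are softened by a local Gaussian blur (σ = 2 px radially) to emulate
their diffuse delineation; calcium borders stay sharp.

Speckle is first-order multiplicative gamma noise with shape `k`
(default 4, ≈ the effective number of incoherently averaged looks;
mean 1, so the noiseless profile is the expectation). Intensities are
quantized to 8 bits. The lumen border waviness is a single angular
harmonic with a seeded phase drifting along the pullback.

Plaques are annular sectors: an arc around a centre angle, a radial band
of fixed thickness starting at the lumen border, over a run of frames.
Arcs and thicknesses snap to the sampling grid, so the generated masks
agree with their nominal geometry to within half a sample — this is what
makes exact parameter-recovery testing possible. Configurations whose
radial extent exceeds the imaging window are rejected at construction.

What the phantom deliberately does *not* model: blood-clearance failure,
stents, thrombus, plaque rupture, sew-up/saturation artifacts, eccentric
catheter position, or the texture statistics of real tissue beyond
first-order speckle. Passing tests on phantoms therefore demonstrates
that the pipeline's machinery is correct and learnable signal is
recovered — not clinical-grade performance on patient data.

## Preprocessing

The network consumes two channels. Channel 1 is the intensity after
log compression (`log1p` rescaled to the 8-bit range) — the standard
dynamic-range representation of OCT data; the map is strictly monotone,
so pixel ordering is preserved. Channel 2 is a per-pixel depth-resolved
attenuation estimate

    μ̂[i] = I[i] / (2·Δr·Σ_{j>i} I[j]),

the single-scattering estimator that assumes all signal beyond sample
`i` originates from attenuated illumination. It is parameter-free and
single-frame, which is why it was chosen over curve-fitting approaches.
Two intrinsic biases follow from the derivation and are covered by the
tests rather than hidden: a discretization bias of relative size ≈ μ·Δr
(the geometric series vs. the continuous integral), and a distal
truncation bias ≈ exp(−2μ(n−i)Δr) because signal beyond the imaging
window is treated as zero. The final `attenuation_window` samples
(default 32) are masked to zero, and all-zero A-lines yield zero rather
than a division error. The estimator always runs on raw (not
log-compressed) intensities, as its derivation requires linear signal.
The channel is scaled to [0, 1] by a robust (99.5th percentile) frame
maximum, gamma-adjusted with γ = 0.5 (brightening weakly attenuating
tissue such as calcium), and rescaled to 8-bit range.

Both channels are normalized by the exact affine map
`(x − 127.5)/127.5 → [−1, 1]`; the constants are part of the contract
and the map is bijective to < 1e−12.

## Artifact augmentation

- **NURD** is modelled as a single-harmonic angular displacement
  `θ' = θ + A·sin(2πfθ/360 + φ)` with seeded random phase — the
  first-order signature of non-uniform catheter rotation. Defaults
  A = 2°, f = 1 cycle/revolution keep the warp far from folding (the
  monotonicity condition `A·2πf/360 < 1` is enforced) and keep per-class
  pixel-count drift below 5% even for narrow classes like the guidewire.
  Image columns are linearly interpolated with wrap-around; labels take
  the nearest source column, so class and intensity are transported by
  the same map. Negating the displacement approximately inverts the
  warp for small amplitudes.
- **Motion** is a rigid radial shift of the whole frame; vacated rows
  are zero-filled and labelled background.
- **Multiple reflection** adds a ghost of each A-line's proximal half at
  double depth with a configurable gain, clipped to the 8-bit range;
  labels are untouched since the ghost carries no tissue.

Artifacts fire independently with configured probabilities in a fixed
order (NURD → motion → reflection), so one generator seed reproduces an
augmentation stream exactly. Magnitudes are uncalibrated defaults — no
public reference quantifies them — and are exposed in `AugmentConfig`.

## Segmentation network

The segmenter is an encoder-decoder with feature bridges, implemented
directly in numpy: convolutions are im2col + one BLAS matmul, and the
backward pass uses the analytic adjoint (correlation with spatially
flipped, in/out-transposed kernels), verified against finite differences
to ~1e−7 relative error in the tests.

Architecture: four encoder blocks of two 3×3 convolutions + ReLU, 2×2
max-pooling and dropout between blocks; 16 filters in the first block
doubling per level (16, 32, 64, 128); a two-convolution bottleneck at
256; four decoder blocks of nearest-neighbour 2× upsampling, skip
concatenation and a single 3×3 convolution + ReLU; a 1×1 projection and
channel softmax produce the 10-class probability field. Input spatial
dimensions must be divisible by 2⁴. Choices the architecture description
leaves open were fixed as: nearest-neighbour upsampling (an "upsampling
layer", not a transposed convolution), dropout 0.1, He initialization.

Loss: `mix·CE + (1−mix)·(1 − softDice)` with mix = 0.5, class-weighted
with equal weights for the three plaque classes (default 5 vs. 1 for the
rest — plaque pixels are a small minority of a frame). The CE weights
are normalized so uniform predictions give exactly ln 10 per pixel; the
soft-Dice term uses an ε-regularised ratio so absent classes contribute
no penalty.

Training: Adam (lr 1e−3, no schedule) as a conventional baseline, seeded
shuffling, and a hard pullback-level split guard — frames of one
pullback never appear in both splits, because adjacent frames are nearly
identical and would leak. The checkpoint returned is the epoch with the
best validation mean plaque-class soft Dice.

## Quantification

Calcified plaques on a frame are 8-connected components of the calcium
class in the polar grid, with wrap-around connectivity across the 0/360°
seam (union-find over the seam columns). Per component: arc = occupied
A-line columns × degrees per column (the A-line axis *is* the angle at
the lumen/catheter centre in polar acquisition); thickness = radial
pixel extent per column × radial calibration, reported as min and max
over columns. Thickness is measured along A-lines rather than normal to
the plaque surface: deterministic, and the natural reading of a
cross-sectional caliper measurement in polar geometry. When a plaque's
outer border abuts a signal void (background or guidewire shadow) its
measure carries a `truncated` flag instead of a guessed posterior
border — near-infrared light often cannot delineate the abluminal side
of thick calcium.

Lesion length supports two reading protocols: `every_frame` chains
consecutive frames whose calcium arcs share at least one angular bin
(length = run count × frame spacing, i.e. each frame represents one
spacing of tissue — the "count" convention, chosen over "span" as the
natural discrete measure that gives a single frame one spacing rather
than zero), and `interval_quadrant` samples frames at a fixed interval
(default 1 mm = 5 frames at 0.2 mm spacing) and requires calcium in the
same fixed 90° quadrant, emulating a manual reader. The two protocols
genuinely disagree on short or drifting lesions; no ordering between
them is assumed.

The OCT-calcium score adds 1 point for max thickness > 0.5 mm, 2 for
max arc > 180°, 1 for length > 5 mm — strict inequalities, so threshold
equality earns nothing — and dichotomizes at ≥ 3 into severe versus
non-severe. When several plaques share a lesion, the lesion score uses
the maxima across its plaques and frames.

## Evaluation statistics

Per-class ROC curves and trapezoidal AUC (equal to the Mann–Whitney rank
statistic) are computed on pixel scores, with the Youden index
`max(sens + spec − 1)` selecting the operating threshold — ties break
toward the lower threshold, and under perfect separation the midpoint of
the empty score gap is returned. Plaque segmentation quality uses a 3×3
confusion matrix restricted to ground-truth plaque pixels (calcium,
lipid, fibrous) with precision/recall/F1 per class and trace/total
accuracy; predictions outside the three plaque classes are excluded and
counted separately. Angular agreement of two calcium arcs uses the 1D
Dice coefficient over 1° bins, with empty-vs-empty defined as 1.
Measurement agreement reports Pearson r (Fisher-z 95% CI), Spearman ρ,
and ICC(2,1) — the two-way random-effects, absolute-agreement,
single-measure form, the standard choice for method comparison because
it penalizes systematic scale or offset differences that correlation
ignores; its CI is the F-distribution interval. Pearson is intended for
thickness (approximately continuous-normal), Spearman for arc and score
(bounded/ordinal).

## Problem sizes and reproducibility

Unit and property tests run on frames from 8×8 to 256×480 in seconds.
The end-to-end benchmark trains the full 16-base, depth-4 network on 200
phantom frames (10 pullbacks × 20 frames) at 64 radial × 80 angular
samples, 0.03 mm/px, for 12 epochs — a problem size chosen so the whole
run fits in a few CPU-minutes — and evaluates on four unseen pullbacks,
reaching held-out calcium pixel AUC > 0.99 and 3-class plaque accuracy
> 0.99 on phantoms. These figures say the pipeline learns and measures
what the generator encodes; they are synthetic-benchmark numbers, not
clinical performance. Every stochastic component (speckle, plaque
geometry, augmentation, initialization, batching, pixel subsampling in
evaluation) is driven by an explicit seed, and same-seed runs are
bit-identical.

## Known limitations

- The 10-class vocabulary fixes three residual classes (background,
  lumen interior, catheter ring) that any polar OCT frame exhibits;
  other reasonable partitions exist.
- The attenuation estimator's bias grows with μ·Δr and near the distal
  window; quantitative μ maps at coarse radial resolution should be
  interpreted accordingly.
- Whether "log-scale" polar representation means intensity compression
  or radial-axis warping is ambiguous in the literature this follows;
  intensity compression is implemented.
- Lesion grouping across frames uses angular-overlap chaining; plaques
  that drift more than their width between consecutive frames split
  into separate lesions.
- The phantom's simplifications (above) mean phantom-trained weights do
  not transfer to clinical images.
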