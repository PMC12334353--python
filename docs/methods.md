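# Methods

## Problem and model

`usinr` reconstructs a continuous 3D ultrasound volume from sparse 2D
B-mode frames acquired on a *known rotational sweep*: a 1D-array
transducer rotates about its depth axis in fixed angular steps, so every
frame pixel has an exact position in 3D. The reconstruction is an
implicit neural representation (INR): a coordinate network

    F(x, y, z) = (I, S)

fitted to one sweep at a time, mapping a world position (mm) to B-mode
intensity `I` and segmentation probability `S`. There is no rendering or
ray marching — ultrasound image planes intersect the volume directly, so
the network is supervised per pixel. One network represents exactly one
acquired volume; nothing generalizes across datasets. Once trained, any
grid, plane or resolution can be synthesized by function evaluation, at
a cost independent of how many frames were acquired.

### Acquisition geometry

The sweep is half-open: `plan_sweep(180, 1.25)` yields the 144 angles
0, 1.25, …, 178.75°, because the 180° plane re-images the 0° plane
(mirrored in-plane). The rotation axis is the depth line through the
lateral centre of the raster, `axis_col = (cols-1)/2`; pixel centres
carry coordinates with spacing `extent/(n-1)`, so the outermost pixel
centres land exactly on the field-of-view bounds. A pixel at lateral
offset `l` and angle θ maps to `(x, l·cosθ, l·sinθ)`; its radial
distance is independent of θ. A consequence of the cylindrical sampling
pattern is that the azimuthal gap between adjacent planes grows linearly
with both the angular step and the distance from the rotation axis —
small off-axis structures are the first casualties of a coarse sweep.

### Network

* Positional encoding: each normalized coordinate value x is expanded to
  `(x, sin(2^j x), cos(2^j x))` for j = 0…B−1. The default B = 15 pairs
  gives the 93-feature input of the full-scale protocol.
* MLP: 10 linear layers of width 256 (full-scale protocol) with sine
  activations and additive skip connections between same-width
  activations every other hidden layer. Every sine layer computes
  `sin(ω·(Wx+b))` with ω = 30; weights are initialized uniform
  ±1/fan_in in the first layer and ±sqrt(6/fan_in)/ω deeper, which keeps
  hidden pre-activations at unit scale (verified by a Monte-Carlo test).
  Applying ω only to the first layer — a reading the literature also
  admits — collapses hidden pre-activations by ~1/ω per layer under this
  init, so the all-layer formulation is used.
* Heads: intensity is a linear output clamped to [0, 1] only at
  rendering time; the mask head passes through a sigmoid.
* Coordinates are normalized into [−1, 1]³ (depth over [0, axial extent],
  transverse axes over ±lateral extent/2); the affine scale is stored in
  the checkpoint so the model evaluates directly at world mm.

The network, its reverse-mode gradients, Adam, and the loss gradients
are implemented in NumPy (float32). All analytic gradients are checked
against central finite differences in the test suite.

## Objectives

* **Image**: `L_image = 1 − SSIM(pred, frame)` with an 11×11 uniform
  window, unit dynamic range and the standard constants k₁ = 0.01²,
  k₂ = 0.03². SSIM is a similarity, so the loss is its complement.
  Windows are restricted to fully valid positions (a half-window border
  is cropped); this makes the adjoint of the box filter a box filter and
  the analytic gradient exact.
* **Segmentation**: negative binary cross-entropy plus a soft Dice
  complement (`1 − 2Σxy/(Σx+Σy)`, smoothing 1e-6 for empty masks) plus a
  pixel-wise false-positive rate `mean(x·(1−y))`. Probabilities are
  clamped to [eps, 1−eps], eps = 1e-6, before logs. The BCE term is
  negated relative to a "score" formulation so that the total is
  minimized at a perfect prediction.
* **Total**: `w_image·L_image + w_seg·L_seg`, default weights 1 and 1
  (the relative weighting of the reference protocol is not published;
  equal weights are the neutral choice and both terms are O(1)).

SSIM is computed per frame, not over pixel batches: it is a windowed
statistic and needs intact image structure. Consequently training
batches are whole frames (default 4 per optimization step) rather than
random pixel subsets.

## Optimization

Adam (β = 0.9/0.999) for a configurable number of epochs — 500 in the
full-scale protocol, one epoch being one shuffled pass over all frames.
The learning rate follows cosine annealing from 1e-3 to 1e-6 stepped per
epoch. Gradients pass through an EMA low-pass amplification filter
("grokfast", α = 0.98, λ = 2): `ema ← α·ema + (1−α)·g`, update uses
`g + λ·ema`. With λ = 0 the filter is the identity; for a constant
gradient stream it converges to (1+λ)·g. A single master seed fans out
to phantom generation, weight init, frame shuffling and speckle noise,
so runs are bit-reproducible on a fixed BLAS configuration.

## Synthetic phantom

The simulator replaces a full acoustic pipeline (wave propagation, RF
beamforming) with geometric slicing plus first-order speckle
statistics:

* Spheres with radii uniform in [4, 15] mm are rejected-sampled into the
  cylinder swept by the frames (55 mm axial × 82 mm lateral field of
  view, ≥1 mm clearance, ≤10 000 attempts). Contrasts are uniform in
  [−2, 8] dB over background, applied in amplitude (10^(dB/20));
  anechoic targets render at level 0. The paper states radii in [4, 15]
  mm in one place and diameters in another; the radius reading is the
  default and `sizes_are_diameters=True` selects the other.
* Speckle is multiplicative unit-mean Rayleigh noise; `speckle_scale`
  ∈ [0, 1] blends linearly between noise-free and fully developed
  speckle while preserving region means. Masks are rendered noise-free
  from the analytic geometry.
* Ground truth is rasterized by point-in-sphere tests at voxel centres;
  analytic volumes are (4/3)πr³.

What the simulator does **not** model: attenuation, shadowing,
elevation beam-width (partial-volume) blur, refraction, real speckle
correlation lengths, and segmentation-model errors (masks are exact).
Passing the synthetic studies therefore demonstrates that the
representation, losses and volumetry recover geometry and contrast
under ideal labelling — not that the pipeline is robust to real-probe
artefacts or imperfect segmentation, which the full-scale protocol
addresses with a separate segmentation model and reports as its main
residual error source.

## Sampling, baseline, volumetry

* `sample_volume` / `reslice` evaluate the model on voxel grids or
  axis-aligned planes (tiled, default 2^18 points per tile; tiling is
  exactly invariant). Default binarization threshold 0.5 (the reference
  protocol does not state its threshold).
* The nearest-neighbour baseline answers queries with the value of the
  Euclidean-nearest acquired pixel via a k-d tree; exact, with duplicate
  sites collapsed to their first occurrence so ties are deterministic.
* Connected components use 26-connectivity by default (6/18
  configurable), relabelled into first-voxel raster order for
  determinism. Object volumes are reported both as voxel counts × voxel
  volume and as the volume of the convex hull of the voxel *centres*
  (computed by the divergence theorem over the watertight hull mesh).
  The centre convention under-estimates by up to half a voxel of surface
  shell; at the grid resolutions used here this is within the reported
  tolerances. Degenerate components (<4 points or coplanar) get volume
  0 and a flag instead of a mesh.
* Metrics: Dice, IoU (empty-vs-empty defined as 1; IoU = D/(2−D) holds
  exactly for binary masks), contrast in dB as the difference of region
  means of the dB image, and relative volume error 100·|V−V̂|/V.

## Reference experiments and their sizes

Two seed-driven studies reproduce the headline synthetic results at
reduced scale; `scripts/acceptance.py` runs each over three derived
seeds and reports the mean.

* **Volume accuracy** (anechoic phantom): 6 spheres, noise-free 128²
  frames, 5° steps (36 frames), width-16 / 6-layer network with the full
  15-band encoding, 300 epochs, 112³ evaluation grid. Headline:
  100 − mean per-sphere voxel-count error. A binary-mask field of six
  disjoint spheres is low-complexity; width 16 reconstructs it with a
  comfortable margin and keeps a run under four minutes on one core.
* **Contrast fidelity**: 6 spheres with contrasts in [−2, 8] dB,
  background amplitude 0.25 (keeps a +8 dB target inside the display
  range under unit-mean speckle), speckle_scale 0.1 ("mild" — the
  perfect-reconstruction noise floor of the contrast measurement is
  0.016 dB at this level), 2.5° steps (72 frames), width 32, 75 epochs.
  For every frame and sphere cross-section of at least 30 pixels,
  contrast = mean target dB − mean background dB (background excludes a
  3-pixel guard band around all targets; dB floor −60 dB) measured on
  the original and the re-rendered frame; headline: mean absolute
  deviation.

The reduced widths/depth and the per-study epoch counts are the
package's reference-experiment sizes for single-CPU execution; the
full-scale protocol (width 256, 10 layers, 500 epochs, 256² frames) is
the library default elsewhere.

A capacity effect worth knowing about: resolving six *distinct
amplitude levels* is much harder for a narrow network than resolving
six binary regions. At width 24 the fitted levels of some spheres
visibly entangle with brighter neighbours (1–2 dB contrast error with
clean geometry); width 32 resolves all levels on most phantoms, but
occasional sphere configurations converge slowly and retain
\>0.5 dB level error at these epoch counts regardless of further width
(48 was tried). The SSIM objective is part of the reason: its
window-normalized luminance term penalizes a uniform level offset
inside a flat region only weakly, so absolute levels are the
slowest-converging component of the fit. The full-scale protocol
escapes this regime with ~10× width and 500 epochs. Consequently the
contrast study's mean deviation is seed-dependent at reduced scale:
favourable phantoms reach ≈0.1 dB, unfavourable ones 0.5–0.8 dB. This
limitation is reported as measured rather than hidden by enlarging the
network beyond what a single-CPU budget affords.

## Numerical choices and edge cases

* float32 everywhere in the hot path; `sin(z)` is computed as
  `cos(z − π/2)` (the faster SIMD kernel in this NumPy build).
* Probability clamps: eps = 1e-6 in losses; dB conversions floor at
  −60 dB.
* Degenerate sweeps (`sweep == step`) yield the single angle 0; a step
  that does not divide the sweep is an error naming both values.
* Non-finite training loss aborts with the offending epoch; non-finite
  query coordinates are rejected.
* Determinism: same seed → identical phantoms, weights, logs and
  metrics (asserted in tests). Across BLAS builds/thread counts,
  floating-point reductions may differ in the last ulp.

Two further measured characteristics of the reduced-scale training
dynamics, reported as observed:

* **The training loss does not descend monotonically.** With the EMA
  gradient amplification at its defaults (λ = 2) the per-epoch loss
  plateaus with oscillations of a few percent (occasionally tens of
  percent on easy scenes) through the middle of the cosine schedule and
  drops sharply once the learning rate decays — roughly a quarter of
  10-epoch moving-average windows rise rather than fall, even on runs
  that end at frame SSIM ≥ 0.99. Convergence is excellent; the *path*
  is not monotone.
* **Component bridging.** When two spheres approach within ~1–2 voxels,
  their predicted masks can merge into one 26-connected component; the
  per-object metrics split such bridged components between the objects
  they overlap by nearest-object assignment, so a thin bridge does not
  erase an object from the report (the meshes and hull volumes are
  still computed per assigned voxel set).

## Known limitations

* Rotation-only geometry (the coordinate mapper is the single extension
  point for other scan paths); no freehand pose estimation.
* One model per volume; no cross-dataset generalization by design.
* The convex-hull volume is only meaningful for convex objects; the
  voxel-count volume is the general-purpose output.
* The NumPy training path is single-threaded; full-scale
  (width-256/500-epoch/144-frame) training is possible but slow on one
  core — the architecture defaults match the full protocol, the
  reference experiments use the reduced sizes above.
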