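# Methods

`dcegrad` implements a gradient-based screening pipeline for breast
dynamic contrast-enhanced MRI (DCE-MRI) together with a 4D phantom
simulator that makes the pipeline testable end to end without patient
data. This note describes the model, its parameters and defaults, the
numerical choices, what the phantom does and does not emulate, and the
known limitations.

## The pipeline

A DCE-MRI study is a 4D volume `S(t, z, y, x)`: `T` dynamic
acquisitions (`t = 0` precontrast, the rest postcontrast) of `Z` axial
slices. The pipeline runs five fixed stages.

1. **Chest removal.** The first slice of the sequence — slice `z = 0`
   of the precontrast acquisition, which in a stack that begins beyond
   the breast contains chest only — is binarised (Otsu by default,
   optionally a fixed threshold, optionally dilated) and the resulting
   mask is zeroed out of every slice of every acquisition. Zeroing, not
   arithmetic subtraction, is used: the goal is to excise the chest so
   its anatomy cannot contribute temporal gradients.

2. **Temporal Sobel gradient.** Each slice is differentiated along the
   acquisition-time axis with a separable Sobel-type operator: the
   central difference `h' = (1, 0, -1)` along `t` combined with the
   triangle filter `h = (1, 2, 1)` along each in-plane axis. The
   equivalent full `3x3x3` kernel has `K[i, j, k] = h(i) h(j) h'(k)`
   (leading time plane `[[1,2,1],[2,4,2],[1,2,1]]`, trailing plane its
   negation). No smoothing crosses the slice axis: slices are
   independent. Only the magnitude of the response is kept — contrast
   uptake and washout are equally informative — which also makes the
   correlation-vs-convolution flip convention immaterial; the package
   fixes it by a ramp oracle (a temporally linear signal of slope `c`
   gives interior magnitude `32 c`, since the in-plane triangle weights
   sum to 16 and the central difference straddles two steps).

3. **Per-slice entropy.** Every gradient slice is quantised to 256 gray
   levels and its Shannon entropy `-sum p_k log2 p_k` computed (range
   0–8 bits). By default one min/max over the *whole* gradient volume
   defines the level mapping, so entropies are comparable across slices
   and acquisitions; per-slice normalisation is available but documented
   as breaking exactly that comparability.

4. **Selection.** The most informative acquisition `t*` maximises the
   per-slice entropies aggregated over slices (`max` by default: the
   acquisition containing the single most informative slice; `mean` and
   `sum` selectable). Within `t*`, the most informative slice `z*` holds
   the maximum gradient magnitude (optionally across the whole
   sequence, or scored by entropy instead). Ties break toward the
   lowest index and are flagged. The precontrast acquisition is
   eligible by default — its boundary-handled gradient is attenuated —
   and can be excluded by flag.

5. **Synthetic images and decision.** The gradient volume at `t*` is
   collapsed into per-pixel mean and *population* standard-deviation
   images over slices (a fixed-population summary, not an estimate; a
   time-axis alternative at `z*` is selectable). Each image yields a
   peak statistic: the global maximum and its z-score
   `(max - mean) / std` over the whole image. A case is **abnormal**
   iff *both* images show a peak, i.e. both z-scores exceed the
   threshold `tau`. The conjunction is the safeguard: diffuse
   background parenchymal enhancement (BPE) inflates the mean image
   fairly uniformly, whereas a focal lesion, present in only a few
   slices, drives the across-slice standard deviation as well.

### The peak threshold `tau`

`tau` is the single tunable of the decision rule (default **5.0**,
dimensionless, exposed everywhere and embedded in every report). The
default is calibrated against the null: for an image of `n` roughly
independent pixels the maximum z-score concentrates near
`sqrt(2 ln n)` — about 4.1 for 64x64 and 4.4 for 128x128 — so a
threshold at 4 would flag "peaks" on structureless images about half
the time. 5.0 sits roughly three Gumbel scale units above the null mean
at desk-scale image sizes. For much larger matrices the operating point
should scale accordingly (`tau ≈ sqrt(2 ln n) + 1`); this n-dependence
is a known limitation of any global-maximum rule. Raising `tau` can
only turn abnormal calls into normal ones (monotonicity), and the
decision is invariant to positive rescaling of the input intensities
(z-scores are scale-free, the gradient is linear, and the level mapping
is min/max based).

## Kinetic-curve classifier and multimodal score

A time-signal curve is summarised by two phases. The **initial
enhancement** is the percent rise from the precontrast value to the
peak within the initial window (default: the first 3 postcontrast
acquisitions), classified `<50%` / `50–100%` / `>100%` — boundaries at
exactly 50% and 100% fall in the middle class (the interval is read as
inclusive, `>100%` as strict). The **postinitial change** is the
percent change from that peak to the final acquisition: continuous
(`> +10%`), plateau (within ±10%, endpoints inclusive), washout
(`< -10%`). Exactly one class per axis is assigned for any curve.

The multimodal lesion score sums 0–2 points over five
radiologist-provided descriptors (shape, border, contrast-medium
pattern, initial class, postinitial class), totals 0–8, and maps to
groups I (0–1, benign), II (2) and III (3, probably benign), IV (4–5,
suspicious abnormality) and V (6–8, highly suggestive of malignancy).
Morphology is never estimated from images; descriptors are caller
inputs, as they are radiologist readings in practice.

## The phantom

The generator emulates the statistical structure the pipeline assumes,
not anatomy:

* **Geometry.** A static chest band across the posterior `chest_depth`
  rows of every slice; two half-elliptical breasts of fatty tissue in
  front of it; a concentric fibroglandular core holding
  `glandular_fraction` (default 0.25) of the breast area. The first
  `breast_start_slice` slices (default 2) contain chest only, mimicking
  stack positions beyond the breast — and giving the chest-mask stage
  the "first slice of the sequence" it expects. Intensities are
  arbitrary scanner units: air 0, fat `baseline_intensity` (default
  100), glandular +10%, chest +30%.
* **BPE.** An exact-count random subset (`bpe_fraction`) of glandular
  voxels follows a mild persistent curve reaching 60% of its total
  amplitude (`bpe_amplitude`, default 0.4 = 40% of baseline) at the
  second postcontrast acquisition and the rest by the end. The fraction
  maps to the standard categories: minimal < 0.25 ≤ mild < 0.50 ≤
  moderate < 0.75 ≤ marked.
* **Lesions.** A sphere (or per-axis-radii ellipsoid for non-mass-like
  blobs) whose voxels follow a two-phase kinetic curve: linear rise
  from baseline to `baseline * (1 + initial/100)` at `peak_index`, then
  linear change to `peak * (1 + change/100)` at the last acquisition.
  Default: radius 2 voxels, initial enhancement 150%, washout −20%,
  peak at the second postcontrast acquisition — a small, strongly
  enhancing malignant-type mass. Curves whose postinitial drift is
  nonnegative are generated with the peak at the last initial-window
  acquisition, so that the in-window argmax of the generated curve is
  the generating peak and re-classification recovers the generating
  classes exactly.
* **Noise.** Additive zero-mean Gaussian (`noise_sigma`, default 2,
  i.e. signal-to-noise ≈ 50 against the baseline), clipped at zero;
  a Rician option (magnitude of a complex Gaussian-perturbed signal) is
  provided for realism. Equal seeds give bit-identical series.
* **Cohorts.** Case seeds derive from one cohort seed. BPE categories
  are drawn as minimal : mild : moderate : marked = 20 : 18 : 8 : 0
  (a screening-like mix in which marked enhancement is absent), with
  the enhancing fraction uniform inside the category band. Lesions draw
  radius U(2, 3) voxels, initial enhancement U(100, 200)%, class
  uniform over continuous/plateau/washout with a consistent change
  (U(15, 40) / U(−8, 8) / U(−40, −15)%).

**What the phantom does not emulate:** pharmacokinetic (Tofts-type)
contrast physiology, bolus-arrival delay, spatially correlated BPE
texture, field inhomogeneity, motion, or coil profiles. Acquisition
indices are ordinal; no physical seconds are modelled. Passing the
phantom-recovery tests therefore shows the pipeline's logic is correct
under its own assumptions, not that clinical accuracy is reproduced.

## Numerical choices

* Axis order is fixed internally as `(t, z, y, x)`; NIfTI's
  `(x, y, z, t)` is transposed on read. Indices are 0-based in code and
  1-based in every report.
* Temporal boundary handling defaults to replicate padding (first/last
  acquisitions get attenuated one-sided responses rather than spurious
  zero-padding edges); reflect and zero are selectable.
* Separable and full-kernel gradients agree exactly on integer data
  (all intermediates are exactly representable in float64) and to 1e-9
  relative tolerance on floats.
* Quantisation maps value `v` to `floor((v - lo) / (hi - lo) * 256)`
  clipped to `[0, 255]`; a degenerate (constant) gradient volume yields
  all-zero entropies with a warning, not an error.
* Standard deviations are population (`ddof = 0`) throughout the
  synthetic images; a single-plane stack yields a zero std image with a
  warning.
* DICOM phantom exports store float64 samples (DoubleFloatPixelData) so
  write→read round trips are bit-exact; integer DICOM input goes
  through the standard rescale-slope/intercept path. Readers order
  slices by metadata only, never by file name.

## Selection behaviour near the enhancement peak

The temporal central difference at acquisition `t` straddles
`t - 1` and `t + 1`, so for any curve that rises linearly from the
precontrast value the gradient magnitude — and with it the entropy of
the gradient images — is maximal one acquisition *before* the signal
peak (for a curve peaking at the second postcontrast acquisition, the
selected acquisition is the first postcontrast one). The selection
therefore recovers the contrast-arrival window rather than the peak
instant itself; on clinical data, where uptake typically straddles the
first and second postcontrast scans, both are plausible selections.
This stencil property is intrinsic to a symmetric derivative and is
asserted, not hidden, in the test suite.

## Problem sizes

Desk-scale defaults (6 acquisitions, 40 slices of 64x64) keep a full
pipeline run near 0.1 s, a 50-case cohort under 10 s, and the whole
test suite plus acceptance script well under a minute on one CPU, while
preserving every structural property the method depends on. Full-scale
geometry (150 slices, larger matrices) is a parameter change, not a
code path.

## Known limitations

* The decision uses global image statistics; multiple simultaneous
  lesions yield one peak location, and a lesion weaker than the BPE
  plateau in the mean image can be missed (the hardest cases are
  moderate BPE with modest lesions, mirroring clinical experience).
* `tau` must be rescaled for image sizes far from the desk scale (see
  above).
* The chest mask comes from one slice; stacks whose first slice already
  contains breast tissue need the `mask_source` override.
* BPE spatial randomness is voxel-independent, which slightly inflates
  the std image's speckle relative to smoothly varying real parenchyma.
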