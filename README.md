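# dcegrad

Temporal-gradient and entropy analysis of breast dynamic
contrast-enhanced MRI (DCE-MRI), with a seeded 4D phantom simulator.

## The problem

In breast DCE-MRI both lesions and normal fibroglandular tissue take up
contrast; the normal-tissue uptake (background parenchymal enhancement,
BPE) can be strong enough to hide lesions from visual reading. This
package implements a fully automatic screening pipeline that
characterises the enhancement of the *whole* breast over the dynamic
acquisitions and flags studies containing a focal suspicious region,
independent of the BPE degree and of lesion morphology (masses and
non-mass-like enhancement alike). It is aimed at researchers in
quantitative breast imaging who want a reproducible, testable reference
implementation of the method, plus ground-truth synthetic data to probe
it with.

## The method

Given a 4D series `S(t, z, y, x)` (`T` acquisitions, one precontrast;
`Z` axial slices):

1. **Chest removal** — the first slice of the sequence is binarised
   (Otsu) into a chest mask, which is zeroed out of every slice.
2. **Temporal Sobel gradient** — each slice is differentiated along the
   time axis: `G = |S * (h ⊗ h ⊗ h′)|` with triangle smoothing
   `h = (1, 2, 1)` in-plane and central difference `h′ = (1, 0, −1)`
   over `t` (a separable 3×3×3 kernel; both routes implemented, exactly
   equal on integer data).
3. **Entropy** — every gradient slice is quantised to 256 levels under
   one volume-wide gray mapping and scored by its Shannon entropy
   `E = −Σ p_k log₂ p_k` (0–8 bits).
4. **Selection** — the acquisition `t*` maximising the slice entropies,
   then the slice `z*` with the maximum gradient at `t*`.
5. **Decision** — per-pixel mean and standard-deviation images of
   `G(t*, ·, y, x)` over slices; the study is called *abnormal* iff
   **both** images show a peak, i.e. a maximum whose z-score
   `(max − mean)/std` exceeds `τ` (default 5.0). The peak location
   points at the lesion.

The package also ships the kinetic-curve classifier (initial
enhancement `<50 / 50–100 / >100 %`; postinitial continuous / plateau /
washout at ±10 %) and the 0–8-point multimodal lesion score with its
diagnostic groups I–V.

The phantom module generates 4D breast phantoms with a static chest
band, configurable BPE fraction (minimal/mild/moderate/marked) and
amplitude, optional lesions with prescribed kinetics, Gaussian or
Rician noise, and full ground truth — deterministic per seed. See
`docs/methods.md` for the model, defaults and limitations.

## Worked example

Simulate a phantom with moderate BPE (30 % of glandular voxels
enhancing) and a strong washout lesion centred at voxel
(slice 20, row 30, col 17), then analyse it:

```sh
cat > phantom.yaml <<'YAML'
n_slices: 40
slice_shape: [64, 64]
chest_depth: 12
seed: 42
bpe_fraction: 0.3
lesion:
  center: [20, 30, 17]
  radius_voxels: 2.0
  initial_enhancement_pct: 150
  postinitial_class: washout
  postinitial_change_pct: -20
YAML
dcegrad simulate --config phantom.yaml --out case
dcegrad run --input case/phantom.nii.gz --out analysis
```

The run prints (abridged; the full JSON, the two synthetic images and
the selected slice are written to `analysis/`):

```json
{
  "decision": "abnormal",
  "selected_acquisition": 2,
  "selected_slice": 20,
  "peak_mean":  {"location": [30, 17], "z_score": 6.18,  "is_peak": true},
  "peak_std":   {"location": [30, 17], "z_score": 20.02, "is_peak": true}
}
```

Reading: the entropy of the temporal-gradient images is maximal at the
first postcontrast acquisition (reported 1-based as 2 — the acquisition
straddling the contrast arrival); the highest gradient sits at slice 20,
adjacent to the lesion's centre slice; both synthetic images peak at
exactly the lesion's in-plane position (row 30, col 17) with z-scores
6.2 and 20.0, far above τ = 5, so the case is flagged abnormal. A
lesion-free phantom under the same settings yields z-scores near 4 in
both images and the decision `normal`.

Other entry points: `dcegrad batch` (directory of cases → per-case
reports plus a cohort CSV), `dcegrad score` (multimodal lesion score
from descriptors), `dcegrad curve` (kinetic classification of a CSV
time-signal curve). Everything is also available as a library
(`dcegrad.generate_phantom`, `dcegrad.temporal_gradient`,
`dcegrad.cli.run_pipeline`, …).

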