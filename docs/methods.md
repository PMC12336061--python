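# Methods

All geometry is metric: an array index `i` maps to world position
`i * spacing_mm + origin_mm`. Arrays are ordered `(nx, ny, nz)`; the
blockface sectioning axis is the third.

## Synthetic specimen (`bbq.phantom`)

`make_phantom` builds a labeled 3-D scene on an isotropic grid (≥ 32 voxels
per axis): background (0), paraffin block (1), white matter (2), grey
matter (3), a cortical ribbon (4), and smooth tubular vessels (5) traversing
the block. Renderers map labels to modality-specific mean intensities and
add Gaussian noise plus smooth multiplicative bias:

* **MRI** — bright ribbon/WM contrast; an optional rigid+scale misalignment
  produces the "as-acquired" volume, with the true transform recorded.
* **Blockface photographs** — per-section 2-D images with a perspective-like
  affine distortion (anisotropic scale + shear), per-section translational
  jitter, multiplicative line (column) gain noise, a lateral bias gradient,
  and depth contamination (each photo mixes the current section with the one
  beneath it, 0.7/0.3).
* **Calibration grid** — a printed dot lattice with known pitch rendered
  through the same distortion, with the true dot centers recorded.
* **Histology sections** — selected sections re-rendered with a stain
  intensity remap (ribbon brightest), an independent smooth random in-plane
  displacement field of bounded amplitude, and noise.

Every corruption's parameters and true transforms are returned as ground
truth, enabling oracle-style tests of each processing step.

## Blockface reconstruction (`bbq.blockface`)

1. **Calibration.** Dots are segmented by percentile thresholding and
   localized by intensity centroids (sub-pixel). Lattice indices are
   assigned by KD-tree neighbour-difference voting; a 2-D affine mapping
   pixel → mm is fit by least squares (fitting mm → px and inverting) with
   the RMS residual reported. `apply_calibration` resamples each photo onto
   an isotropic grid (pixel size = the affine's smallest singular value),
   anchored at the image centre.
2. **QC.** Flagged sections are replaced by their nearest preceding valid
   section; section 0 cannot be excluded.
3. **Vertical alignment.** Neighbouring sections are aligned by 1-D
   normalized cross-correlation along the vertical axis with parabolic
   sub-pixel refinement, re-anchored so the middle section is fixed.
4. **Line-artifact removal.** Technique A divides each column by the ratio
   of its mean to the mean of its flanking-window neighbours (moving-average
   destriping of multiplicative gain). Technique B notches low-`ky`,
   non-DC-`kx` Fourier coefficients, removing coherent column sinusoids
   while preserving the global mean exactly.
5. **Assembly.** Cleaned sections are stacked into an `ImageVolume` with the
   known section spacing. `reconstruct` chains these steps (technique A:
   destripe then median filter; B: median then notch) and returns a log.

## MIND descriptors (`bbq.mind`)

For each voxel, patch distances `Dp` to the 6 axial neighbours (4 in 2-D)
are computed with a reflect-padded box sum over a small patch. A local
variance estimate `V` (mean of the `Dp`, floored at a small fraction of the
image variance) converts distances to similarities `exp(-Dp / V)`, which are
normalized by their per-location maximum — so every component lies in
`(0, 1]` and each location's maximum is exactly 1. The cost between two
images is the mean squared difference of descriptor vectors. Because the
descriptors depend only on intensity *relations* within a neighbourhood,
the cost is invariant to affine intensity rescaling, making it suitable
across modalities.

## Registration (`bbq.register`, `bbq.transforms`)

Transforms are chains of stages; linear stages store `(M, t, center)` with
pull action `x ↦ M(x − c) + c + t`, and the nonlinear stage is a cubic
B-spline displacement field whose control-point motion is capped at 0.4 ×
the control spacing, guaranteeing invertibility (inverses are computed
numerically onto a displacement field). Chains serialize to JSON and invert
exactly (linear) or to within a small residual (nonlinear), reported by
`roundtrip_residual_mm`.

`register` runs a coarse-to-fine pyramid over stages rigid → scale →
affine → nonlinear (configurable; a 2-D default exists for section
registration). Linear stages are optimized by Nelder-Mead on scaled
parameters; the moving image is resampled and its MIND descriptors are
recomputed at every cost evaluation (warping precomputed descriptors breaks
the max normalization). Both images are pre-smoothed slightly to equalize
noise floors across modalities. The nonlinear stage minimizes MIND cost
plus a bending-energy penalty by L-BFGS-B with analytic gradients, inside an
outer re-linearization loop. Each stage reverts if it worsens the
objective; per-stage objective values are attached to the returned chain.

## Evaluation (`bbq.metrics`)

* **Dice** on whole-tissue (or per-label) masks, with chain-aware
  resampling of the moving label map; empty-vs-empty is undefined (NaN,
  with a warning).
* **Histology volume reconstruction** stacks registered sections into a
  volume, filling unsampled planes by nearest or linear interpolation along
  the sectioning axis with clamping at the ends.
* **Vessel agreement**: masks are skeletonized (single 26-connected
  component required), ordered into a curve, resampled uniformly by arc
  length, and compared by mean point distance with endpoint-flip matching.

## Pipeline (`bbq.pipeline`)

`run_pipeline` executes simulate → reconstruct → register3d → extract →
register2d → evaluate, writing per-stage artifacts (calibration JSON,
blockface NIfTI, transform chains, per-section TIFFs, metrics CSV,
histology volume) and a manifest with per-stage objectives and whole-tissue
Dice scores. The 2-D per-section score compares the registered MRI's label
plane at each section index against the histology ground-truth labels pulled
through that section's 2-D chain — the 2-D analog of the 3-D
MRI-vs-blockface comparison. Failures raise `PipelineError` naming the
stage. Configurations round-trip through YAML and hash stably for
provenance.
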