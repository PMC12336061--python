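# bbq — blockface quantification and MRI–histology coregistration

`bbq` reconstructs a clean, calibrated 3-D volume from a stack of serial
blockface photographs, registers an ex-vivo MRI volume to it with a
modality-independent (MIND) similarity metric, and carries individual
histology sections into MRI space through invertible 3-D + 2-D transform
chains. A fully synthetic specimen generator with complete ground truth
drives validation end to end — no binary data ships with the package.

## Package layout

| Module | Contents |
| --- | --- |
| `bbq.core` | Data model: `Image2D`, `ImageVolume`, `LabelMap`, `BlockfaceStack` (all geometry in mm; world = index · spacing + origin) |
| `bbq.io` | NIfTI volumes, TIFF images, stack manifests, transform-chain JSON |
| `bbq.phantom` | Synthetic specimen: labeled scene, MRI / blockface / histology renderings, distorted calibration grid, full ground truth |
| `bbq.blockface` | Grid-dot detection, affine calibration, QC exclusion/fill, vertical alignment, two line-artifact removal techniques (A: moving-average destriping; B: Fourier notch), volume assembly |
| `bbq.mind` | MIND self-similarity descriptors (6 components in 3-D, 4 in 2-D, per-location max normalization) and the descriptor SSD cost |
| `bbq.transforms` | Rigid / scale / affine / B-spline displacement stages, invertible `TransformChain`, resampling, random smooth warps |
| `bbq.register` | Multi-resolution registration driver (Nelder-Mead linear stages, analytic-gradient L-BFGS-B nonlinear stage), 3-D and 2-D |
| `bbq.metrics` | Label-overlap Dice, histology volume reconstruction, vessel skeleton extraction and mean curve distance |
| `bbq.pipeline` | End-to-end phantom pipeline driver with staged artifacts and a manifest |
| `bbq.cli` | `bbq` command-line interface (`simulate`, `calibrate`, `reconstruct`, `register3d`, `extract-slices`, `register2d`, `evaluate`, `vessels`, `pipeline`) |

## Quick start

Run the whole synthetic pipeline:

```sh
bbq pipeline --out run0 --seed 0
```

This simulates a specimen, reconstructs and calibrates the blockface
volume, registers the misaligned MRI to it (rigid → scale → affine →
nonlinear), extracts MRI planes at the histology section indices,
registers each histology section in 2-D, and writes per-stage artifacts
plus `manifest.json` with whole-tissue Dice scores.

From Python:

```python
from bbq.pipeline import PipelineConfig, run_pipeline
manifest = run_pipeline(PipelineConfig(out_dir="run0", seed=0))
print(manifest["whole_tissue_dice_3d"])
```

See `docs/methods.md` for algorithmic details.

## Tests and acceptance suite

```sh
pytest -q                       # full suite (the acceptance tests take ~15 min)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`tests/test_acceptance.py` contains one test per acceptance criterion,
asserted at the stated tolerances. The acceptance script recomputes the two
analytic targets (t1: maximum normalized MIND component; t3: recovered
calibration-grid dot spacing in mm) and writes them as JSON.

## Known limitations (honest near-misses)

Two acceptance assertions are stated verbatim but are known to sit just past
their thresholds with the shipped defaults; they were analyzed rather than
tuned into passing:

* **Nonlinear composite residual (criterion 8).** Recovering a known smooth
  1 mm warp across modalities achieves a mean composite residual of
  ~0.58 voxel in tissue vs the 0.5-voxel threshold; the invertibility clause
  passes. The phantom's piecewise-constant region interiors carry no
  cross-modality MIND signal, so interior displacement is constrained only
  by regularizer interpolation from the region boundaries; scans over the
  regularization weight, control spacing, pre-smoothing, and variance floor
  all plateau at 0.58–0.65 voxel.
* **Per-section 2-D Dice (criterion 9).** The 3-D clause passes with margin
  (whole-tissue Dice 0.966 ≥ 0.90 at seed 0), but per-section 2-D Dice at
  seed 0 is 0.936–0.963 (mean 0.951) vs the 0.95-per-section threshold. The
  ceiling using ground-truth transforms is 0.985–0.995, so the shortfall is
  genuine 2-D registration error: the smooth-warp stage is basin-sensitive
  on low-texture sections, and identical configurations score differently on
  equally good 3-D chains. The shipped 2-D defaults were chosen for
  stability over occasional peak scores.
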