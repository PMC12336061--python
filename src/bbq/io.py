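"""File I/O: NIfTI volumes, TIFF stacks with JSON manifests, CSV reports."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile

from .core import ImageVolume, LabelMap, BlockfaceStack, Image2D

__all__ = [
    "read_volume", "write_volume",
    "read_labels", "write_labels",
    "read_stack", "write_stack",
    "read_image2d", "write_image2d",
]


def write_volume(vol: ImageVolume, path) -> None:
    """Write a volume as NIfTI; spacing goes into the affine diagonal and the
    origin into its translation column."""
    affine = np.diag([*vol.spacing_mm, 1.0])
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(vol.voxels.astype(np.float64), affine), str(path))


def read_volume(path) -> ImageVolume:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"volume not found: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises various types for bad files
        raise ValueError(f"could not read {path} as NIfTI: {exc}") from exc
    affine = img.affine
    data = np.asarray(img.dataobj, dtype=np.float64)
    spacing = tuple(float(np.linalg.norm(affine[:3, d])) for d in range(3))
    origin = tuple(float(v) for v in affine[:3, 3])
    return ImageVolume(data, spacing, origin)


def write_labels(labels: LabelMap, path) -> None:
    if labels.labels.ndim != 3:
        raise ValueError("only 3-D label maps are written as NIfTI")
    affine = np.diag([*labels.spacing_mm, 1.0])
    affine[:3, 3] = labels.origin
    nib.save(nib.Nifti1Image(labels.labels.astype(np.int32), affine), str(path))


def read_labels(path, label_names=None) -> LabelMap:
    vol = read_volume(path)
    return LabelMap(vol.voxels.astype(np.int32), vol.spacing_mm, vol.origin_mm,
                    label_names=label_names or {})


def write_image2d(image: Image2D, path) -> None:
    tifffile.imwrite(str(path), image.pixels.astype(np.float32))


def read_image2d(path, pixel_size_mm: float, **meta) -> Image2D:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    return Image2D(tifffile.imread(str(path)).astype(float), pixel_size_mm,
                   **meta)


def write_stack(stack: BlockfaceStack, directory, prefix: str = "blockface"
                ) -> Path:
    """Write numbered TIFF slices plus a JSON manifest; returns the manifest
    path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = []
    for pos, idx in enumerate(stack.section_indices):
        fname = f"{prefix}_{idx:05d}.tif"
        tifffile.imwrite(str(directory / fname),
                         stack.slices[pos].astype(np.float32))
        entries.append({"file": fname, "section_index": idx,
                        "excluded": bool(stack.excluded[pos]),
                        "vertical_offset_mm": float(stack.vertical_offsets_mm[pos])})
    manifest = {
        "pixel_size_mm": stack.pixel_size_mm,
        "section_spacing_mm": stack.section_spacing_mm,
        "origin_mm": list(stack.origin_mm),
        "slices": entries,
    }
    mpath = directory / f"{prefix}_manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return mpath


def read_stack(manifest_path) -> BlockfaceStack:
    """Read a stack from its JSON manifest; slices are ordered by section
    index regardless of the on-disk listing, and numbering gaps produce a
    warning (not an error: sparse histology sampling is legitimate)."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    entries = sorted(manifest["slices"], key=lambda e: e["section_index"])
    directory = manifest_path.parent
    missing = [e["file"] for e in entries if not (directory / e["file"]).exists()]
    if missing:
        raise ValueError(f"manifest lists files that do not exist: {missing}")
    idx = [e["section_index"] for e in entries]
    gaps = [g for a, b in zip(idx, idx[1:]) for g in range(a + 1, b)]
    if gaps:
        warnings.warn(f"section numbering has gaps at {gaps}")
    slices = [tifffile.imread(str(directory / e["file"])).astype(float)
              for e in entries]
    return BlockfaceStack(
        slices=slices,
        section_indices=idx,
        pixel_size_mm=float(manifest["pixel_size_mm"]),
        section_spacing_mm=float(manifest["section_spacing_mm"]),
        excluded=[bool(e.get("excluded", False)) for e in entries],
        vertical_offsets_mm=[float(e.get("vertical_offset_mm", 0.0))
                             for e in entries],
        origin_mm=tuple(manifest.get("origin_mm", (0.0, 0.0))),
    )
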