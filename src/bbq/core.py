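"""Shared data containers for the blockface/MRI coregistration pipeline.

Coordinate conventions, used everywhere in this package:

* volumes are ``(nx, ny, nz)`` arrays; 2-D images are ``(nx, ny)``;
* axis 0 is the horizontal in-plane axis (photo columns), axis 1 is the
  vertical in-plane axis (photo rows), axis 2 is the sectioning axis (z);
* voxel indices are 0-based and world position (mm) = index * spacing + origin.

All physical quantities are millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "Image2D",
    "ImageVolume",
    "LabelMap",
    "BlockfaceStack",
]


def _as_float_array(a, ndim: int, name: str) -> np.ndarray:
    arr = np.asarray(a, dtype=float)
    if arr.ndim != ndim:
        raise ValueError(f"{name} must be {ndim}-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass
class Image2D:
    """A single 2-D image with physical pixel size.

    ``section_index`` ties blockface photographs and histology sections to
    their position in the cutting sequence; ``source`` tags the modality
    ("blockface", "mri", "histology", ...).
    """

    pixels: np.ndarray
    pixel_size_mm: float
    origin_mm: tuple[float, float] = (0.0, 0.0)
    section_index: int | None = None
    source: str = ""

    def __post_init__(self) -> None:
        self.pixels = _as_float_array(self.pixels, 2, "pixels")
        if not self.pixel_size_mm > 0:
            raise ValueError("pixel_size_mm must be positive")
        self.origin_mm = (float(self.origin_mm[0]), float(self.origin_mm[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def spacing(self) -> np.ndarray:
        return np.array([self.pixel_size_mm, self.pixel_size_mm])

    @property
    def origin(self) -> np.ndarray:
        return np.asarray(self.origin_mm, dtype=float)

    def copy(self, pixels: np.ndarray | None = None) -> "Image2D":
        out = replace(self)
        out.pixels = self.pixels.copy() if pixels is None else np.asarray(pixels, float)
        return out


@dataclass
class ImageVolume:
    """A 3-D intensity grid with anisotropic voxel spacing and origin (mm)."""

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = _as_float_array(self.voxels, 3, "voxels")
        sp = tuple(float(s) for s in self.spacing_mm)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError("spacing_mm must be 3 positive scalars")
        self.spacing_mm = sp
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def spacing(self) -> np.ndarray:
        return np.asarray(self.spacing_mm, dtype=float)

    @property
    def origin(self) -> np.ndarray:
        return np.asarray(self.origin_mm, dtype=float)

    def world_extent(self) -> np.ndarray:
        """Physical size of the grid (mm) along each axis."""
        return (np.array(self.shape) - 1) * self.spacing

    def plane(self, k: int, source: str = "") -> Image2D:
        """Extract z-plane ``k`` as a 2-D image (isotropic in-plane spacing required)."""
        if not 0 <= k < self.shape[2]:
            raise IndexError(f"plane index {k} out of range [0, {self.shape[2]})")
        sx, sy, _ = self.spacing_mm
        if not np.isclose(sx, sy):
            raise ValueError("plane extraction requires isotropic in-plane spacing")
        return Image2D(
            self.voxels[:, :, k].copy(),
            pixel_size_mm=sx,
            origin_mm=(self.origin_mm[0], self.origin_mm[1]),
            section_index=k,
            source=source,
        )

    def copy(self, voxels: np.ndarray | None = None) -> "ImageVolume":
        out = replace(self)
        out.voxels = self.voxels.copy() if voxels is None else np.asarray(voxels, float)
        return out


@dataclass
class LabelMap:
    """An integer segmentation grid (2-D or 3-D) with label names.

    Label 0 is background by convention; "whole tissue" means the union of
    all non-zero labels.
    """

    labels: np.ndarray
    spacing_mm: Sequence[float]
    origin_mm: Sequence[float] | None = None
    label_names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise ValueError("labels must be integers")
            arr = arr.astype(np.int32)
        if arr.ndim not in (2, 3):
            raise ValueError("labels must be a 2-D or 3-D grid")
        if arr.min() < 0:
            raise ValueError("labels must be non-negative")
        self.labels = arr
        sp = tuple(float(s) for s in self.spacing_mm)
        if len(sp) != arr.ndim or any(s <= 0 for s in sp):
            raise ValueError("spacing_mm must match dimensionality and be positive")
        self.spacing_mm = sp
        if self.origin_mm is None:
            self.origin_mm = (0.0,) * arr.ndim
        else:
            self.origin_mm = tuple(float(o) for o in self.origin_mm)
        self.label_names = dict(self.label_names)

    @property
    def spacing(self) -> np.ndarray:
        return np.asarray(self.spacing_mm, dtype=float)

    @property
    def origin(self) -> np.ndarray:
        return np.asarray(self.origin_mm, dtype=float)

    def present_labels(self) -> list[int]:
        return [int(v) for v in np.unique(self.labels) if v != 0]


@dataclass
class BlockfaceStack:
    """An ordered stack of blockface photographs of a sectioned block.

    ``section_spacing_mm`` is the microtome advance per cut (5-10 um in
    practice), i.e. the through-plane spacing of the assembled volume.
    ``vertical_offsets_mm`` is filled in by the 1-D alignment step.
    """

    slices: list[np.ndarray]
    section_indices: list[int]
    pixel_size_mm: float
    section_spacing_mm: float
    excluded: list[bool] = field(default_factory=list)
    vertical_offsets_mm: list[float] = field(default_factory=list)
    origin_mm: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.slices = [np.asarray(s, dtype=float) for s in self.slices]
        if any(s.ndim != 2 for s in self.slices):
            raise ValueError("every slice must be a 2-D array")
        n = len(self.slices)
        self.section_indices = [int(i) for i in self.section_indices]
        if len(self.section_indices) != n:
            raise ValueError("section_indices must match number of slices")
        if n > 1 and not np.all(np.diff(self.section_indices) > 0):
            raise ValueError("section_indices must be strictly increasing")
        if not self.pixel_size_mm > 0:
            raise ValueError("pixel_size_mm must be positive")
        if not self.section_spacing_mm > 0:
            raise ValueError("section_spacing_mm must be positive")
        if not self.excluded:
            self.excluded = [False] * n
        if len(self.excluded) != n:
            raise ValueError("excluded flags must match number of slices")
        if not self.vertical_offsets_mm:
            self.vertical_offsets_mm = [0.0] * n
        if len(self.vertical_offsets_mm) != n:
            raise ValueError("vertical_offsets_mm must match number of slices")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def uniform_shape(self) -> tuple[int, int]:
        shapes = {s.shape for s in self.slices}
        if len(shapes) != 1:
            raise ValueError(f"slices have ragged shapes: {sorted(shapes)}")
        return next(iter(shapes))

    def copy(self) -> "BlockfaceStack":
        return BlockfaceStack(
            slices=[s.copy() for s in self.slices],
            section_indices=list(self.section_indices),
            pixel_size_mm=self.pixel_size_mm,
            section_spacing_mm=self.section_spacing_mm,
            excluded=list(self.excluded),
            vertical_offsets_mm=list(self.vertical_offsets_mm),
            origin_mm=self.origin_mm,
        )
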