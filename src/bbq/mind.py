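"""Modality Independent Neighbourhood Descriptor (MIND).

At each location ``x`` of an image ``I`` the descriptor holds, for each offset
``r`` in a search region ``R``,

    MIND(I, x, r) = (1 / n) * exp(-Dp(I, x, r) / V(I, x)),

where ``Dp`` is a patch-wise sum of squared intensity differences between the
patch at ``x`` and the patch at ``x + r``, ``V`` is a patch-wise variance
estimate (here: the mean of Dp over R, floored at a small epsilon), and ``n``
normalizes so the largest component at each location is exactly 1.

With the immediate-neighbourhood search region this yields a 6-vector per
voxel in 3-D and a 4-vector per pixel in 2-D.  The patch is the centre
point plus its immediate axial neighbours (7 points in 3-D, 5 in 2-D).
Boundaries use reflected image padding.

Because ``Dp`` and ``V`` both scale with the square of any affine intensity
rescaling, the descriptor — and hence the registration cost built on it — is
invariant to monotone linear contrast changes, which is what makes it usable
across MRI, blockface, and histology contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import Image2D, ImageVolume

__all__ = ["MindField", "compute_mind", "mind_cost", "mind_descriptors"]

#: Relative variance floor: epsilon = VARIANCE_FLOOR_REL * var(I).
VARIANCE_FLOOR_REL = 1e-6


def _axis_offsets(ndim: int) -> list[tuple[int, ...]]:
    """Immediate axial neighbour offsets (2*ndim of them), in fixed order."""
    offsets = []
    for ax in range(ndim):
        for sign in (-1, 1):
            o = [0] * ndim
            o[ax] = sign
            offsets.append(tuple(o))
    return offsets


@dataclass
class MindField:
    """Per-location MIND descriptor vectors.

    ``descriptors`` has shape ``(k, *image_shape)`` with ``k = 2 * ndim``
    (one component per search-region offset, in :func:`_axis_offsets` order).
    """

    descriptors: np.ndarray
    search_offsets: list[tuple[int, ...]]
    patch_offsets: list[tuple[int, ...]]
    variance_floor: float

    @property
    def ndim(self) -> int:
        return self.descriptors.ndim - 1

    @property
    def n_components(self) -> int:
        return self.descriptors.shape[0]


def mind_descriptors(intensities: np.ndarray,
                     variance_floor_rel: float = VARIANCE_FLOOR_REL) -> np.ndarray:
    """Raw descriptor array ``(2*ndim, *shape)`` for a plain intensity grid."""
    arr = np.asarray(intensities, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite intensities")
    if any(s < 3 for s in arr.shape):
        raise ValueError("image extents must be at least 3 per axis")
    ndim = arr.ndim
    search = _axis_offsets(ndim)
    patch = [tuple([0] * ndim)] + _axis_offsets(ndim)

    # Dp(x, r) = sum_{o in patch} (I(x+o) - I(x+r+o))^2
    #          = [box-sum over patch offsets of (I - shift_r I)^2](x),
    # computed on a reflect-padded copy so boundary locations are defined.
    pad = 2
    padded = np.pad(arr, pad, mode="reflect")

    kernel = np.zeros((3,) * ndim)
    for o in patch:
        kernel[tuple(i + 1 for i in o)] = 1.0

    core = tuple(slice(pad, pad + s) for s in arr.shape)
    dp = np.empty((len(search), *arr.shape))
    for i, r in enumerate(search):
        # shift the padded image by r, square the difference, box-sum over patch
        rolled = np.roll(padded, shift=[-r[d] for d in range(ndim)],
                         axis=tuple(range(ndim)))
        d2 = (padded - rolled) ** 2
        summed = ndimage.correlate(d2, kernel, mode="nearest")
        dp[i] = summed[core]

    eps = max(variance_floor_rel * float(np.var(arr)), np.finfo(float).tiny)
    v = np.maximum(dp.mean(axis=0), eps)
    comp = np.exp(-dp / v)
    n = comp.max(axis=0)
    return comp / n


def compute_mind(image: ImageVolume | Image2D | np.ndarray,
                 variance_floor_rel: float = VARIANCE_FLOOR_REL) -> MindField:
    """MIND descriptor field of a 2-D or 3-D image."""
    if isinstance(image, ImageVolume):
        arr = image.voxels
    elif isinstance(image, Image2D):
        arr = image.pixels
    else:
        arr = np.asarray(image, dtype=float)
    desc = mind_descriptors(arr, variance_floor_rel)
    ndim = arr.ndim
    return MindField(
        descriptors=desc,
        search_offsets=_axis_offsets(ndim),
        patch_offsets=[tuple([0] * ndim)] + _axis_offsets(ndim),
        variance_floor=max(variance_floor_rel * float(np.var(arr)),
                           np.finfo(float).tiny),
    )


def mind_cost(fixed: MindField | np.ndarray, moving: MindField | np.ndarray) -> float:
    """Mean Euclidean distance between corresponding descriptor vectors.

    The mean (rather than the sum) makes values comparable across pyramid
    levels and image sizes.
    """
    a = fixed.descriptors if isinstance(fixed, MindField) else np.asarray(fixed)
    b = moving.descriptors if isinstance(moving, MindField) else np.asarray(moving)
    if a.shape != b.shape:
        raise ValueError(f"descriptor grids differ: {a.shape} vs {b.shape}")
    return float(np.mean(np.sqrt(np.sum((a - b) ** 2, axis=0))))
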