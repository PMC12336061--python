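"""Blockface photograph stack -> clean calibrated 3-D volume.

Processing order (enforced by :func:`reconstruct`): perspective calibration,
quality-control exclusion with duplication fill, 1-D vertical translation
alignment, cropping/resampling, vertical-line artifact removal (technique "A",
a sliding column normalization, or technique "B", a Fourier notch), 3-D
median filtering, volume assembly.

Technique A normalizes each column multiplicatively by the mean of its
flanking columns inside a sliding window — blade artifacts modulate
reflectance, so a ratio correction removes them while preserving tissue
contrast.  Technique B zeroes the Fourier coefficients on the
zero-vertical-frequency line (where patterns that are constant along the
vertical axis concentrate), sparing a band around the DC origin so the
global intensity is untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import Image2D, ImageVolume, BlockfaceStack

__all__ = [
    "CalibrationModel",
    "detect_grid_points",
    "assign_lattice_indices",
    "estimate_calibration",
    "apply_calibration",
    "qc_exclude_and_fill",
    "align_vertical_translation",
    "crop_and_resample",
    "remove_lines_moving_average",
    "remove_lines_fourier",
    "median_filter_stack",
    "assemble_volume",
    "reconstruct",
]


@dataclass
class CalibrationModel:
    """In-plane affine mapping raw pixel coordinates to physical mm.

    ``affine`` is 2x3: ``mm = L @ px + t``.  ``residual_rms_px`` is the RMS
    misfit of the detected dots against the fitted lattice, in pixels.
    """

    affine: np.ndarray
    residual_rms_px: float
    n_points: int

    def __post_init__(self) -> None:
        a = np.asarray(self.affine, float)
        if a.shape != (2, 3):
            raise ValueError("affine must be 2x3")
        if abs(np.linalg.det(a[:, :2])) < 1e-15:
            raise ValueError("affine is singular")
        if not np.isfinite(self.residual_rms_px):
            raise ValueError("residual_rms_px must be finite")
        self.affine = a

    def px_to_mm(self, pts_px: np.ndarray) -> np.ndarray:
        a = self.affine
        return np.asarray(pts_px, float) @ a[:, :2].T + a[:, 2]

    def to_dict(self) -> dict:
        return {"affine": self.affine.tolist(),
                "residual_rms_px": float(self.residual_rms_px),
                "n_points": int(self.n_points)}

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationModel":
        return cls(np.array(d["affine"]), d["residual_rms_px"], d["n_points"])


class CalibrationError(RuntimeError):
    """Raised when a calibration grid cannot be detected or fitted."""


def detect_grid_points(grid_image: Image2D | np.ndarray,
                       intensity_threshold: float | None = None,
                       min_area_px: int = 4) -> np.ndarray:
    """Detect dark calibration dots and return their centroids (px).

    Pixels darker than the threshold (default: midway between the image's
    1st and 99th percentile) form connected components; components above the
    minimum area contribute an intensity-weighted centroid.  Points are
    returned row-major by lattice position.
    """
    img = grid_image.pixels if isinstance(grid_image, Image2D) else \
        np.asarray(grid_image, float)
    if img.size == 0:
        raise CalibrationError("empty calibration image")
    if intensity_threshold is None:
        lo, hi = np.percentile(img, [1, 99])
        intensity_threshold = 0.5 * (lo + hi)
    dark = img < intensity_threshold
    lab, n = ndimage.label(dark)
    if n == 0:
        raise CalibrationError("no dots found in calibration image")
    weights = np.maximum(intensity_threshold - img, 0.0)
    centers = []
    for i in range(1, n + 1):
        mask = lab == i
        if mask.sum() < min_area_px:
            continue
        w = weights * mask
        total = w.sum()
        xs, ys = np.nonzero(mask)
        cx = float((w[xs, ys] * xs).sum() / total)
        cy = float((w[xs, ys] * ys).sum() / total)
        centers.append((cx, cy))
    if len(centers) < 6:
        raise CalibrationError(
            f"only {len(centers)} dots detected; at least 6 are required")
    pts = np.asarray(centers)
    ij = assign_lattice_indices(pts)
    order = np.lexsort((ij[:, 1], ij[:, 0]))
    return pts[order]


def assign_lattice_indices(points: np.ndarray) -> np.ndarray:
    """Assign integer lattice coordinates (i, j) to detected grid points.

    The two lattice basis vectors are voted from nearest-neighbour difference
    vectors (median over the dominant direction clusters); integer coordinates
    follow by rounding in the basis frame.  Ties are broken row-major.
    """
    pts = np.asarray(points, float)
    n = len(pts)
    if n < 4:
        raise CalibrationError("too few points to infer a lattice")
    tree = cKDTree(pts)
    k = min(5, n)
    _, idx = tree.query(pts, k=k)
    diffs = []
    for i in range(n):
        for j in idx[i, 1:]:
            diffs.append(pts[j] - pts[i])
    diffs = np.asarray(diffs)
    # fold to a half plane so v and -v vote together
    flip = (diffs[:, 0] < 0) | ((diffs[:, 0] == 0) & (diffs[:, 1] < 0))
    diffs[flip] *= -1
    lengths = np.linalg.norm(diffs, axis=1)
    med = np.median(lengths)
    near = diffs[(lengths > 0.5 * med) & (lengths < 1.5 * med)]
    if len(near) == 0:
        raise CalibrationError("could not infer lattice spacing")

    def dominant(cands: np.ndarray) -> np.ndarray:
        seed_dir = cands[np.argmin(np.linalg.norm(cands, axis=1))]
        seed_dir = seed_dir / np.linalg.norm(seed_dir)
        cos = np.abs(cands @ seed_dir) / np.linalg.norm(cands, axis=1)
        cluster = cands[cos > np.cos(np.deg2rad(20))]
        return np.median(cluster, axis=0)

    v1 = dominant(near)
    u1 = v1 / np.linalg.norm(v1)
    cos = np.abs(near @ u1) / np.linalg.norm(near, axis=1)
    rest = near[cos < np.cos(np.deg2rad(60))]
    if len(rest) == 0:
        raise CalibrationError("grid points appear collinear")
    v2 = dominant(rest)
    # first basis vector = the more horizontal one, so (i, j) track (x, y)
    if abs(v1[0]) * np.linalg.norm(v2) < abs(v2[0]) * np.linalg.norm(v1):
        v1, v2 = v2, v1
    basis = np.column_stack([v1, v2])
    if abs(np.linalg.det(basis)) < 1e-9:
        raise CalibrationError("degenerate lattice basis")
    origin = pts[np.argmin(np.linalg.norm(pts - pts.mean(axis=0), axis=1))]
    coords = np.linalg.solve(basis, (pts - origin).T).T
    ij = np.round(coords).astype(int)
    ij -= ij.min(axis=0)
    # orient so index (0, 0) is the top-left point
    if basis[0, 0] < 0:
        ij[:, 0] = ij[:, 0].max() - ij[:, 0]
    if basis[1, 1] < 0:
        ij[:, 1] = ij[:, 1].max() - ij[:, 1]
    if len(np.unique(ij, axis=0)) != len(ij):
        raise CalibrationError("lattice index assignment is ambiguous")
    return ij


def estimate_calibration(points: np.ndarray, dot_spacing_mm: float
                         ) -> CalibrationModel:
    """Least-squares affine mapping detected dot centroids to the ideal lattice.

    The ideal lattice places point (i, j) at (i, j) * dot_spacing_mm.  The
    model's ``affine`` maps raw pixels to these physical coordinates.
    """
    pts = np.asarray(points, float)
    if len(pts) < 3:
        raise CalibrationError("at least 3 points are required")
    ij = assign_lattice_indices(pts)
    ideal_mm = ij.astype(float) * dot_spacing_mm
    # fit mm -> px first so the residual is naturally in pixels
    design = np.column_stack([ideal_mm, np.ones(len(pts))])
    if np.linalg.matrix_rank(design) < 3:
        raise CalibrationError("collinear points: affine fit is rank deficient")
    sol, _, _, _ = np.linalg.lstsq(design, pts, rcond=None)
    fitted_px = design @ sol
    residual_rms_px = float(np.sqrt(np.mean(np.sum((fitted_px - pts) ** 2, axis=1))))
    b_lin, b_off = sol[:2].T, sol[2]
    a_lin = np.linalg.inv(b_lin)
    a_off = -a_lin @ b_off
    affine = np.column_stack([a_lin, a_off])
    return CalibrationModel(affine=affine, residual_rms_px=residual_rms_px,
                            n_points=len(pts))


def apply_calibration(stack: BlockfaceStack, model: CalibrationModel,
                      target_pixel_mm: float | None = None) -> BlockfaceStack:
    """Resample every slice through the calibration affine onto a common
    physical grid (linear interpolation); updates the stack's pixel size.

    The calibration affine fixes scale and shear but its absolute offset is
    arbitrary (it depends on which dot the lattice indexing called (0, 0)), so
    the corrected frame is anchored to the raw image centre: the output origin
    is chosen so the content at the raw centre keeps the physical position it
    had under the stack's nominal pixel size.
    """
    shape = stack.uniform_shape
    a = model.affine
    lin, off = a[:, :2], a[:, 2]
    if target_pixel_mm is None:
        target_pixel_mm = float(np.min(np.linalg.svd(lin, compute_uv=False)))
    # physical bounding box of the raw slice corners
    corners_px = np.array([[0, 0], [shape[0] - 1, 0],
                           [0, shape[1] - 1], [shape[0] - 1, shape[1] - 1]],
                          dtype=float)
    corners_mm = corners_px @ lin.T + off
    lo = corners_mm.min(axis=0)
    hi = corners_mm.max(axis=0)
    out_shape = tuple(int(np.floor((hi[d] - lo[d]) / target_pixel_mm)) + 1
                      for d in range(2))
    inv = np.linalg.inv(lin)
    matrix = inv * target_pixel_mm
    offset = inv @ (lo - off)
    out = stack.copy()
    out.slices = [ndimage.affine_transform(s, matrix, offset=offset,
                                           output_shape=out_shape, order=1,
                                           mode="nearest")
                  for s in stack.slices]
    out.pixel_size_mm = target_pixel_mm
    raw_center_mm = (np.asarray(stack.origin_mm)
                     + (np.array(shape, float) - 1) / 2.0 * stack.pixel_size_mm)
    origin = raw_center_mm - (np.array(out_shape, float) - 1) / 2.0 * target_pixel_mm
    out.origin_mm = (float(origin[0]), float(origin[1]))
    return out


def qc_exclude_and_fill(stack: BlockfaceStack, excluded_indices) -> BlockfaceStack:
    """Replace each excluded slice by a copy of the nearest preceding
    non-excluded slice, keeping the sequence length and flags."""
    excl = sorted(int(i) for i in set(excluded_indices))
    n = len(stack)
    for i in excl:
        if not 0 <= i < n:
            raise IndexError(f"excluded index {i} out of range [0, {n})")
    if 0 in excl:
        raise ValueError("slice 0 cannot be excluded: it has no predecessor")
    out = stack.copy()
    excluded_set = set(excl)
    for i in excl:
        j = i - 1
        while j in excluded_set:
            j -= 1
        out.slices[i] = out.slices[j].copy()
        out.excluded[i] = True
    return out


def _ncc_vertical(a: np.ndarray, b: np.ndarray, shift: int) -> float:
    """Pearson correlation between a shifted by `shift` (content moved +shift
    along the vertical axis) and b, over the overlap."""
    ny = a.shape[1]
    y0, y1 = max(0, shift), ny + min(0, shift)
    if y1 - y0 < 4:
        return -np.inf
    asub = a[:, y0 - shift:y1 - shift].ravel()
    bsub = b[:, y0:y1].ravel()
    asub = asub - asub.mean()
    bsub = bsub - bsub.mean()
    denom = np.linalg.norm(asub) * np.linalg.norm(bsub)
    if denom == 0:
        return 0.0
    return float(asub @ bsub / denom)


def align_vertical_translation(stack: BlockfaceStack, max_shift_mm: float
                               ) -> BlockfaceStack:
    """Sequential 1-D vertical alignment of consecutive slices.

    For each pair, the vertical shift maximizing the normalized
    cross-correlation is found over +-max_shift_mm with parabolic sub-pixel
    refinement; cumulative offsets are re-anchored to the middle slice (so
    drift does not accumulate) and applied along the vertical axis only.
    """
    n = len(stack)
    if n < 2:
        raise ValueError("alignment needs at least 2 slices")
    shape = stack.uniform_shape
    px = stack.pixel_size_mm
    s_max = int(np.ceil(max_shift_mm / px))
    if s_max >= shape[1]:
        raise ValueError("max_shift_mm exceeds the image height")
    rel = np.zeros(n)
    for k in range(1, n):
        a, b = stack.slices[k], stack.slices[k - 1]
        shifts = np.arange(-s_max, s_max + 1)
        scores = np.array([_ncc_vertical(a, b, int(s)) for s in shifts])
        i = int(np.argmax(scores))
        best = float(shifts[i])
        if 0 < i < len(shifts) - 1 and np.all(np.isfinite(scores[i - 1:i + 2])):
            y0, y1, y2 = scores[i - 1:i + 2]
            denom = y0 - 2 * y1 + y2
            if denom < 0:
                best += 0.5 * (y0 - y2) / denom
        rel[k] = best
    cum = np.cumsum(rel)
    cum -= cum[n // 2]
    out = stack.copy()
    for k in range(n):
        if cum[k] != 0.0:
            out.slices[k] = ndimage.shift(stack.slices[k], (0.0, cum[k]),
                                          order=1, mode="nearest")
    out.vertical_offsets_mm = [float(c * px) for c in cum]
    return out


def crop_and_resample(stack: BlockfaceStack, crop_box_mm, target_pixel_mm: float
                      ) -> BlockfaceStack:
    """Crop all slices identically (box in mm relative to the slice origin)
    and resample to an isotropic in-plane target resolution."""
    x0, y0, x1, y1 = (float(v) for v in crop_box_mm)
    px = stack.pixel_size_mm
    shape = stack.uniform_shape
    i0, j0 = int(round(x0 / px)), int(round(y0 / px))
    i1, j1 = int(round(x1 / px)), int(round(y1 / px))
    if i0 < 0 or j0 < 0 or i1 > shape[0] or j1 > shape[1] or i0 >= i1 or j0 >= j1:
        raise ValueError(f"crop box {crop_box_mm} outside slice extents {shape}")
    ratio = target_pixel_mm / px
    out_nx = int(np.floor((i1 - i0) * px / target_pixel_mm))
    out_ny = int(np.floor((j1 - j0) * px / target_pixel_mm))
    ci = i0 + np.arange(out_nx) * ratio
    cj = j0 + np.arange(out_ny) * ratio
    coords = np.meshgrid(ci, cj, indexing="ij")
    sigma = max(0.0, (ratio - 1.0) / 2.0)  # antialias when downsampling
    out = stack.copy()
    new_slices = []
    for s in stack.slices:
        src = ndimage.gaussian_filter(s, sigma) if sigma > 0 else s
        new_slices.append(ndimage.map_coordinates(src, coords, order=1,
                                                  mode="nearest"))
    out.slices = new_slices
    out.pixel_size_mm = float(target_pixel_mm)
    out.origin_mm = (stack.origin_mm[0] + x0, stack.origin_mm[1] + y0)
    return out


def remove_lines_moving_average(image: np.ndarray, window_cols: int = 15
                                ) -> np.ndarray:
    """Technique A: sliding multiplicative column normalization.

    Each column is rescaled by (mean of the flanking columns' means inside the
    window, excluding the column itself) / (its own mean).  Edge columns use
    whatever flank is available.
    """
    img = np.asarray(image, float)
    nx = img.shape[0]
    if window_cols < 3 or window_cols % 2 == 0:
        raise ValueError("window_cols must be an odd integer >= 3")
    if window_cols >= nx:
        raise ValueError("window_cols must be smaller than the image width")
    col_means = img.mean(axis=1)
    floor = 1e-6 * float(np.max(np.abs(img))) if img.size else 1e-6
    if np.any(col_means <= floor):
        warnings.warn("near-zero column means floored during line removal")
    half = window_cols // 2
    flank = np.empty(nx)
    csum = np.concatenate([[0.0], np.cumsum(col_means)])
    for c in range(nx):
        a, b = max(0, c - half), min(nx, c + half + 1)
        total = csum[b] - csum[a]
        count = b - a - 1
        flank[c] = (total - col_means[c]) / max(count, 1)
    scale = flank / np.maximum(col_means, floor)
    return img * scale[:, None]


def remove_lines_fourier(image: np.ndarray, band_halfwidth_bins: int = 1,
                         center_exclusion_bins: int = 3) -> np.ndarray:
    """Technique B: notch out the zero-vertical-frequency line in the 2-D
    spectrum (where vertical line artifacts live), preserving the region
    around the DC origin so the global mean is untouched."""
    img = np.asarray(image, float)
    if band_halfwidth_bins < 0:
        raise ValueError("band_halfwidth_bins must be >= 0")
    if center_exclusion_bins < 1:
        raise ValueError("center_exclusion_bins must be >= 1")
    nx, ny = img.shape
    f = np.fft.fft2(img)
    kx = np.minimum(np.arange(nx), nx - np.arange(nx))
    ky = np.minimum(np.arange(ny), ny - np.arange(ny))
    mask = (ky[None, :] <= band_halfwidth_bins) & \
           (kx[:, None] >= center_exclusion_bins)
    f[mask] = 0.0
    return np.real(np.fft.ifft2(f))


def median_filter_stack(stack: BlockfaceStack, kernel=(3, 3, 3)) -> BlockfaceStack:
    """3-D median filter over the assembled grid with reflected boundaries."""
    kernel = tuple(int(k) for k in kernel)
    if any(k < 1 or k % 2 == 0 for k in kernel):
        raise ValueError("kernel dimensions must be odd positive integers")
    shape = stack.uniform_shape
    grid_shape = (shape[0], shape[1], len(stack))
    if any(k > s for k, s in zip(kernel, grid_shape)):
        raise ValueError("kernel exceeds stack dimensions")
    grid = np.stack(stack.slices, axis=2)
    if kernel != (1, 1, 1):
        grid = ndimage.median_filter(grid, size=kernel, mode="mirror")
    out = stack.copy()
    out.slices = [grid[:, :, k] for k in range(len(stack))]
    return out


def assemble_volume(stack: BlockfaceStack) -> ImageVolume:
    """Stack the slices along z; spacing = (pixel, pixel, section spacing)."""
    shape = stack.uniform_shape  # raises on ragged slices
    del shape
    grid = np.stack(stack.slices, axis=2)
    return ImageVolume(grid,
                       (stack.pixel_size_mm, stack.pixel_size_mm,
                        stack.section_spacing_mm),
                       (stack.origin_mm[0], stack.origin_mm[1], 0.0))


def reconstruct(stack: BlockfaceStack,
                calibration: CalibrationModel | None = None,
                excluded_indices=(),
                max_shift_mm: float = 0.5,
                crop_box_mm=None,
                target_pixel_mm: float | None = None,
                technique: str = "A",
                window_cols: int = 15,
                band_halfwidth_bins: int = 1,
                center_exclusion_bins: int = 3,
                median_kernel=(3, 3, 3),
                log: list | None = None) -> tuple[ImageVolume, BlockfaceStack]:
    """Full reconstruction: calibrate, QC-fill, align, crop, destripe, median
    filter, assemble.  Technique "A" destripes then median-filters; technique
    "B" median-filters then applies the Fourier notch (their published order
    differs and is kept).  Returns the assembled volume and the processed
    stack (which carries the per-slice vertical offsets)."""
    def note(msg: str) -> None:
        if log is not None:
            log.append(msg)

    s = stack
    if calibration is not None:
        s = apply_calibration(s, calibration, target_pixel_mm=None)
        note(f"calibrated: pixel size {s.pixel_size_mm:.5f} mm")
    if excluded_indices:
        s = qc_exclude_and_fill(s, excluded_indices)
        note(f"qc: duplicated {len(set(excluded_indices))} excluded slices")
    if len(s) >= 2 and max_shift_mm > 0:
        s = align_vertical_translation(s, max_shift_mm)
        note("aligned 1-D vertical translation")
    if crop_box_mm is not None or target_pixel_mm is not None:
        shape = s.uniform_shape
        if crop_box_mm is None:
            crop_box_mm = (0.0, 0.0, shape[0] * s.pixel_size_mm,
                           shape[1] * s.pixel_size_mm)
        if target_pixel_mm is None:
            target_pixel_mm = s.pixel_size_mm
        s = crop_and_resample(s, crop_box_mm, target_pixel_mm)
        note(f"cropped/resampled to {s.uniform_shape} at "
             f"{s.pixel_size_mm:.5f} mm")
    if technique == "A":
        s = s.copy()
        s.slices = [remove_lines_moving_average(sl, window_cols)
                    for sl in s.slices]
        s = median_filter_stack(s, median_kernel)
        note("technique A: column normalization then median filter")
    elif technique == "B":
        s = median_filter_stack(s, median_kernel)
        s = s.copy()
        s.slices = [remove_lines_fourier(sl, band_halfwidth_bins,
                                         center_exclusion_bins)
                    for sl in s.slices]
        note("technique B: median filter then Fourier notch")
    elif technique not in (None, "none"):
        raise ValueError(f"unknown destriping technique {technique!r}")
    vol = assemble_volume(s)
    note(f"assembled volume {vol.shape}")
    return vol, s
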