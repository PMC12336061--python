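"""Registration accuracy metrics: Dice overlap and vessel-curve distances.

Dice = 2|A n B| / (|A| + |B|) is computed per anatomical label after
transporting the moving segmentation with nearest-neighbour interpolation,
plus a "whole tissue" score on the union of all foreground labels.  Vessel
alignment is assessed in 3-D by skeletonizing each vessel mask to a
centerline, fitting a smooth parametric curve, resampling it uniformly in
arc length, and averaging the pointwise Euclidean distances between the two
resampled curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import interpolate, ndimage
from skimage.morphology import skeletonize

from .core import Image2D, ImageVolume, LabelMap, BlockfaceStack
from .transforms import TransformChain, apply_transform

__all__ = [
    "OverlapReport",
    "dice",
    "evaluate_registration",
    "reconstruct_histology_volume",
    "skeletonize_vessel",
    "resample_curve",
    "mean_curve_distance",
]

#: Returned when both label sets are empty: the score is undefined there and
#: a silent 0 or 1 would corrupt averages.
UNDEFINED_DICE = float("nan")

WHOLE_TISSUE = "whole_tissue"


@dataclass
class OverlapReport:
    """Per-label and whole-tissue Dice scores with voxel counts."""

    per_label_dice: dict[int, float]
    whole_tissue_dice: float
    label_names: dict[int, str] = field(default_factory=dict)
    n_voxels_a: dict[int, int] = field(default_factory=dict)
    n_voxels_b: dict[int, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for lab, d in sorted(self.per_label_dice.items()):
            rows.append({
                "label": lab,
                "name": self.label_names.get(lab, str(lab)),
                "dice": d,
                "n_voxels_fixed": self.n_voxels_a.get(lab, 0),
                "n_voxels_moving": self.n_voxels_b.get(lab, 0),
            })
        rows.append({"label": -1, "name": WHOLE_TISSUE,
                     "dice": self.whole_tissue_dice,
                     "n_voxels_fixed": sum(self.n_voxels_a.values()),
                     "n_voxels_moving": sum(self.n_voxels_b.values())})
        return pd.DataFrame(rows)


def _label_sets(a: LabelMap, b: LabelMap, label) -> tuple[np.ndarray, np.ndarray]:
    if a.labels.shape != b.labels.shape:
        raise ValueError(f"label grids differ: {a.labels.shape} vs {b.labels.shape}")
    if label == WHOLE_TISSUE:
        return a.labels > 0, b.labels > 0
    return a.labels == label, b.labels == label


def dice(a: LabelMap, b: LabelMap, label=WHOLE_TISSUE) -> float:
    """Dice similarity of one label (or of all foreground, "whole_tissue").

    Returns NaN (with a warning) when the label is present in neither map.
    """
    ma, mb = _label_sets(a, b, label)
    sa, sb = int(ma.sum()), int(mb.sum())
    if sa + sb == 0:
        warnings.warn(f"Dice undefined for label {label!r}: both sets empty")
        return UNDEFINED_DICE
    inter = int(np.logical_and(ma, mb).sum())
    return 2.0 * inter / (sa + sb)


def evaluate_registration(fixed_labels: LabelMap, moving_labels: LabelMap,
                          chain: TransformChain | None = None) -> OverlapReport:
    """Transport the moving labels (nearest neighbour) and score the overlap.

    ``chain=None`` compares the maps on a common grid without resampling.
    Labels present on only one side are scored (Dice 0) and kept in the
    report with their voxel counts rather than dropped.
    """
    moved = moving_labels if chain is None else \
        apply_transform(moving_labels, chain, interpolation="nearest")
    labels = sorted(set(fixed_labels.present_labels())
                    | set(moved.present_labels()))
    per_label = {}
    na, nb = {}, {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for lab in labels:
            per_label[lab] = dice(fixed_labels, moved, lab)
            na[lab] = int((fixed_labels.labels == lab).sum())
            nb[lab] = int((moved.labels == lab).sum())
    whole = dice(fixed_labels, moved, WHOLE_TISSUE)
    names = dict(fixed_labels.label_names)
    names.update(moving_labels.label_names)
    return OverlapReport(per_label_dice=per_label, whole_tissue_dice=whole,
                         label_names=names, n_voxels_a=na, n_voxels_b=nb)


def reconstruct_histology_volume(sections: list[Image2D],
                                 stack: BlockfaceStack,
                                 fill: str = "linear") -> ImageVolume:
    """Stack registered sections into a volume on the blockface grid.

    Each section sits at z = index * section spacing; z-planes between
    sampled sections are filled by linear interpolation along z ("linear")
    or by copying the nearest sampled section ("nearest").
    """
    if fill not in ("linear", "nearest"):
        raise ValueError("fill must be 'linear' or 'nearest'")
    if not sections:
        raise ValueError("no sections given")
    idx = [s.section_index for s in sections]
    if any(i is None for i in idx):
        raise ValueError("every section needs a section_index")
    if len(set(idx)) != len(idx):
        raise ValueError("duplicate section indices")
    order = np.argsort(idx)
    sections = [sections[i] for i in order]
    idx = sorted(idx)
    shape2d = sections[0].shape
    if any(s.shape != shape2d for s in sections):
        raise ValueError("sections must share dimensions")

    nz = len(stack)
    vol = np.zeros((*shape2d, nz))
    idx_arr = np.array(idx, dtype=float)
    data = np.stack([s.pixels for s in sections], axis=2)
    for k in range(nz):
        if fill == "nearest" or len(idx) == 1:
            j = int(np.argmin(np.abs(idx_arr - k)))
            vol[:, :, k] = data[:, :, j]
        else:
            j = int(np.clip(np.searchsorted(idx_arr, k), 1, len(idx) - 1))
            k0, k1 = idx_arr[j - 1], idx_arr[j]
            if k <= k0:
                vol[:, :, k] = data[:, :, j - 1]
            elif k >= k1:
                vol[:, :, k] = data[:, :, j]
            else:
                t = (k - k0) / (k1 - k0)
                vol[:, :, k] = (1 - t) * data[:, :, j - 1] + t * data[:, :, j]
    px = sections[0].pixel_size_mm
    return ImageVolume(vol, (px, px, stack.section_spacing_mm),
                       (sections[0].origin_mm[0], sections[0].origin_mm[1], 0.0))


def _skeleton_longest_path(coords: np.ndarray) -> np.ndarray:
    """Order skeleton voxels along the longest geodesic path (tree diameter:
    two breadth-first passes on the 26-connected voxel graph)."""
    n = len(coords)
    index = {tuple(c): i for i, c in enumerate(coords)}
    neighbours: list[list[int]] = [[] for _ in range(n)]
    offsets = [np.array(o) for o in np.ndindex(3, 3, 3)
               if tuple(o) != (1, 1, 1)]
    for i, c in enumerate(coords):
        for o in offsets:
            j = index.get(tuple(c + o - 1))
            if j is not None:
                neighbours[i].append(j)

    def bfs(start: int) -> tuple[np.ndarray, np.ndarray]:
        dist = np.full(n, -1)
        parent = np.full(n, -1)
        dist[start] = 0
        queue = [start]
        while queue:
            nxt = []
            for u in queue:
                for v in neighbours[u]:
                    if dist[v] < 0:
                        dist[v] = dist[u] + 1
                        parent[v] = u
                        nxt.append(v)
            queue = nxt
        return dist, parent

    d0, _ = bfs(0)
    if np.any(d0 < 0):
        raise ValueError("skeleton voxel graph is disconnected")
    a = int(np.argmax(d0))
    d1, parent = bfs(a)
    b = int(np.argmax(d1))
    path = [b]
    while parent[path[-1]] >= 0:
        path.append(int(parent[path[-1]]))
    return coords[np.array(path[::-1])]


def skeletonize_vessel(mask: LabelMap) -> np.ndarray:
    """Centerline of a tubular mask as an ordered point sequence (mm).

    Topological 3-D thinning reduces the mask to a voxel skeleton; the
    longest geodesic path through its 26-connected graph is extracted and
    returned end-to-end in world coordinates.
    """
    m = mask.labels > 0
    if not m.any():
        raise ValueError("empty vessel mask")
    _, n_comp = ndimage.label(m, structure=np.ones((3,) * m.ndim))
    if n_comp != 1:
        raise ValueError(f"vessel mask has {n_comp} connected components; "
                         "expected a single tubular component")
    skel = skeletonize(m)
    coords = np.column_stack(np.nonzero(skel))
    if len(coords) == 0:  # thinning can erase a tiny blob; fall back to mask
        coords = np.column_stack(np.nonzero(m))
    ordered = _skeleton_longest_path(coords)
    return ordered * mask.spacing + mask.origin


def resample_curve(points: np.ndarray, n: int, smoothing: float = 0.0
                   ) -> np.ndarray:
    """Fit a smooth parametric spline and resample at uniform arc length.

    ``smoothing`` is the spline smoothing-penalty weight (0 interpolates the
    input points exactly).  The output has exactly ``n`` points with equal
    consecutive arc-length gaps.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need at least 2 points")
    if n < 2:
        raise ValueError("n must be >= 2")
    if np.allclose(pts, pts[0]):
        raise ValueError("degenerate curve: all points identical")
    # drop consecutive duplicates, which break the parameterization
    keep = np.r_[True, np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-12]
    pts = pts[keep]
    k = min(3, len(pts) - 1)
    tck, _ = interpolate.splprep(pts.T, s=smoothing, k=k)
    # dense evaluation -> arc length table -> uniform stations
    u_dense = np.linspace(0.0, 1.0, max(20 * n, 400))
    dense = np.array(interpolate.splev(u_dense, tck)).T
    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arc = np.r_[0.0, np.cumsum(seg)]
    stations = np.linspace(0.0, arc[-1], n)
    u_uniform = np.interp(stations, arc, u_dense)
    return np.array(interpolate.splev(u_uniform, tck)).T


def mean_curve_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Mean pointwise Euclidean distance between two resampled curves (mm).

    Curves are compared index-wise after orientation matching: ``b`` is
    flipped when that reduces the summed endpoint distances.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError(f"curves differ in shape: {a.shape} vs {b.shape}")
    straight = (np.linalg.norm(a[0] - b[0]) + np.linalg.norm(a[-1] - b[-1]))
    flipped = (np.linalg.norm(a[0] - b[-1]) + np.linalg.norm(a[-1] - b[0]))
    if flipped < straight:
        b = b[::-1]
    return float(np.mean(np.linalg.norm(a - b, axis=1)))
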