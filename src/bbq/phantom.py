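"""Synthetic specimen generator with complete ground truth.

Emulates the data a blockface sectioning experiment produces: a labelled
tissue slab embedded in paraffin, rendered (a) as an MRI volume, (b) as a
stack of blockface photographs carrying the acquisition artifacts the
reconstruction pipeline must undo (in-plane affine/aspect-ratio distortion,
per-slice vertical jitter from the microtome home position, multiplicative
vertical line artifacts from the blade, a top-bottom illumination gradient,
optional depth contamination, noise), (c) as a calibration-grid photograph,
and (d) as nonlinearly deformed histology sections with a distinct stain-like
contrast.

Labels: 0 background (oil/air), 1 paraffin, 2 white matter, 3 grey matter,
4 small-structure ribbon (a dentate-gyrus-like thin sheet), 5 vessel.

Every stochastic draw is recorded in :class:`PhantomGroundTruth`, so each
corruption can be checked and inverted in tests.  All operations are
deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .core import Image2D, ImageVolume, BlockfaceStack, LabelMap

__all__ = [
    "PhantomScene",
    "DistortionSpec",
    "HistologyDeformationSpec",
    "PhantomGroundTruth",
    "make_phantom",
    "render_mri",
    "render_blockface_stack",
    "render_calibration_grid",
    "render_histology_sections",
    "LABEL_NAMES",
    "MRI_INTENSITY",
    "BLOCKFACE_INTENSITY",
    "HISTOLOGY_INTENSITY",
]

LABEL_NAMES = {
    0: "background",
    1: "paraffin",
    2: "white_matter",
    3: "grey_matter",
    4: "ribbon",
    5: "vessel",
}

# Default rendering tables (arbitrary units).  The three modalities get
# deliberately different contrast orderings: blockface inverts the grey/white
# relation relative to MRI, which is the kind of modality gap the MIND-based
# registration has to bridge.
MRI_INTENSITY = {0: 10.0, 1: 25.0, 2: 85.0, 3: 55.0, 4: 95.0, 5: 30.0}
BLOCKFACE_INTENSITY = {0: 15.0, 1: 80.0, 2: 40.0, 3: 65.0, 4: 25.0, 5: 90.0}
HISTOLOGY_INTENSITY = {0: 95.0, 1: 90.0, 2: 60.0, 3: 35.0, 4: 15.0, 5: 70.0}


@dataclass
class PhantomScene:
    """A labelled synthetic specimen block."""

    labels: np.ndarray  # (nx, ny, nz) integer grid
    voxel_size_mm: float
    vessel_centerlines: list[np.ndarray]  # each (n_pts, 3), world mm
    vessel_radius_mm: float
    seed: int

    def label_map(self) -> LabelMap:
        return LabelMap(self.labels, (self.voxel_size_mm,) * 3,
                        label_names=LABEL_NAMES)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape


@dataclass
class DistortionSpec:
    """Everything the blockface camera and microtome do to a clean section.

    ``perspective_affine`` is a 2x3 in-plane matrix (pixel units, applied
    about the image centre) modelling the telecentric-lens aspect-ratio
    distortion; ``line_gain_amplitude`` is the SD of the log column gain;
    ``depth_weights`` mixes the next-deeper planes into the surface image
    (empty = pure surface imaging, the Brewster behaviour).
    """

    perspective_affine: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))
    vertical_jitter_sd_mm: float = 0.0
    line_gain_amplitude: float = 0.0
    line_gain_correlation_px: float = 1.0
    bias_gradient_amplitude: float = 0.0
    depth_weights: tuple[float, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.perspective_affine, float)
        if a.shape != (2, 3):
            raise ValueError("perspective_affine must be 2x3")
        if abs(np.linalg.det(a[:, :2])) < 1e-12:
            raise ValueError("perspective_affine linear part must be invertible")
        self.perspective_affine = a
        for name in ("vertical_jitter_sd_mm", "line_gain_amplitude",
                     "bias_gradient_amplitude", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.line_gain_correlation_px > 0:
            raise ValueError("line_gain_correlation_px must be positive")
        w = tuple(float(v) for v in self.depth_weights)
        if w and (min(w) < 0 or sum(w) >= 1):
            raise ValueError("depth_weights must be non-negative and sum to < 1")
        self.depth_weights = w

    @property
    def is_identity(self) -> bool:
        ident = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        return (np.allclose(self.perspective_affine, ident)
                and self.vertical_jitter_sd_mm == 0
                and self.line_gain_amplitude == 0
                and self.bias_gradient_amplitude == 0
                and not self.depth_weights
                and self.noise_sd == 0)


@dataclass
class HistologyDeformationSpec:
    """Smooth in-plane deformation + stain-like contrast for histology sections.

    ``contrast_map`` maps normalized intensity in [0, 1] to [0, 1]; the default
    inverted gamma remap mimics the qualitative contrast flip between an H&E
    section and MRI.  The generated displacement fields are rescaled if needed
    so their spatial gradient stays below 0.5, keeping the warp injective.
    """

    displacement_amplitude_mm: float = 0.0
    smoothness_mm: float = 1.0
    contrast_map: Callable[[np.ndarray], np.ndarray] | None = None
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.displacement_amplitude_mm < 0 or self.noise_sd < 0:
            raise ValueError("amplitudes must be >= 0")
        if not self.smoothness_mm > 0:
            raise ValueError("smoothness_mm must be positive")

    def remap(self, normalized: np.ndarray) -> np.ndarray:
        if self.contrast_map is not None:
            return self.contrast_map(normalized)
        return (1.0 - normalized) ** 1.5


@dataclass
class PhantomGroundTruth:
    """Record of every corruption applied during simulation."""

    seed: int | None = None
    perspective_affine: np.ndarray | None = None
    vertical_offsets_mm: np.ndarray | None = None  # per slice
    column_gains: np.ndarray | None = None  # (n_slices, nx)
    bias_gradient_amplitude: float = 0.0
    depth_weights: tuple[float, ...] = ()
    grid_dot_centers_px: np.ndarray | None = None  # distorted (N, 2)
    grid_dot_centers_ideal_px: np.ndarray | None = None
    histology_displacements_mm: dict[int, np.ndarray] = field(default_factory=dict)
    mri_bias_field: np.ndarray | None = None
    clean_planes: dict[int, np.ndarray] = field(default_factory=dict)


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return q <= 1.0


def _smooth_noise(rng: np.random.Generator, shape, sigma) -> np.ndarray:
    """Gaussian-correlated unit-SD noise field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def make_phantom(shape: Sequence[int], voxel_size_mm: float, n_vessels: int,
                 seed: int) -> PhantomScene:
    """Build a labelled specimen block.

    The paraffin block fills the grid up to a background margin; tissue is an
    ellipsoidal grey-matter slab with a white-matter core, a thin curved
    ribbon, and ``n_vessels`` tubular vessels running roughly along the
    sectioning (z) axis, each spanning at least 10 sections.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3 or any(s < 32 for s in shape):
        raise ValueError("phantom extents must be >= 32 voxels per axis")
    if n_vessels < 0:
        raise ValueError("n_vessels must be >= 0")
    nx, ny, nz = shape
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int32)

    # paraffin block with a background frame in-plane
    m = max(2, min(nx, ny) // 16)
    labels[m:nx - m, m:ny - m, :] = 1

    # tissue slab: grey-matter ellipsoid with white-matter core, kept inside
    # the paraffin with margin both in-plane and along z
    cz = (nz - 1) / 2.0
    center = ((nx - 1) / 2.0, (ny - 1) / 2.0, cz)
    ax_x = (nx / 2 - m) * 0.62
    ax_y = (ny / 2 - m) * 0.58
    ax_z = nz * 0.38
    gm = _ellipsoid_mask(shape, center, (ax_x, ax_y, ax_z))
    wm = _ellipsoid_mask(shape, center, (0.62 * ax_x, 0.58 * ax_y, 0.8 * ax_z))
    labels[gm] = 3
    labels[wm] = 2

    # ribbon: thin shell band between white and grey matter, limited to a
    # wedge of in-plane angles -> a curved sheet a couple of voxels thick
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    q = sum(((g - c) / a) ** 2
            for g, c, a in zip(grids, center, (0.8 * ax_x, 0.75 * ax_y, 0.9 * ax_z)))
    shell = (q > 0.92) & (q < 1.08)
    theta = np.arctan2(grids[1] - center[1], grids[0] - center[0])
    wedge = (theta > -0.9) & (theta < 0.9)
    ribbon = shell & wedge & gm
    labels[ribbon] = 4

    # vessels: smooth random-walk centerlines along z through the tissue
    radius_vox = 1.6
    centerlines: list[np.ndarray] = []
    z0 = int(np.ceil(cz - 0.8 * ax_z)) + 1
    z1 = int(np.floor(cz + 0.8 * ax_z)) - 1
    z_idx = np.arange(z0, z1 + 1)
    if n_vessels > 0 and len(z_idx) < 10:
        raise ValueError("phantom too small along z for vessels spanning 10 sections")
    xg, yg = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float),
                         indexing="ij")
    for _ in range(n_vessels):
        # lateral path: start inside the white-matter core, drift smoothly
        start = center[:2] + rng.uniform(-0.3, 0.3, 2) * (ax_x, ax_y)
        steps = rng.standard_normal((len(z_idx), 2)) * 0.6
        steps = ndimage.gaussian_filter1d(steps, sigma=4.0, axis=0)
        path = start[None, :] + np.cumsum(steps, axis=0)
        # keep the path well inside the grey matter ellipsoid
        rel = (path - np.asarray(center[:2])) / np.array([0.7 * ax_x, 0.7 * ax_y])
        norm = np.linalg.norm(rel, axis=1)
        scale = np.where(norm > 1, 1.0 / norm, 1.0)
        path = np.asarray(center[:2]) + rel * scale[:, None] * np.array(
            [0.7 * ax_x, 0.7 * ax_y])
        for (px, py), z in zip(path, z_idx):
            disk = (xg - px) ** 2 + (yg - py) ** 2 <= radius_vox ** 2
            plane = labels[:, :, z]
            plane[disk & (plane >= 2)] = 5
        pts = np.column_stack([path, z_idx.astype(float)]) * voxel_size_mm
        centerlines.append(pts)

    return PhantomScene(labels=labels, voxel_size_mm=float(voxel_size_mm),
                        vessel_centerlines=centerlines,
                        vessel_radius_mm=radius_vox * voxel_size_mm, seed=seed)


def _render_labels(labels: np.ndarray, intensity_table: Mapping[int, float]
                   ) -> np.ndarray:
    present = np.unique(labels)
    missing = [int(v) for v in present if int(v) not in intensity_table]
    if missing:
        raise KeyError(f"intensity table missing labels {missing}")
    lut = np.zeros(int(present.max()) + 1)
    for k, v in intensity_table.items():
        if k <= present.max():
            lut[k] = v
    return lut[labels]


def render_mri(scene: PhantomScene, intensity_table: Mapping[int, float],
               noise_sd: float, seed: int, bias_amplitude: float = 0.0
               ) -> tuple[ImageVolume, PhantomGroundTruth]:
    """Render the scene with MRI-like contrast.

    Intensity = table mean x smooth multiplicative bias (bounded by
    ``bias_amplitude``) + Gaussian noise.  With zero noise and zero bias the
    per-label intensity equals the table mean exactly.
    """
    rng = np.random.default_rng(seed)
    base = _render_labels(scene.labels, intensity_table)
    gt = PhantomGroundTruth(seed=seed)
    if bias_amplitude > 0:
        f = _smooth_noise(rng, scene.shape, sigma=min(scene.shape) / 4)
        f = f / np.max(np.abs(f))
        bias = 1.0 + bias_amplitude * f
        gt.mri_bias_field = bias
        base = base * bias
    if noise_sd > 0:
        base = base + rng.normal(0.0, noise_sd, scene.shape)
    vol = ImageVolume(base, (scene.voxel_size_mm,) * 3)
    return vol, gt


def _apply_affine_about_center(img: np.ndarray, affine_2x3: np.ndarray,
                               order: int = 1) -> np.ndarray:
    """Resample so that ideal point q maps to observed point A q (about centre)."""
    a = np.asarray(affine_2x3, float)
    lin, off = a[:, :2], a[:, 2]
    center = (np.array(img.shape, float) - 1) / 2.0
    inv = np.linalg.inv(lin)
    # observed(p) = ideal(A^-1 (p - c - off) + c)
    return ndimage.affine_transform(img, inv, offset=center - inv @ (center + off),
                                    order=order, mode="constant",
                                    cval=float(img.min()))


def _column_gain(rng: np.random.Generator, n_cols: int, amplitude: float,
                 correlation_px: float) -> np.ndarray:
    """exp of a Gaussian-smoothed white-noise signal; ``amplitude`` is the SD
    of the log gain, so gains are positive and multiplicative."""
    g = ndimage.gaussian_filter1d(rng.standard_normal(n_cols), correlation_px)
    sd = g.std()
    if sd > 0:
        g = g / sd
    return np.exp(amplitude * g)


def render_blockface_stack(scene: PhantomScene, spec: DistortionSpec,
                           intensity_table: Mapping[int, float] | None = None,
                           ) -> tuple[BlockfaceStack, PhantomGroundTruth]:
    """Render each z-plane of the scene as a distorted blockface photograph.

    Slice k is the plane-k rendering, optionally mixed with deeper planes
    (depth contamination), composed with the perspective affine, shifted
    vertically by Gaussian jitter, multiplied by a smooth random column gain
    field and a top-bottom linear intensity gradient, plus noise.  All draws
    are recorded in the returned ground truth.
    """
    if intensity_table is None:
        intensity_table = BLOCKFACE_INTENSITY
    rng = np.random.default_rng(spec.seed)
    nx, ny, nz = scene.shape
    rendered = _render_labels(scene.labels, intensity_table)

    jitters = (rng.normal(0.0, spec.vertical_jitter_sd_mm, nz)
               if spec.vertical_jitter_sd_mm > 0 else np.zeros(nz))
    gains = np.ones((nz, nx))
    if spec.line_gain_amplitude > 0:
        for k in range(nz):
            gains[k] = _column_gain(rng, nx, spec.line_gain_amplitude,
                                    spec.line_gain_correlation_px)
    noise_seed = rng.integers(0, 2 ** 31)
    noise_rng = np.random.default_rng(noise_seed)

    px = scene.voxel_size_mm
    k_depth = len(spec.depth_weights)
    grad = np.linspace(-1.0, 1.0, ny)[None, :]  # along the vertical axis
    ident_affine = np.allclose(spec.perspective_affine,
                               np.array([[1.0, 0, 0], [0, 1.0, 0]]))
    slices = []
    gt = PhantomGroundTruth(seed=spec.seed,
                            perspective_affine=spec.perspective_affine.copy(),
                            vertical_offsets_mm=jitters.copy(),
                            column_gains=gains.copy(),
                            bias_gradient_amplitude=spec.bias_gradient_amplitude,
                            depth_weights=spec.depth_weights)
    for k in range(nz):
        plane = rendered[:, :, k]
        if k_depth:
            w_sum = sum(spec.depth_weights)
            plane = (1.0 - w_sum) * plane
            for j, w in enumerate(spec.depth_weights, start=1):
                plane = plane + w * rendered[:, :, min(k + j, nz - 1)]
        gt.clean_planes[k] = plane.copy()
        img = plane
        if not ident_affine:
            img = _apply_affine_about_center(img, spec.perspective_affine)
        if jitters[k] != 0.0:
            img = ndimage.shift(img, (0.0, jitters[k] / px), order=1,
                                mode="nearest")
        img = img * gains[k][:, None]
        if spec.bias_gradient_amplitude > 0:
            img = img * (1.0 + spec.bias_gradient_amplitude * grad)
        if spec.noise_sd > 0:
            img = img + noise_rng.normal(0.0, spec.noise_sd, img.shape)
        slices.append(img)

    stack = BlockfaceStack(slices=slices, section_indices=list(range(nz)),
                           pixel_size_mm=px, section_spacing_mm=px)
    return stack, gt


def render_calibration_grid(spec: DistortionSpec, dot_spacing_mm: float,
                            grid_extent: tuple[int, int],
                            pixel_size_mm: float = 0.25,
                            margin_px: int = 20,
                            dot_sigma_px: float = 2.0,
                            ) -> tuple[Image2D, PhantomGroundTruth]:
    """Render a photographed calibration grid: dark dots of known spacing on a
    light background, distorted by the spec's perspective affine.

    Dots are Gaussian blobs so their intensity-weighted centroids are
    sub-pixel accurate.  Both ideal and distorted dot centres are recorded.
    """
    if dot_spacing_mm <= 0:
        raise ValueError("dot_spacing_mm must be positive")
    gx, gy = (int(g) for g in grid_extent)
    if gx < 3 or gy < 3:
        raise ValueError("grid_extent must be at least 3 dots per axis")
    step = dot_spacing_mm / pixel_size_mm
    w = int(np.ceil((gx - 1) * step)) + 2 * margin_px + 1
    h = int(np.ceil((gy - 1) * step)) + 2 * margin_px + 1

    # ideal lattice centred in the image
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    ix = cx + (np.arange(gx) - (gx - 1) / 2.0) * step
    iy = cy + (np.arange(gy) - (gy - 1) / 2.0) * step
    ideal = np.array([[x, y] for x in ix for y in iy])  # row-major by lattice

    a = spec.perspective_affine
    lin, off = a[:, :2], a[:, 2]
    center = np.array([cx, cy])
    distorted = (ideal - center) @ lin.T + center + off
    if (distorted.min() < 2 or distorted[:, 0].max() > w - 3
            or distorted[:, 1].max() > h - 3):
        raise ValueError("distorted lattice exceeds image extents")

    img = np.ones((w, h))
    xg, yg = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float),
                         indexing="ij")
    for px_c, py_c in distorted:
        x0, x1 = int(px_c - 5 * dot_sigma_px), int(px_c + 5 * dot_sigma_px) + 1
        y0, y1 = int(py_c - 5 * dot_sigma_px), int(py_c + 5 * dot_sigma_px) + 1
        x0, y0 = max(x0, 0), max(y0, 0)
        sub_x, sub_y = xg[x0:x1, y0:y1], yg[x0:x1, y0:y1]
        blob = np.exp(-(((sub_x - px_c) ** 2 + (sub_y - py_c) ** 2)
                        / (2 * dot_sigma_px ** 2)))
        img[x0:x1, y0:y1] = np.minimum(img[x0:x1, y0:y1], 1.0 - blob)

    gt = PhantomGroundTruth(seed=spec.seed,
                            perspective_affine=a.copy(),
                            grid_dot_centers_px=distorted,
                            grid_dot_centers_ideal_px=ideal)
    return Image2D(img, pixel_size_mm=pixel_size_mm, source="calibration"), gt


def _smooth_displacement(rng: np.random.Generator, shape, amplitude_mm: float,
                         smoothness_mm: float, pixel_mm: float) -> np.ndarray:
    """Smooth random 2-D displacement field (2, nx, ny) in mm, max magnitude
    equal to ``amplitude_mm``, gradient-capped for injectivity."""
    sigma = smoothness_mm / pixel_mm
    field = np.stack([_smooth_noise(rng, shape, sigma) for _ in range(2)])
    mag = np.linalg.norm(field, axis=0)
    peak = mag.max()
    if peak > 0 and amplitude_mm > 0:
        field = field * (amplitude_mm / peak)
    else:
        field = np.zeros_like(field)
    # cap the spatial gradient so x -> x + u(x) stays injective
    if amplitude_mm > 0:
        grads = []
        for c in range(2):
            g = np.gradient(field[c], pixel_mm)
            grads.append(np.sqrt(g[0] ** 2 + g[1] ** 2))
        gmax = max(g.max() for g in grads)
        if gmax > 0.5:
            field = field * (0.5 / gmax)
    return field


def _warp_2d(img: np.ndarray, disp_mm: np.ndarray, pixel_mm: float,
             inverse: bool = False, order: int = 1) -> np.ndarray:
    """Pull-warp: out(p) = img(p + u(p)); with ``inverse`` the field's numeric
    inverse is applied instead."""
    nx, ny = img.shape
    xg, yg = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float),
                         indexing="ij")
    u = disp_mm / pixel_mm
    if inverse:
        # fixed point for v with v(p) = -u(p + v(p))
        vx = np.zeros_like(xg)
        vy = np.zeros_like(yg)
        for _ in range(60):
            sx = ndimage.map_coordinates(u[0], [xg + vx, yg + vy], order=1,
                                         mode="nearest")
            sy = ndimage.map_coordinates(u[1], [xg + vx, yg + vy], order=1,
                                         mode="nearest")
            nvx, nvy = -sx, -sy
            delta = max(np.max(np.abs(nvx - vx)), np.max(np.abs(nvy - vy)))
            vx, vy = nvx, nvy
            if delta < 1e-3:
                break
        coords = [xg + vx, yg + vy]
    else:
        coords = [xg + u[0], yg + u[1]]
    return ndimage.map_coordinates(img, coords, order=order, mode="nearest")


def render_histology_sections(scene: PhantomScene, indices: Sequence[int],
                              spec: HistologyDeformationSpec,
                              intensity_table: Mapping[int, float] | None = None,
                              ) -> tuple[list[Image2D], PhantomGroundTruth]:
    """Render sections with stain-like contrast and smooth 2-D deformations.

    Each section is the plane rendering passed through the spec's monotone
    contrast remap, pull-warped by a smooth random displacement field of the
    stated amplitude (recorded per section), plus noise.
    """
    if intensity_table is None:
        intensity_table = HISTOLOGY_INTENSITY
    nz = scene.shape[2]
    for k in indices:
        if not 0 <= k < nz:
            raise IndexError(f"section index {k} out of range [0, {nz})")
    rng = np.random.default_rng(spec.seed)
    rendered = _render_labels(scene.labels, intensity_table)
    lo, hi = rendered.min(), rendered.max()
    span = hi - lo if hi > lo else 1.0
    px = scene.voxel_size_mm
    gt = PhantomGroundTruth(seed=spec.seed)
    sections: list[Image2D] = []
    for k in indices:
        plane = spec.remap((rendered[:, :, k] - lo) / span) * 100.0
        gt.clean_planes[k] = plane.copy()
        disp = _smooth_displacement(rng, plane.shape,
                                    spec.displacement_amplitude_mm,
                                    spec.smoothness_mm, px)
        gt.histology_displacements_mm[k] = disp
        img = _warp_2d(plane, disp, px) if spec.displacement_amplitude_mm > 0 \
            else plane.copy()
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, img.shape)
        sections.append(Image2D(img, pixel_size_mm=px, section_index=int(k),
                                source="histology"))
    return sections, gt
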