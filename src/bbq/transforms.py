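"""Invertible spatial transform chains (rigid / isotropic scale / affine / nonlinear).

A :class:`TransformChain` maps moving-space world coordinates to fixed-space
world coordinates (its ``fwd`` direction).  Images are resampled by *pulling*
through the inverse direction: for every fixed-space voxel centre ``x`` the
chain yields the moving-space position ``pull(x)`` to sample.  Registration
optimizes the pull maps directly.

Stage order follows the optimization order (rigid, isotropic scale, affine,
nonlinear); in the pull composition the nonlinear displacement acts first,
directly on fixed-space coordinates:

    pull(x) = rigid.pull( scale.pull( affine.pull( x + u(x) ) ) )

The nonlinear stage stores displacement vectors on a coarse control lattice,
interpolated with cubic B-splines.  Control displacements are bounded below
0.4x the control spacing, which is sufficient for the map to stay injective
(hence invertible).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import Image2D, ImageVolume, LabelMap

__all__ = [
    "RigidStage",
    "ScaleStage",
    "AffineStage",
    "LinearStage",
    "NonlinearStage",
    "DisplacementFieldStage",
    "TransformChain",
    "invert_chain",
    "apply_transform",
    "random_bspline_warp",
]

#: Fraction of the control spacing that bounds each control displacement;
#: below this bound a cubic-B-spline displacement field is injective.
INVERTIBILITY_BOUND = 0.4


def rotation_matrix(angles: Sequence[float], ndim: int) -> np.ndarray:
    """Rotation matrix from Euler angles (radians).

    2-D: one angle.  3-D: (rx, ry, rz), composed as Rx @ Ry @ Rz.
    """
    if ndim == 2:
        (a,) = angles
        c, s = np.cos(a), np.sin(a)
        return np.array([[c, -s], [s, c]])
    ax, ay, az = angles
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rx @ ry @ rz


class _LinearBase:
    """Common machinery for stages whose pull map is x -> M (x - c) + c + t."""

    def _matrix_offset(self) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def pull_points(self, pts: np.ndarray) -> np.ndarray:
        m, t = self._matrix_offset()
        c = np.asarray(self.center, float)
        return (pts - c) @ m.T + c + t

    def fwd_points(self, pts: np.ndarray) -> np.ndarray:
        m, t = self._matrix_offset()
        c = np.asarray(self.center, float)
        minv = np.linalg.inv(m)
        return (pts - c - t) @ minv.T + c


@dataclass
class RigidStage(_LinearBase):
    """Rotation about ``center`` plus translation."""

    ndim: int
    angles: np.ndarray  # radians; 1 angle (2-D) or 3 (3-D)
    translation: np.ndarray  # mm
    center: np.ndarray  # mm

    def __post_init__(self) -> None:
        self.angles = np.atleast_1d(np.asarray(self.angles, float))
        self.translation = np.asarray(self.translation, float)
        self.center = np.asarray(self.center, float)
        n_ang = 1 if self.ndim == 2 else 3
        if self.angles.size != n_ang or self.translation.size != self.ndim:
            raise ValueError("rigid parameter sizes do not match dimensionality")

    @classmethod
    def identity(cls, ndim: int, center) -> "RigidStage":
        n_ang = 1 if ndim == 2 else 3
        return cls(ndim, np.zeros(n_ang), np.zeros(ndim), np.asarray(center, float))

    def _matrix_offset(self):
        return rotation_matrix(self.angles, self.ndim), self.translation

    @property
    def n_params(self) -> int:
        return self.angles.size + self.ndim

    def get_params(self) -> np.ndarray:
        return np.concatenate([self.angles, self.translation])

    def set_params(self, p: np.ndarray) -> None:
        p = np.asarray(p, float)
        self.angles = p[: self.angles.size].copy()
        self.translation = p[self.angles.size :].copy()

    def to_dict(self) -> dict:
        return {
            "type": "rigid",
            "ndim": self.ndim,
            "angles_rad": self.angles.tolist(),
            "translation_mm": self.translation.tolist(),
            "center_mm": self.center.tolist(),
        }


@dataclass
class ScaleStage(_LinearBase):
    """Isotropic scaling about ``center`` (3-D chain only, by convention)."""

    ndim: int
    scale: float
    center: np.ndarray

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        self.center = np.asarray(self.center, float)

    @classmethod
    def identity(cls, ndim: int, center) -> "ScaleStage":
        return cls(ndim, 1.0, np.asarray(center, float))

    def _matrix_offset(self):
        return self.scale * np.eye(self.ndim), np.zeros(self.ndim)

    @property
    def n_params(self) -> int:
        return 1

    def get_params(self) -> np.ndarray:
        return np.array([np.log(self.scale)])

    def set_params(self, p: np.ndarray) -> None:
        self.scale = float(np.exp(p[0]))

    def to_dict(self) -> dict:
        return {
            "type": "scale",
            "ndim": self.ndim,
            "scale": self.scale,
            "center_mm": self.center.tolist(),
        }


@dataclass
class AffineStage(_LinearBase):
    """Full linear matrix plus translation about ``center``."""

    ndim: int
    matrix: np.ndarray
    translation: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float).reshape(self.ndim, self.ndim)
        self.translation = np.asarray(self.translation, float)
        self.center = np.asarray(self.center, float)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine matrix is singular")

    @classmethod
    def identity(cls, ndim: int, center) -> "AffineStage":
        return cls(ndim, np.eye(ndim), np.zeros(ndim), np.asarray(center, float))

    def _matrix_offset(self):
        return self.matrix, self.translation

    @property
    def n_params(self) -> int:
        return self.ndim * self.ndim + self.ndim

    def get_params(self) -> np.ndarray:
        return np.concatenate([(self.matrix - np.eye(self.ndim)).ravel(), self.translation])

    def set_params(self, p: np.ndarray) -> None:
        d = self.ndim
        self.matrix = np.eye(d) + np.asarray(p[: d * d], float).reshape(d, d)
        self.translation = np.asarray(p[d * d :], float).copy()

    def to_dict(self) -> dict:
        return {
            "type": "affine",
            "ndim": self.ndim,
            "matrix": self.matrix.tolist(),
            "translation_mm": self.translation.tolist(),
            "center_mm": self.center.tolist(),
        }


@dataclass
class LinearStage(_LinearBase):
    """Generic homogeneous linear stage, used for closed-form inverses."""

    ndim: int
    matrix: np.ndarray
    translation: np.ndarray
    center: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float).reshape(self.ndim, self.ndim)
        self.translation = np.asarray(self.translation, float)
        self.center = np.asarray(self.center, float)

    def _matrix_offset(self):
        return self.matrix, self.translation

    def to_dict(self) -> dict:
        return {
            "type": "linear",
            "ndim": self.ndim,
            "matrix": self.matrix.tolist(),
            "translation_mm": self.translation.tolist(),
            "center_mm": self.center.tolist(),
        }


# --------------------------------------------------------------------------
# cubic B-spline machinery for the nonlinear stage
# --------------------------------------------------------------------------

def _bspline3(t: np.ndarray) -> np.ndarray:
    """The cubic B-spline kernel, support (-2, 2), partition of unity."""
    t = np.abs(np.asarray(t, float))
    out = np.zeros_like(t)
    m1 = t < 1
    m2 = (t >= 1) & (t < 2)
    out[m1] = (4.0 - 6.0 * t[m1] ** 2 + 3.0 * t[m1] ** 3) / 6.0
    out[m2] = (2.0 - t[m2]) ** 3 / 6.0
    return out


def bspline_basis_matrix(coords_mm: np.ndarray, ctrl_origin: float, ctrl_spacing: float,
                         n_ctrl: int) -> np.ndarray:
    """Dense 1-D basis matrix B with B[i, k] = beta3((x_i - c_k) / spacing)."""
    x = (np.asarray(coords_mm, float)[:, None] - ctrl_origin) / ctrl_spacing
    k = np.arange(n_ctrl)[None, :]
    return _bspline3(x - k)


@dataclass
class NonlinearStage:
    """Free-form displacement on a cubic-B-spline control lattice.

    ``coeffs`` has shape ``(ndim, *n_ctrl)`` and holds displacement vectors in
    mm at the control points.  The pull map is ``x -> x + u(x)``.
    """

    ndim: int
    ctrl_origin: np.ndarray  # mm, per axis
    ctrl_spacing: np.ndarray  # mm, per axis
    coeffs: np.ndarray

    def __post_init__(self) -> None:
        self.ctrl_origin = np.asarray(self.ctrl_origin, float)
        self.ctrl_spacing = np.asarray(self.ctrl_spacing, float)
        self.coeffs = np.asarray(self.coeffs, float)
        if self.coeffs.shape[0] != self.ndim or self.coeffs.ndim != self.ndim + 1:
            raise ValueError("coeffs must have shape (ndim, *n_ctrl)")

    @classmethod
    def for_domain(cls, ndim: int, origin_mm, extent_mm, control_spacing_mm: float
                   ) -> "NonlinearStage":
        """Identity stage whose lattice covers [origin, origin+extent] with margin."""
        origin_mm = np.asarray(origin_mm, float)
        extent_mm = np.asarray(extent_mm, float)
        n_ctrl = np.maximum(4, np.ceil(extent_mm / control_spacing_mm).astype(int) + 4)
        ctrl_origin = origin_mm - 1.5 * control_spacing_mm
        coeffs = np.zeros((ndim, *n_ctrl))
        return cls(ndim, ctrl_origin, np.full(ndim, float(control_spacing_mm)), coeffs)

    @property
    def n_ctrl(self) -> tuple[int, ...]:
        return self.coeffs.shape[1:]

    @property
    def max_allowed_mm(self) -> float:
        return INVERTIBILITY_BOUND * float(self.ctrl_spacing.min())

    def basis_matrices(self, shape, spacing, origin) -> list[np.ndarray]:
        """Per-axis dense basis matrices mapping control coeffs to a voxel grid."""
        mats = []
        for ax in range(self.ndim):
            coords = origin[ax] + np.arange(shape[ax]) * spacing[ax]
            mats.append(bspline_basis_matrix(coords, self.ctrl_origin[ax],
                                             self.ctrl_spacing[ax], self.n_ctrl[ax]))
        return mats

    def displacement_on_grid(self, shape, spacing, origin,
                             coeffs: np.ndarray | None = None) -> np.ndarray:
        """Dense displacement field ``(ndim, *shape)`` via separable tensor products."""
        coeffs = self.coeffs if coeffs is None else coeffs
        mats = self.basis_matrices(shape, spacing, origin)
        return upsample_coeffs(coeffs, mats)

    def displacement_at_points(self, pts: np.ndarray) -> np.ndarray:
        """Evaluate u at arbitrary world points ``(N, ndim)``."""
        pts = np.asarray(pts, float)
        rel = (pts - self.ctrl_origin) / self.ctrl_spacing
        base = np.floor(rel).astype(int) - 1  # first of 4 support control points
        frac = rel - np.floor(rel)
        # per-axis weights for the 4 support points
        w = [np.stack([_bspline3(frac[:, ax] + 1 - j) for j in range(4)], axis=1)
             for ax in range(self.ndim)]
        out = np.zeros_like(pts)
        nc = self.n_ctrl
        if self.ndim == 2:
            for i in range(4):
                ki = np.clip(base[:, 0] + i, 0, nc[0] - 1)
                for j in range(4):
                    kj = np.clip(base[:, 1] + j, 0, nc[1] - 1)
                    wij = w[0][:, i] * w[1][:, j]
                    out += wij[:, None] * self.coeffs[:, ki, kj].T
        else:
            for i in range(4):
                ki = np.clip(base[:, 0] + i, 0, nc[0] - 1)
                for j in range(4):
                    kj = np.clip(base[:, 1] + j, 0, nc[1] - 1)
                    wij = w[0][:, i] * w[1][:, j]
                    for k in range(4):
                        kk = np.clip(base[:, 2] + k, 0, nc[2] - 1)
                        wijk = wij * w[2][:, k]
                        out += wijk[:, None] * self.coeffs[:, ki, kj, kk].T
        return out

    def pull_points(self, pts: np.ndarray) -> np.ndarray:
        return pts + self.displacement_at_points(pts)

    def fwd_points(self, pts: np.ndarray, tol_mm: float = 1e-3, max_iter: int = 100
                   ) -> np.ndarray:
        """Invert x -> x + u(x) by fixed-point iteration (contractive under the
        0.4x-spacing bound)."""
        pts = np.asarray(pts, float)
        x = pts.copy()
        for _ in range(max_iter):
            x_new = pts - self.displacement_at_points(x)
            delta = np.max(np.abs(x_new - x)) if x.size else 0.0
            x = x_new
            if delta < tol_mm:
                return x
        raise RuntimeError(
            f"displacement inversion did not converge (last residual {delta:.3g} mm)")

    def to_dict(self) -> dict:
        return {
            "type": "nonlinear",
            "ndim": self.ndim,
            "ctrl_origin_mm": self.ctrl_origin.tolist(),
            "ctrl_spacing_mm": self.ctrl_spacing.tolist(),
            "coeffs_mm": self.coeffs.tolist(),
        }


def upsample_coeffs(coeffs: np.ndarray, mats: list[np.ndarray]) -> np.ndarray:
    """Apply per-axis basis matrices to control coefficients ``(ndim, *n_ctrl)``."""
    out = coeffs
    ndim = coeffs.shape[0]
    for ax, b in enumerate(mats):
        out = np.moveaxis(np.tensordot(b, out, axes=(1, ax + 1)), 0, ax + 1)
    assert out.shape[0] == ndim
    return out


def project_to_coeffs(dense_grad: np.ndarray, mats: list[np.ndarray]) -> np.ndarray:
    """Adjoint of :func:`upsample_coeffs`: project a dense gradient onto coeffs."""
    out = dense_grad
    for ax, b in enumerate(mats):
        out = np.moveaxis(np.tensordot(b.T, out, axes=(1, ax + 1)), 0, ax + 1)
    return out


@dataclass
class DisplacementFieldStage:
    """Displacement sampled on a regular grid, linearly interpolated.

    Used to represent numeric inverses of nonlinear stages.  Pull map is
    ``x -> x + v(x)``; outside the grid the field is edge-extended.
    """

    ndim: int
    origin: np.ndarray
    spacing: np.ndarray
    field: np.ndarray  # (ndim, *shape), mm

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float)
        self.spacing = np.asarray(self.spacing, float)
        self.field = np.asarray(self.field, float)

    def displacement_at_points(self, pts: np.ndarray) -> np.ndarray:
        idx = ((np.asarray(pts, float) - self.origin) / self.spacing).T
        return np.stack([
            ndimage.map_coordinates(self.field[c], idx, order=1, mode="nearest")
            for c in range(self.ndim)
        ], axis=1)

    def pull_points(self, pts: np.ndarray) -> np.ndarray:
        return pts + self.displacement_at_points(pts)

    def fwd_points(self, pts: np.ndarray, tol_mm: float = 1e-3, max_iter: int = 100
                   ) -> np.ndarray:
        pts = np.asarray(pts, float)
        x = pts.copy()
        for _ in range(max_iter):
            x_new = pts - self.displacement_at_points(x)
            delta = np.max(np.abs(x_new - x)) if x.size else 0.0
            x = x_new
            if delta < tol_mm:
                return x
        raise RuntimeError(
            f"displacement inversion did not converge (last residual {delta:.3g} mm)")

    def to_dict(self) -> dict:
        return {
            "type": "displacement_field",
            "ndim": self.ndim,
            "origin_mm": self.origin.tolist(),
            "spacing_mm": self.spacing.tolist(),
            "field_mm": self.field.tolist(),
        }


@dataclass
class SpaceInfo:
    """Geometry of an image grid (shape, spacing, origin), all in mm."""

    shape: tuple[int, ...]
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.spacing = np.asarray(self.spacing, float)
        self.origin = np.asarray(self.origin, float)

    @classmethod
    def of(cls, image: ImageVolume | Image2D | LabelMap) -> "SpaceInfo":
        if isinstance(image, ImageVolume):
            return cls(image.shape, image.spacing, image.origin)
        if isinstance(image, Image2D):
            return cls(image.shape, image.spacing, image.origin)
        return cls(image.labels.shape, image.spacing, image.origin)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    def grid_points(self) -> np.ndarray:
        """World coordinates of all voxel centres, shape (N, ndim)."""
        axes = [self.origin[d] + np.arange(self.shape[d]) * self.spacing[d]
                for d in range(self.ndim)]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1)

    def center(self) -> np.ndarray:
        return self.origin + (np.array(self.shape) - 1) * self.spacing / 2.0

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "spacing_mm": self.spacing.tolist(),
            "origin_mm": self.origin.tolist(),
        }


_STAGE_TYPES = {
    "rigid": RigidStage,
    "scale": ScaleStage,
    "affine": AffineStage,
    "linear": LinearStage,
    "nonlinear": NonlinearStage,
    "displacement_field": DisplacementFieldStage,
}


def _stage_from_dict(d: dict):
    t = d["type"]
    if t == "rigid":
        return RigidStage(d["ndim"], np.array(d["angles_rad"]),
                          np.array(d["translation_mm"]), np.array(d["center_mm"]))
    if t == "scale":
        return ScaleStage(d["ndim"], d["scale"], np.array(d["center_mm"]))
    if t in ("affine", "linear"):
        cls = AffineStage if t == "affine" else LinearStage
        return cls(d["ndim"], np.array(d["matrix"]),
                   np.array(d["translation_mm"]), np.array(d["center_mm"]))
    if t == "nonlinear":
        return NonlinearStage(d["ndim"], np.array(d["ctrl_origin_mm"]),
                              np.array(d["ctrl_spacing_mm"]), np.array(d["coeffs_mm"]))
    if t == "displacement_field":
        return DisplacementFieldStage(d["ndim"], np.array(d["origin_mm"]),
                                      np.array(d["spacing_mm"]), np.array(d["field_mm"]))
    raise ValueError(f"unknown stage type {t!r}")


@dataclass
class TransformChain:
    """Ordered invertible stages mapping moving space to fixed space.

    ``stages`` are listed in optimization order (rigid first).  ``pull_points``
    maps fixed-space world coordinates to moving-space coordinates and is the
    direction used for resampling; ``fwd_points`` is its inverse.
    """

    ndim: int
    stages: list = field(default_factory=list)
    fixed_space: SpaceInfo | None = None
    moving_space: SpaceInfo | None = None

    def pull_points(self, pts: np.ndarray) -> np.ndarray:
        x = np.asarray(pts, float)
        for s in reversed(self.stages):
            x = s.pull_points(x)
        return x

    def fwd_points(self, pts: np.ndarray) -> np.ndarray:
        x = np.asarray(pts, float)
        for s in self.stages:
            x = s.fwd_points(x)
        return x

    def roundtrip_residual_mm(self, pts: np.ndarray) -> float:
        """Max |fwd(pull(x)) - x| over the given points."""
        pts = np.asarray(pts, float)
        return float(np.max(np.linalg.norm(self.fwd_points(self.pull_points(pts)) - pts,
                                           axis=1))) if pts.size else 0.0

    def to_dict(self) -> dict:
        return {
            "ndim": self.ndim,
            "stages": [s.to_dict() for s in self.stages],
            "fixed_space": self.fixed_space.to_dict() if self.fixed_space else None,
            "moving_space": self.moving_space.to_dict() if self.moving_space else None,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "TransformChain":
        def space(s):
            if s is None:
                return None
            return SpaceInfo(tuple(s["shape"]), np.array(s["spacing_mm"]),
                             np.array(s["origin_mm"]))

        return cls(d["ndim"], [_stage_from_dict(s) for s in d["stages"]],
                   space(d.get("fixed_space")), space(d.get("moving_space")))

    @classmethod
    def load(cls, path) -> "TransformChain":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _invert_stage(stage, grid_space: SpaceInfo | None):
    if isinstance(stage, _LinearBase):
        m, t = stage._matrix_offset()
        minv = np.linalg.inv(m)
        # pull' (y) = m^-1 (y - c - t) + c  ==  m^-1 (y - c) + c + (-m^-1 t)
        return LinearStage(stage.ndim, minv, -minv @ t, stage.center)
    if isinstance(stage, (NonlinearStage, DisplacementFieldStage)):
        if grid_space is None:
            raise ValueError("a fixed_space grid is required to invert a nonlinear stage")
        pts = grid_space.grid_points()
        inv_pts = stage.fwd_points(pts)  # solves x + u(x) = y on the grid
        field = (inv_pts - pts).T.reshape((stage.ndim, *grid_space.shape))
        return DisplacementFieldStage(stage.ndim, grid_space.origin,
                                      grid_space.spacing, field)
    raise TypeError(f"cannot invert stage of type {type(stage).__name__}")


def invert_chain(chain: TransformChain) -> TransformChain:
    """Invert a chain: linear stages in closed form, nonlinear numerically.

    The result maps fixed space to moving space (spaces swap roles); its pull
    direction equals the original chain's forward direction.
    """
    inv_stages = [_invert_stage(s, chain.fixed_space) for s in reversed(chain.stages)]
    return TransformChain(chain.ndim, inv_stages,
                          fixed_space=chain.moving_space,
                          moving_space=chain.fixed_space)


def apply_transform(image: ImageVolume | Image2D | LabelMap,
                    chain: TransformChain,
                    interpolation: str = "linear"):
    """Resample ``image`` (moving) onto the chain's fixed space.

    ``interpolation`` is "linear" or "cubic" for intensities or "nearest" for
    label maps; out-of-field locations get 0 / the background label.
    """
    if chain.fixed_space is None:
        raise ValueError("chain has no fixed_space geometry to resample onto")
    order = {"linear": 1, "nearest": 0, "cubic": 3}[interpolation]
    src = SpaceInfo.of(image)
    if src.ndim != chain.ndim:
        raise ValueError("image dimensionality does not match chain")
    fixed = chain.fixed_space
    pts = chain.pull_points(fixed.grid_points())
    idx = ((pts - src.origin) / src.spacing).T

    if isinstance(image, LabelMap):
        data = image.labels.astype(float)
        out = ndimage.map_coordinates(data, idx, order=0, mode="constant", cval=0.0)
        out = out.reshape(fixed.shape).astype(image.labels.dtype)
        return LabelMap(out, tuple(fixed.spacing), tuple(fixed.origin),
                        label_names=image.label_names)
    arr = image.voxels if isinstance(image, ImageVolume) else image.pixels
    out = ndimage.map_coordinates(arr, idx, order=order, mode="constant", cval=0.0)
    out = out.reshape(fixed.shape)
    if isinstance(image, ImageVolume):
        return ImageVolume(out, tuple(fixed.spacing), tuple(fixed.origin))
    return Image2D(out, float(fixed.spacing[0]), tuple(fixed.origin),
                   section_index=image.section_index, source=image.source)


def random_bspline_warp(ndim: int, origin_mm, extent_mm, control_spacing_mm: float,
                        amplitude_mm: float, seed: int) -> NonlinearStage:
    """A random smooth, invertible warp drawn on a B-spline control lattice.

    Control displacements are i.i.d. Gaussian, rescaled so the largest control
    displacement equals ``amplitude_mm`` (capped at the invertibility bound).
    """
    stage = NonlinearStage.for_domain(ndim, origin_mm, extent_mm, control_spacing_mm)
    rng = np.random.default_rng(seed)
    coeffs = rng.standard_normal(stage.coeffs.shape)
    peak = np.max(np.linalg.norm(coeffs, axis=0))
    target = min(amplitude_mm, stage.max_allowed_mm)
    if peak > 0:
        coeffs *= target / peak
    stage.coeffs = coeffs
    return stage
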