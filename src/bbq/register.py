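"""MIND-driven multi-stage deformable registration.

The cost is the mean Euclidean distance between the MIND descriptor vectors
of the fixed image and of the warped moving image, plus a smoothness penalty
(mean squared spatial gradient of the nonlinear displacement) that keeps the
deformation smooth and invertible.  It is minimized in successive stages —
3-D: rigid, isotropic scale, affine, nonlinear; 2-D: rigid, affine,
nonlinear — each initialized from the previous, over a multi-resolution
pyramid.

Low-dimensional (linear) stages use a derivative-free simplex search with the
MIND field of the warped moving image recomputed at every evaluation.  The
nonlinear stage optimizes cubic-B-spline control displacements with L-BFGS-B
and an analytic gradient; there the moving image is pre-warped through the
linear stages once per pyramid level, its MIND channels are computed once,
and the channels themselves are warped during the iterations.  Box bounds of
0.4x the control spacing on every control displacement guarantee the
deformation stays injective.

Everything is deterministic given the inputs and configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import ndimage, optimize

from .core import Image2D, ImageVolume, BlockfaceStack
from .mind import mind_descriptors, VARIANCE_FLOOR_REL
from .transforms import (AffineStage, NonlinearStage, RigidStage, ScaleStage,
                         SpaceInfo, TransformChain, upsample_coeffs,
                         project_to_coeffs, INVERTIBILITY_BOUND)

__all__ = ["RegistrationConfig", "register", "register_2d",
           "extract_corresponding_slice", "RegistrationError"]

logger = logging.getLogger(__name__)


class RegistrationError(RuntimeError):
    pass


@dataclass
class RegistrationConfig:
    """Tunable knobs of the multi-stage registration.

    ``pyramid_factors`` are decreasing integer downsampling factors (1 =
    native resolution).  ``maxiter_linear`` / ``maxiter_nonlinear`` cap the
    iterations per (stage, level); ``simplex_steps`` are the initial simplex
    extents in scaled parameter units, one per pyramid level (coarse levels
    search wider).  ``reg_weight`` is the nonlinear smoothness weight;
    ``control_spacing_mm`` sets the B-spline lattice pitch and thereby the
    largest representable displacement (0.4x the spacing).  ``presmooth_vox``
    is a Gaussian sigma (in voxels of the current pyramid level) applied to
    both images before computing MIND: without it, the interpolation inherent
    in warping smooths the moving image's noise while the fixed image keeps
    its own, and that asymmetric noise floor biases the optimum away from the
    true alignment.
    """

    stages: tuple[str, ...] = ("rigid", "scale", "affine", "nonlinear")
    pyramid_factors: tuple[int, ...] = (4, 2, 1)
    maxiter_linear: tuple[int, ...] = (200, 120, 40)
    maxiter_nonlinear: tuple[int, ...] = (0, 40, 30)
    simplex_steps: tuple[float, ...] = (1.0, 0.3, 0.1)
    angle_scale_rad: float = 0.05
    translation_scale_mm: float = 0.5
    log_scale_scale: float = 0.03
    affine_entry_scale: float = 0.03
    reg_weight: float = 5.0
    nonlinear_outer: int = 4
    control_spacing_mm: float = 2.5
    variance_floor_rel: float = VARIANCE_FLOOR_REL
    presmooth_vox: float = 0.7
    com_init: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if list(self.pyramid_factors) != sorted(self.pyramid_factors, reverse=True):
            raise ValueError("pyramid_factors must be decreasing")
        if self.reg_weight < 0:
            raise ValueError("reg_weight must be >= 0")
        n = len(self.pyramid_factors)
        for name in ("maxiter_linear", "maxiter_nonlinear", "simplex_steps"):
            v = getattr(self, name)
            if np.isscalar(v):
                v = (v,) * n
            v = tuple(v)
            if len(v) != n:
                raise ValueError(f"{name} must have one entry per pyramid level")
            setattr(self, name, v)

    @classmethod
    def default_2d(cls, **overrides) -> "RegistrationConfig":
        kw = dict(stages=("rigid", "affine", "nonlinear"),
                  pyramid_factors=(2, 1),
                  maxiter_linear=(150, 60),
                  maxiter_nonlinear=(30, 30),
                  simplex_steps=(0.6, 0.15),
                  reg_weight=3.0,
                  control_spacing_mm=1.5,
                  presmooth_vox=1.0)
        kw.update(overrides)
        return cls(**kw)


class _Level(NamedTuple):
    factor: int
    fixed_mind: np.ndarray
    space: SpaceInfo  # fixed-image grid at this level
    grid_pts: np.ndarray  # (N, ndim) world coordinates of that grid
    moving_coef: np.ndarray  # cubic-spline coefficients of (moving - min)
    moving_min: float
    moving_space: SpaceInfo


def _make_level(factor: int, fixed_mind: np.ndarray, space: SpaceInfo,
                moving_arr: np.ndarray, moving_space: SpaceInfo) -> _Level:
    lo = float(moving_arr.min())
    coef = ndimage.spline_filter(moving_arr - lo, order=3,
                                 mode="grid-constant")
    return _Level(factor, fixed_mind, space, space.grid_points(), coef, lo,
                  moving_space)


def _presmooth(arr: np.ndarray, sigma_vox: float) -> np.ndarray:
    return ndimage.gaussian_filter(arr, sigma_vox) if sigma_vox > 0 else arr


def _downsample(arr: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return arr
    sm = ndimage.gaussian_filter(arr, sigma=factor / 2.0)
    return sm[tuple(slice(None, None, factor) for _ in range(arr.ndim))]


def _level_space(space: SpaceInfo, factor: int) -> SpaceInfo:
    shape = tuple((s + factor - 1) // factor for s in space.shape)
    return SpaceInfo(shape, space.spacing * factor, space.origin)


def _center_of_mass_mm(arr: np.ndarray, space: SpaceInfo) -> np.ndarray:
    w = np.abs(arr - np.median(arr))
    total = w.sum()
    if total == 0:
        return space.center()
    com_idx = np.array(ndimage.center_of_mass(w))
    return space.origin + com_idx * space.spacing


def _param_scales(stage, cfg: RegistrationConfig) -> np.ndarray:
    if isinstance(stage, RigidStage):
        return np.concatenate([np.full(stage.angles.size, cfg.angle_scale_rad),
                               np.full(stage.ndim, cfg.translation_scale_mm)])
    if isinstance(stage, ScaleStage):
        return np.array([cfg.log_scale_scale])
    if isinstance(stage, AffineStage):
        d = stage.ndim
        return np.concatenate([np.full(d * d, cfg.affine_entry_scale),
                               np.full(d, cfg.translation_scale_mm)])
    raise TypeError(type(stage))


def _pull_through(stages: list, pts: np.ndarray) -> np.ndarray:
    for s in reversed(stages):
        pts = s.pull_points(pts)
    return pts


def _warped_moving(level: _Level, stages: list) -> np.ndarray:
    pts = _pull_through(stages, level.grid_pts)
    idx = ((pts - level.moving_space.origin) / level.moving_space.spacing).T
    out = ndimage.map_coordinates(level.moving_coef, idx, order=3,
                                  prefilter=False, mode="grid-constant",
                                  cval=0.0)
    return out.reshape(level.space.shape) + level.moving_min


def _overlap_fraction(level: _Level, stages: list) -> float:
    pts = _pull_through(stages, level.grid_pts)
    idx = (pts - level.moving_space.origin) / level.moving_space.spacing
    inside = np.all((idx >= 0) & (idx <= np.array(level.moving_space.shape) - 1),
                    axis=1)
    return float(inside.mean())


def _reg_penalty_and_grad(u: np.ndarray, spacing: np.ndarray, lam: float
                          ) -> tuple[float, np.ndarray]:
    """lam * mean squared forward-difference gradient of u, and its gradient."""
    ndim = u.shape[0]
    n = u[0].size
    penalty = 0.0
    grad = np.zeros_like(u)
    for c in range(ndim):
        for ax in range(ndim):
            dif = np.diff(u[c], axis=ax) / spacing[ax]
            penalty += float(np.sum(dif ** 2))
            g = dif * (2.0 / (spacing[ax] * n))
            lo = [slice(None)] * ndim
            hi = [slice(None)] * ndim
            lo[ax] = slice(None, -1)
            hi[ax] = slice(1, None)
            grad[c][tuple(lo)] -= g
            grad[c][tuple(hi)] += g
    return lam * penalty / n, lam * grad


def _mind_distance(desc_a: np.ndarray, desc_b: np.ndarray) -> float:
    return float(np.mean(np.sqrt(np.sum((desc_a - desc_b) ** 2, axis=0))))


def _optimize_linear(stage, stages_before: list, levels: list[_Level],
                     cfg: RegistrationConfig, vfloor: float) -> None:
    """Simplex search of one linear stage across the pyramid (in place)."""
    scales = _param_scales(stage, cfg)
    for li, level in enumerate(levels):
        maxiter = cfg.maxiter_linear[li]
        if maxiter <= 0:
            continue
        z0 = stage.get_params() / scales

        def cost(z):
            stage.set_params(z * scales)
            warped = _presmooth(_warped_moving(level, stages_before + [stage]),
                                cfg.presmooth_vox)
            return _mind_distance(mind_descriptors(warped, vfloor),
                                  level.fixed_mind)

        step = cfg.simplex_steps[li]
        simplex = np.vstack([z0] + [z0 + step * e for e in np.eye(len(z0))])
        res = optimize.minimize(cost, z0, method="Nelder-Mead",
                                options={"maxiter": maxiter,
                                         "initial_simplex": simplex,
                                         "xatol": 1e-4, "fatol": 1e-9})
        stage.set_params(res.x * scales)
        logger.debug("%s @1/%d: cost %.6f after %d evals",
                     type(stage).__name__, level.factor, res.fun, res.nfev)


def _optimize_nonlinear(stage: NonlinearStage, stages_before: list,
                        levels: list[_Level], cfg: RegistrationConfig,
                        vfloor: float) -> None:
    """L-BFGS-B over control displacements with analytic gradients.

    Per (level, outer iteration) the moving image is warped through the full
    current estimate, its MIND channels are computed once, and the channels
    are then resampled at the *incremental* displacement u - u0 during the
    inner optimization.  Warping descriptors instead of recomputing them is
    only accurate for small increments, so the outer loop re-linearizes at
    the running estimate until the increment is small.
    """
    bound = INVERTIBILITY_BOUND * float(stage.ctrl_spacing.min()) - 1e-9
    for li, level in enumerate(levels):
        maxiter = cfg.maxiter_nonlinear[li]
        if maxiter <= 0:
            continue
        shape = level.space.shape
        ndim = len(shape)
        sig = cfg.presmooth_vox
        fch = level.fixed_mind
        if sig > 0:
            fch = ndimage.gaussian_filter(fch, (0,) + (sig,) * ndim)
        mats = stage.basis_matrices(shape, level.space.spacing,
                                    level.space.origin)
        n_vox = int(np.prod(shape))
        grid = level.grid_pts.reshape(*shape, ndim)

        for outer in range(cfg.nonlinear_outer):
            m_cur = _presmooth(_warped_moving(level, stages_before + [stage]),
                               cfg.presmooth_vox)
            mch = mind_descriptors(m_cur, vfloor)
            # Smooth the descriptor fields of both sides identically: warping
            # the moving channels smooths whatever voxel-scale noise they
            # carry, so an unsmoothed pair rewards any deformation increment
            # for its blurring alone.
            if sig > 0:
                mch = ndimage.gaussian_filter(mch, (0,) + (sig,) * ndim)
            k = mch.shape[0]
            gch = np.stack([np.stack(np.gradient(mch[c], *level.space.spacing))
                            for c in range(k)])  # (k, ndim, *shape), per mm
            u0 = upsample_coeffs(stage.coeffs, mats)

            def fun_and_grad(c_flat):
                coeffs = c_flat.reshape(stage.coeffs.shape)
                u = upsample_coeffs(coeffs, mats)  # (ndim, *shape), mm
                pts = grid + np.moveaxis(u - u0, 0, -1)
                idx = [(pts[..., d].ravel() - level.space.origin[d])
                       / level.space.spacing[d] for d in range(ndim)]
                warped = np.stack([
                    ndimage.map_coordinates(mch[c], idx, order=1,
                                            mode="nearest").reshape(shape)
                    for c in range(k)])
                r = warped - fch
                e = np.sqrt(np.sum(r ** 2, axis=0) + 1e-24)
                data = float(np.mean(e))
                dedu = np.zeros((ndim, *shape))
                for c in range(k):
                    w = r[c] / (e * n_vox)
                    for d in range(ndim):
                        gcd = ndimage.map_coordinates(gch[c, d], idx, order=1,
                                                      mode="nearest"
                                                      ).reshape(shape)
                        dedu[d] += w * gcd
                penalty, preg = _reg_penalty_and_grad(u, level.space.spacing,
                                                      cfg.reg_weight)
                grad_c = project_to_coeffs(dedu + preg, mats)
                return data + penalty, grad_c.ravel()

            c0 = stage.coeffs.ravel().copy()
            res = optimize.minimize(fun_and_grad, c0, jac=True,
                                    method="L-BFGS-B",
                                    bounds=[(-bound, bound)] * c0.size,
                                    options={"maxiter": maxiter, "ftol": 1e-12,
                                             "gtol": 1e-10})
            step = float(np.max(np.abs(res.x - c0)))
            stage.coeffs = res.x.reshape(stage.coeffs.shape)
            logger.debug("nonlinear @1/%d outer %d: cost %.6f step %.4f mm",
                         level.factor, outer, res.fun, step)
            if step < 0.05 * float(stage.ctrl_spacing.min()):
                break


def register(fixed: ImageVolume, moving: ImageVolume,
             config: RegistrationConfig | None = None,
             init: TransformChain | None = None) -> TransformChain:
    """Register ``moving`` to ``fixed`` (3-D), returning the transform chain.

    ``init`` optionally supplies a coarse pre-alignment (standing in for a
    manual reorientation); its stages are kept frozen at the head of the
    returned chain.  When no init is given, the rigid translation starts from
    the intensity centre-of-mass offset.  The returned chain carries a
    ``stage_objectives`` list logging the full-resolution objective after each
    stage (non-increasing, since every stage starts from the previous optimum
    and only accepts improvements at the finest level).
    """
    return _register_nd(fixed, moving, config or RegistrationConfig(), init)


def register_2d(fixed: Image2D, moving: Image2D,
                config: RegistrationConfig | None = None,
                direction: str = "to-fixed") -> TransformChain:
    """2-D bidirectional registration (rigid, affine, nonlinear stages).

    ``direction`` selects the target space: "to-fixed" (default) resamples
    ``moving`` onto ``fixed``'s grid; "swap" exchanges the roles for the case
    where the downstream goal lives in the other image's space.
    """
    if direction == "swap":
        fixed, moving = moving, fixed
    elif direction != "to-fixed":
        raise ValueError("direction must be 'to-fixed' or 'swap'")
    cfg = config or RegistrationConfig.default_2d()
    return _register_nd(fixed, moving, cfg, None)


def _register_nd(fixed, moving, cfg: RegistrationConfig,
                 init: TransformChain | None) -> TransformChain:
    fixed_arr = fixed.voxels if isinstance(fixed, ImageVolume) else fixed.pixels
    moving_arr = moving.voxels if isinstance(moving, ImageVolume) else moving.pixels
    if not (np.all(np.isfinite(fixed_arr)) and np.all(np.isfinite(moving_arr))):
        raise ValueError("volumes must be finite")
    fixed_space = SpaceInfo.of(fixed)
    moving_space = SpaceInfo.of(moving)
    ndim = fixed_space.ndim
    vfloor = cfg.variance_floor_rel
    center = fixed_space.center()
    frozen: list = list(init.stages) if init is not None else []

    levels: list[_Level] = []
    for factor in cfg.pyramid_factors:
        f_arr = _downsample(fixed_arr, factor)
        if min(f_arr.shape) < 4:
            raise ValueError(f"pyramid factor {factor} leaves too small an image")
        lsp = _level_space(fixed_space, factor)
        f_mind = mind_descriptors(_presmooth(f_arr, cfg.presmooth_vox), vfloor)
        levels.append(_make_level(factor, f_mind, lsp,
                                  _downsample(moving_arr, factor),
                                  _level_space(moving_space, factor)))
    finest = levels[-1]

    if init is not None:
        overlap = _overlap_fraction(finest, frozen)
        if overlap < 0.05:
            raise RegistrationError(
                f"initial transform leaves only {overlap:.1%} of the fixed "
                "field of view inside the moving volume")

    stage_objectives: list[tuple[str, float]] = []
    stages: list = []

    def record(name: str) -> None:
        warped = _presmooth(_warped_moving(finest, frozen + stages),
                            cfg.presmooth_vox)
        cost = _mind_distance(mind_descriptors(warped, vfloor),
                              finest.fixed_mind)
        for s in stages:
            if isinstance(s, NonlinearStage):
                u = s.displacement_on_grid(finest.space.shape,
                                           finest.space.spacing,
                                           finest.space.origin)
                cost += _reg_penalty_and_grad(u, finest.space.spacing,
                                              cfg.reg_weight)[0]
        stage_objectives.append((name, cost))
        logger.info("objective after %s: %.6f", name, cost)

    record("init")

    for name in cfg.stages:
        if name == "rigid":
            stage = RigidStage.identity(ndim, center)
            if cfg.com_init and init is None and not stages:
                com_f = _center_of_mass_mm(fixed_arr, fixed_space)
                com_m = _center_of_mass_mm(moving_arr, moving_space)
                stage.translation = com_m - com_f
        elif name == "scale":
            if ndim != 3:
                raise ValueError("the isotropic scale stage is 3-D only")
            stage = ScaleStage.identity(ndim, center)
        elif name == "affine":
            stage = AffineStage.identity(ndim, center)
        elif name == "nonlinear":
            stage = NonlinearStage.for_domain(
                ndim, fixed_space.origin,
                (np.array(fixed_space.shape) - 1) * fixed_space.spacing,
                cfg.control_spacing_mm)
        else:
            raise ValueError(f"unknown stage {name!r}")

        p0 = stage.coeffs.ravel().copy() if name == "nonlinear" \
            else stage.get_params()
        if name == "nonlinear":
            _optimize_nonlinear(stage, frozen + stages, levels, cfg, vfloor)
        else:
            _optimize_linear(stage, frozen + stages, levels, cfg, vfloor)
        stages.append(stage)
        cost_before = stage_objectives[-1][1]
        record(name)
        if stage_objectives[-1][1] > cost_before + 1e-12:
            # a coarse level led the stage astray; keep the previous optimum
            if name == "nonlinear":
                stage.coeffs = p0.reshape(stage.coeffs.shape)
            else:
                stage.set_params(p0)
            stage_objectives.pop()
            record(name + " (reverted)")

    chain = TransformChain(ndim, frozen + stages, fixed_space=fixed_space,
                           moving_space=moving_space)
    chain.stage_objectives = stage_objectives
    return chain


def extract_corresponding_slice(registered_mri: ImageVolume,
                                stack: BlockfaceStack,
                                section_index: int) -> Image2D:
    """Extract the MRI plane corresponding to blockface section ``k``.

    ``registered_mri`` must already live in the blockface volume's space (one
    z-plane per section), so plane ``k`` is the MRI counterpart of blockface
    photo ``k`` and of the histology section cut at that position.
    """
    positions = {idx: pos for pos, idx in enumerate(stack.section_indices)}
    if section_index not in positions:
        raise IndexError(f"section index {section_index} not present in stack")
    img = registered_mri.plane(positions[section_index], source="mri")
    img.section_index = int(section_index)
    return img
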