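"""Transform stage and chain tests: inverses, serialization, resampling."""

import numpy as np
import pytest

from bbq.core import ImageVolume, LabelMap
from bbq.transforms import (AffineStage, DisplacementFieldStage, NonlinearStage,
                            RigidStage, ScaleStage, SpaceInfo, TransformChain,
                            apply_transform, invert_chain, random_bspline_warp,
                            rotation_matrix)


def _space(shape=(20, 20, 20), spacing=0.5):
    return SpaceInfo(shape, np.full(len(shape), spacing),
                     np.zeros(len(shape)))


def _random_points(rng, n, lo=1.0, hi=8.0, ndim=3):
    return rng.uniform(lo, hi, size=(n, ndim))


@pytest.mark.parametrize("stage_factory", [
    lambda c: RigidStage(3, np.array([0.1, -0.05, 0.2]),
                         np.array([0.3, -0.1, 0.2]), c),
    lambda c: ScaleStage(3, 1.07, c),
    lambda c: AffineStage(3, np.eye(3) + 0.05 * np.arange(9).reshape(3, 3) / 9,
                          np.array([0.1, 0.0, -0.2]), c),
])
def test_linear_stage_fwd_pull_are_inverses(stage_factory):
    rng = np.random.default_rng(0)
    stage = stage_factory(np.array([5.0, 5.0, 5.0]))
    pts = _random_points(rng, 50)
    assert np.allclose(stage.pull_points(stage.fwd_points(pts)), pts, atol=1e-10)
    assert np.allclose(stage.fwd_points(stage.pull_points(pts)), pts, atol=1e-10)


def test_rotation_matrix_is_orthonormal():
    r3 = rotation_matrix([0.2, -0.4, 0.9], 3)
    r2 = rotation_matrix([0.3], 2)
    assert np.allclose(r3 @ r3.T, np.eye(3), atol=1e-12)
    assert np.isclose(np.linalg.det(r3), 1.0)
    assert np.allclose(r2 @ r2.T, np.eye(2), atol=1e-12)


def test_nonlinear_fwd_pull_roundtrip():
    warp = random_bspline_warp(3, (0.0, 0.0, 0.0), (10.0, 10.0, 10.0),
                               control_spacing_mm=2.5, amplitude_mm=0.8, seed=1)
    rng = np.random.default_rng(2)
    pts = _random_points(rng, 40, 2.0, 8.0)
    back = warp.fwd_points(warp.pull_points(pts))
    assert np.max(np.linalg.norm(back - pts, axis=1)) < 1e-3


def test_random_bspline_warp_respects_invertibility_bound():
    warp = random_bspline_warp(3, (0.0, 0.0, 0.0), (10.0, 10.0, 10.0),
                               control_spacing_mm=2.5, amplitude_mm=50.0, seed=3)
    peak = np.max(np.linalg.norm(warp.coeffs, axis=0))
    assert peak <= warp.max_allowed_mm + 1e-12
    # and the capped warp must still invert cleanly
    rng = np.random.default_rng(4)
    pts = _random_points(rng, 30, 2.0, 8.0)
    assert np.max(np.linalg.norm(
        warp.fwd_points(warp.pull_points(pts)) - pts, axis=1)) < 1e-2


def test_chain_roundtrip_residual_and_double_inversion():
    space = _space()
    c = space.center()
    chain = TransformChain(3, [
        RigidStage(3, np.array([0.05, 0.02, -0.03]), np.array([0.2, 0.1, 0.0]), c),
        ScaleStage(3, 1.04, c),
        random_bspline_warp(3, space.origin, (np.array(space.shape) - 1) * space.spacing,
                            2.5, 0.5, seed=5),
    ], fixed_space=space, moving_space=space)
    pts = space.grid_points()[::37]
    assert chain.roundtrip_residual_mm(pts) < 1e-3

    inv = invert_chain(chain)
    # fwd∘inv.fwd ≈ identity on interior points (numeric field inversion)
    interior = pts[np.all((pts > 1.5) & (pts < 8.0), axis=1)]
    back = inv.fwd_points(chain.fwd_points(interior))
    assert np.max(np.linalg.norm(back - interior, axis=1)) < 0.1

    inv2 = invert_chain(inv)
    back2 = inv2.fwd_points(interior)
    fwd = chain.fwd_points(interior)
    assert np.max(np.linalg.norm(back2 - fwd, axis=1)) < 0.1


def test_chain_save_load_roundtrip(tmp_path):
    space = _space((10, 12, 14), 0.3)
    c = space.center()
    chain = TransformChain(3, [
        RigidStage(3, np.array([0.1, 0.0, -0.2]), np.array([1.0, 0.0, 0.5]), c),
        ScaleStage(3, 0.96, c),
        AffineStage(3, np.eye(3) * 1.01, np.zeros(3), c),
        random_bspline_warp(3, space.origin,
                            (np.array(space.shape) - 1) * space.spacing,
                            1.5, 0.3, seed=6),
    ], fixed_space=space, moving_space=space)
    path = tmp_path / "chain.json"
    chain.save(path)
    loaded = TransformChain.load(path)
    pts = space.grid_points()[::11]
    assert np.allclose(loaded.pull_points(pts), chain.pull_points(pts), atol=1e-12)
    assert loaded.fixed_space.shape == space.shape


def test_apply_transform_integer_shift_nearest_oracle():
    rng = np.random.default_rng(7)
    vol = ImageVolume(rng.normal(size=(12, 12, 12)), (1.0, 1.0, 1.0))
    space = SpaceInfo.of(vol)
    # pull map x -> x + (2, 0, 0) mm: output voxel p samples input voxel p + 2
    stage = AffineStage(3, np.eye(3), np.array([2.0, 0.0, 0.0]), np.zeros(3))
    chain = TransformChain(3, [stage], fixed_space=space, moving_space=space)
    out = apply_transform(vol, chain, interpolation="nearest")
    assert np.allclose(out.voxels[:-2], vol.voxels[2:])


def test_apply_transform_labels_use_nearest_and_keep_dtype():
    labels = LabelMap(np.arange(27).reshape(3, 3, 3) % 4, (1.0, 1.0, 1.0))
    space = SpaceInfo.of(labels)
    chain = TransformChain(3, [], fixed_space=space, moving_space=space)
    out = apply_transform(labels, chain, interpolation="nearest")
    assert out.labels.dtype == labels.labels.dtype
    assert np.array_equal(out.labels, labels.labels)


def test_apply_transform_requires_fixed_space():
    vol = ImageVolume(np.zeros((4, 4, 4)), (1.0, 1.0, 1.0))
    with pytest.raises(ValueError):
        apply_transform(vol, TransformChain(3, []))


def test_displacement_field_stage_matches_constant_shift():
    space = _space((8, 8, 8), 1.0)
    field = np.zeros((3, 8, 8, 8))
    field[0] = 1.5  # pull displacement +1.5 mm along x
    stage = DisplacementFieldStage(3, space.origin, space.spacing, field)
    pts = space.grid_points()[::13]
    assert np.allclose(stage.pull_points(pts) - pts,
                       np.array([1.5, 0.0, 0.0]), atol=1e-9)
    back = stage.fwd_points(stage.pull_points(pts))
    interior = np.all((pts > 1.0) & (pts < 6.0), axis=1)
    assert np.max(np.linalg.norm(back[interior] - pts[interior], axis=1)) < 1e-3


def test_nonlinear_displacement_matches_basis_expansion():
    warp = random_bspline_warp(2, (0.0, 0.0), (9.0, 9.0), 3.0, 0.5, seed=8)
    shape, spacing, origin = (10, 10), np.array([1.0, 1.0]), np.zeros(2)
    dense = warp.displacement_on_grid(shape, spacing, origin)
    pts = SpaceInfo(shape, spacing, origin).grid_points()
    at_pts = warp.displacement_at_points(pts).T.reshape((2, *shape))
    assert np.allclose(dense, at_pts, atol=1e-9)
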