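"""Registration tests: identity stability and parameter recovery.

Recovery tests render the misaligned moving image on an expanded canvas so
no content is lost at the borders, and create it with cubic interpolation to
match the interpolation the optimizer uses when warping candidates.
"""

import numpy as np
import pytest

from bbq.core import Image2D
from bbq.phantom import MRI_INTENSITY, make_phantom, render_mri
from bbq.register import (RegistrationConfig, extract_corresponding_slice,
                          register, register_2d)
from bbq.transforms import (RigidStage, ScaleStage, SpaceInfo, TransformChain,
                            apply_transform)


@pytest.fixture(scope="module")
def mri48():
    scene = make_phantom((48, 48, 48), 0.1, 2, seed=11)
    vol, _ = render_mri(scene, MRI_INTENSITY, noise_sd=1.0, seed=21)
    return vol


def _expanded(space, margin):
    return SpaceInfo(tuple(s + 2 * margin for s in space.shape), space.spacing,
                     space.origin - margin * space.spacing)


def test_register_identity_recovers_no_motion(mri48):
    cfg = RegistrationConfig(stages=("rigid",), pyramid_factors=(2,),
                             maxiter_linear=(60,), simplex_steps=(0.3,),
                             maxiter_nonlinear=(0,))
    chain = register(mri48, mri48.copy(), cfg)
    rigid = chain.stages[0]
    assert np.max(np.abs(rigid.angles)) < np.deg2rad(0.3)
    assert np.max(np.abs(rigid.translation)) < 0.05  # mm


def test_register_recovers_rigid_misalignment(mri48):
    space = SpaceInfo.of(mri48)
    c = space.center()
    true = RigidStage(3, np.deg2rad([3.0, -2.0, 2.5]),
                      np.array([0.2, -0.15, 0.1]), c)
    mis = TransformChain(3, [true], fixed_space=_expanded(space, 6),
                         moving_space=space)
    moving = apply_transform(mri48, mis, interpolation="cubic")
    cfg = RegistrationConfig(stages=("rigid",))
    chain = register(mri48, moving, cfg)
    # recovered chain composed with the applied one ≈ identity on test points
    pts = space.grid_points()[::271]
    pulled = true.pull_points(chain.pull_points(pts))
    err = np.linalg.norm(pulled - pts, axis=1)
    assert err.mean() < 0.1  # 1 voxel = 0.1 mm


def test_register_recovers_scale(mri48):
    space = SpaceInfo.of(mri48)
    c = space.center()
    true = ScaleStage(3, 1.08, c)
    mis = TransformChain(3, [true], fixed_space=_expanded(space, 6),
                         moving_space=space)
    moving = apply_transform(mri48, mis, interpolation="cubic")
    chain = register(mri48, moving, RegistrationConfig(stages=("rigid", "scale")))
    rec = [s for s in chain.stages if isinstance(s, ScaleStage)][0]
    assert abs(rec.scale * 1.08 - 1.0) < 0.01


def test_register_2d_recovers_translation():
    scene = make_phantom((48, 48, 48), 0.1, 1, seed=13)
    vol, _ = render_mri(scene, MRI_INTENSITY, noise_sd=1.0, seed=23)
    img = vol.plane(24)
    space = SpaceInfo.of(img)
    true = RigidStage(2, np.array([np.deg2rad(2.0)]), np.array([0.15, -0.1]),
                      space.center())
    mis = TransformChain(2, [true], fixed_space=_expanded(space, 6),
                         moving_space=space)
    moving = apply_transform(img, mis, interpolation="cubic")
    chain = register_2d(img, moving,
                        RegistrationConfig.default_2d(stages=("rigid",)))
    pts = space.grid_points()[::37]
    pulled = true.pull_points(chain.pull_points(pts))
    assert np.linalg.norm(pulled - pts, axis=1).mean() < 0.1


def test_register_reports_stage_objectives(mri48):
    cfg = RegistrationConfig(stages=("rigid",), pyramid_factors=(4,),
                             maxiter_linear=(20,), simplex_steps=(0.5,),
                             maxiter_nonlinear=(0,))
    chain = register(mri48, mri48.copy(), cfg)
    names = [n for n, _ in chain.stage_objectives]
    assert names == ["init", "rigid"]
    assert all(np.isfinite(v) for _, v in chain.stage_objectives)


def test_registration_config_validation():
    with pytest.raises(ValueError):
        RegistrationConfig(pyramid_factors=(1, 2))
    with pytest.raises(ValueError):
        RegistrationConfig(reg_weight=-1.0)
    with pytest.raises(ValueError):
        RegistrationConfig(maxiter_linear=(10, 20))  # 2 entries, 3 levels


def test_extract_corresponding_slice(mri48):
    from bbq.core import BlockfaceStack
    stack = BlockfaceStack(
        slices=[np.zeros((48, 48))] * 48, section_indices=list(range(48)),
        pixel_size_mm=0.1, section_spacing_mm=0.1)
    img = extract_corresponding_slice(mri48, stack, 30)
    assert isinstance(img, Image2D)
    assert img.section_index == 30
    assert np.array_equal(img.pixels, mri48.voxels[:, :, 30])
    with pytest.raises(IndexError):
        extract_corresponding_slice(mri48, stack, 99)
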