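"""Overlap and curve-distance metric tests with closed-form oracles."""

import numpy as np
import pytest

from bbq.core import BlockfaceStack, Image2D, LabelMap
from bbq.metrics import (dice, evaluate_registration, mean_curve_distance,
                         reconstruct_histology_volume, resample_curve,
                         skeletonize_vessel)
from bbq.transforms import AffineStage, SpaceInfo, TransformChain


def _cube_labels(shift=0):
    arr = np.zeros((30, 30, 30), dtype=int)
    arr[5 + shift:25 + shift, 5:25, 5:25] = 1
    return LabelMap(arr, (1.0, 1.0, 1.0))


def test_shifted_cube_dice_closed_form():
    # 20-voxel cube shifted by 2 along one axis: overlap 18/20 per axis
    a, b = _cube_labels(0), _cube_labels(2)
    expected = 2 * (18 * 20 * 20) / (2 * 20 ** 3)
    assert dice(a, b) == pytest.approx(expected)  # = 0.9


def test_identical_inputs_give_dice_one_and_zero_distance():
    a = _cube_labels()
    assert dice(a, a) == 1.0
    line = np.column_stack([np.linspace(0, 10, 50), np.zeros(50), np.zeros(50)])
    assert mean_curve_distance(line, line) == 0.0


def test_dice_both_empty_is_nan_with_warning():
    empty = LabelMap(np.zeros((5, 5, 5), dtype=int), (1.0,) * 3)
    with pytest.warns(UserWarning):
        assert np.isnan(dice(empty, empty))


def test_dice_one_sided_label_is_zero():
    a = _cube_labels()
    empty = LabelMap(np.zeros_like(a.labels), (1.0,) * 3)
    assert dice(a, empty) == 0.0


def test_evaluate_registration_reports_one_sided_labels():
    a = _cube_labels()
    b = LabelMap(np.where(a.labels == 1, 2, 0), (1.0,) * 3)
    rep = evaluate_registration(a, b, None)
    assert rep.per_label_dice[1] == 0.0
    assert rep.per_label_dice[2] == 0.0
    assert rep.whole_tissue_dice == 1.0  # same foreground, different labels
    frame = rep.to_frame()
    assert set(frame["label"]) == {1, 2, -1}


def test_evaluate_registration_resamples_through_chain():
    a = _cube_labels()
    space = SpaceInfo.of(a)
    # chain whose pull map shifts content so the moved cube matches exactly
    stage = AffineStage(3, np.eye(3), np.array([2.0, 0.0, 0.0]), np.zeros(3))
    chain = TransformChain(3, [stage], fixed_space=space, moving_space=space)
    moved_back = evaluate_registration(_cube_labels(-2), _cube_labels(0), chain)
    identity = evaluate_registration(_cube_labels(-2), _cube_labels(0), None)
    assert moved_back.whole_tissue_dice > identity.whole_tissue_dice
    assert moved_back.whole_tissue_dice == 1.0


def test_parallel_line_curve_distance_equals_offset():
    t = np.linspace(0, 10, 80)
    a = np.column_stack([t, np.zeros_like(t), np.zeros_like(t)])
    b = a + np.array([0.0, 0.7, 0.0])
    ra = resample_curve(a, 25)
    rb = resample_curve(b, 25)
    assert mean_curve_distance(ra, rb) == pytest.approx(0.7, abs=1e-6)


def test_mean_curve_distance_orientation_invariant():
    t = np.linspace(0, 5, 30)
    a = np.column_stack([t, t ** 2 / 5, np.zeros_like(t)])
    assert mean_curve_distance(a, a[::-1]) == pytest.approx(0.0, abs=1e-12)


def test_resample_curve_uniform_arc_length():
    t = np.linspace(0, 2 * np.pi, 100)
    helix = np.column_stack([np.cos(t), np.sin(t), t / 3])
    out = resample_curve(helix, 40)
    assert out.shape == (40, 3)
    gaps = np.linalg.norm(np.diff(out, axis=0), axis=1)
    assert gaps.std() / gaps.mean() < 0.01


def test_resample_curve_rejects_degenerate_input():
    with pytest.raises(ValueError):
        resample_curve(np.ones((10, 3)), 5)
    with pytest.raises(ValueError):
        resample_curve(np.zeros((1, 3)), 5)


def test_skeletonize_straight_tube_recovers_axis():
    arr = np.zeros((9, 9, 40), dtype=int)
    xg, yg = np.meshgrid(np.arange(9), np.arange(9), indexing="ij")
    disk = (xg - 4) ** 2 + (yg - 4) ** 2 <= 4
    arr[:, :, 3:37][disk] = 1
    mask = LabelMap(arr, (0.1, 0.1, 0.1))
    pts = skeletonize_vessel(mask)
    # centerline stays near the tube axis (x = y = 0.4 mm)
    assert np.max(np.abs(pts[:, 0] - 0.4)) < 0.15
    assert np.max(np.abs(pts[:, 1] - 0.4)) < 0.15
    assert pts[:, 2].max() - pts[:, 2].min() > 2.0


def test_skeletonize_rejects_empty_and_fragmented():
    empty = LabelMap(np.zeros((5, 5, 5), dtype=int), (1.0,) * 3)
    with pytest.raises(ValueError):
        skeletonize_vessel(empty)
    frag = np.zeros((10, 10, 10), dtype=int)
    frag[1, 1, 1] = 1
    frag[8, 8, 8] = 1
    with pytest.raises(ValueError):
        skeletonize_vessel(LabelMap(frag, (1.0,) * 3))


def _stack(nz):
    return BlockfaceStack(slices=[np.zeros((6, 6))] * nz,
                          section_indices=list(range(nz)),
                          pixel_size_mm=0.5, section_spacing_mm=0.5)


def test_reconstruct_histology_volume_linear_fill_interpolates():
    s0 = Image2D(np.zeros((6, 6)), 0.5, section_index=0)
    s4 = Image2D(np.full((6, 6), 8.0), 0.5, section_index=4)
    vol = reconstruct_histology_volume([s4, s0], _stack(6), fill="linear")
    assert vol.shape == (6, 6, 6)
    assert np.allclose(vol.voxels[:, :, 2], 4.0)  # halfway between 0 and 8
    assert np.allclose(vol.voxels[:, :, 5], 8.0)  # clamped beyond the last


def test_reconstruct_histology_volume_nearest_fill():
    s0 = Image2D(np.zeros((6, 6)), 0.5, section_index=0)
    s4 = Image2D(np.full((6, 6), 8.0), 0.5, section_index=4)
    vol = reconstruct_histology_volume([s0, s4], _stack(6), fill="nearest")
    assert np.allclose(vol.voxels[:, :, 1], 0.0)
    assert np.allclose(vol.voxels[:, :, 3], 8.0)


def test_reconstruct_histology_volume_validates_input():
    s0 = Image2D(np.zeros((6, 6)), 0.5, section_index=0)
    with pytest.raises(ValueError):
        reconstruct_histology_volume([], _stack(4))
    with pytest.raises(ValueError):
        reconstruct_histology_volume([s0, s0], _stack(4))
    with pytest.raises(ValueError):
        reconstruct_histology_volume([s0], _stack(4), fill="cubic")
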