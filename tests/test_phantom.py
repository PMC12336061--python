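"""Phantom generator tests: determinism, geometry, and recorded ground truth."""

import numpy as np
import pytest

from bbq.phantom import (DistortionSpec, HistologyDeformationSpec,
                         BLOCKFACE_INTENSITY, MRI_INTENSITY, make_phantom,
                         render_blockface_stack, render_calibration_grid,
                         render_histology_sections, render_mri)


def test_make_phantom_deterministic():
    a = make_phantom((48, 48, 48), 0.1, 2, seed=7)
    b = make_phantom((48, 48, 48), 0.1, 2, seed=7)
    c = make_phantom((48, 48, 48), 0.1, 2, seed=8)
    assert np.array_equal(a.labels, b.labels)
    assert not np.array_equal(a.labels, c.labels)


def test_make_phantom_contains_all_labels(scene):
    assert set(np.unique(scene.labels)) == {0, 1, 2, 3, 4, 5}


def test_vessels_span_at_least_ten_sections(scene):
    assert len(scene.vessel_centerlines) == 2
    for line in scene.vessel_centerlines:
        z = line[:, 2] / scene.voxel_size_mm
        assert z.max() - z.min() >= 10
    z_extent = np.nonzero((scene.labels == 5).any(axis=(0, 1)))[0]
    assert z_extent.max() - z_extent.min() >= 10


def test_make_phantom_validates_arguments():
    with pytest.raises(ValueError):
        make_phantom((16, 48, 48), 0.1, 1, seed=0)
    with pytest.raises(ValueError):
        make_phantom((48, 48, 48), 0.1, -1, seed=0)


def test_render_mri_noiseless_matches_table(scene, mri_clean):
    for label, value in MRI_INTENSITY.items():
        mask = scene.labels == label
        assert np.allclose(mri_clean.voxels[mask], value)


def test_render_mri_records_bias_field(scene, mri_noisy):
    vol, gt = mri_noisy
    assert gt.mri_bias_field is not None
    assert np.max(np.abs(gt.mri_bias_field - 1.0)) <= 0.02 + 1e-12
    assert vol.shape == scene.shape


def test_blockface_stack_records_every_corruption(scene, distorted_stack):
    stack, gt, spec = distorted_stack
    nz = scene.shape[2]
    assert len(stack) == nz
    assert gt.vertical_offsets_mm.shape == (nz,)
    assert gt.column_gains.shape == (nz, scene.shape[0])
    assert np.array_equal(gt.perspective_affine, spec.perspective_affine)
    assert gt.bias_gradient_amplitude == spec.bias_gradient_amplitude
    assert len(gt.clean_planes) == nz
    # jitter draws follow the requested scale (loose 5-sigma-of-SD bound)
    assert 0.01 < np.std(gt.vertical_offsets_mm) < 0.12


def test_blockface_identity_spec_reproduces_clean_rendering(scene):
    stack, gt = render_blockface_stack(scene, DistortionSpec(seed=1))
    k = scene.shape[2] // 2
    expected = np.zeros(scene.shape[:2])
    lut = dict(BLOCKFACE_INTENSITY)
    plane_labels = scene.labels[:, :, k]
    for lab, v in lut.items():
        expected[plane_labels == lab] = v
    assert np.allclose(stack.slices[k], expected)
    assert np.allclose(stack.slices[k], gt.clean_planes[k])


def test_calibration_grid_records_ideal_and_distorted_centers(calibration_grid):
    img, gt, spec = calibration_grid
    assert gt.grid_dot_centers_px.shape == (64, 2)
    assert gt.grid_dot_centers_ideal_px.shape == (64, 2)
    # distorted = affine(ideal) about the image centre
    a = spec.perspective_affine
    center = (np.array(img.shape, float) - 1) / 2.0
    pred = (gt.grid_dot_centers_ideal_px - center) @ a[:, :2].T + center + a[:, 2]
    assert np.allclose(pred, gt.grid_dot_centers_px, atol=1e-9)


def test_histology_sections_warp_amplitude_and_determinism(scene,
                                                           histology_sections):
    sections, gt, spec = histology_sections
    assert [s.section_index for s in sections] == [12, 24, 36]
    for k in (12, 24, 36):
        disp = gt.histology_displacements_mm[k]
        mag = np.linalg.norm(disp, axis=0)
        assert mag.max() <= spec.displacement_amplitude_mm + 1e-9
        assert mag.max() > 0.5 * spec.displacement_amplitude_mm
    again, _ = render_histology_sections(scene, [12, 24, 36], spec)
    assert np.array_equal(again[0].pixels, sections[0].pixels)


def test_histology_contrast_differs_from_blockface(scene, histology_sections):
    sections, _, _ = histology_sections
    # stain-like remap inverts contrast: the ribbon is darkest in the raw
    # table, so after the inverted remap it renders brightest
    k = 24
    plane_labels = scene.labels[:, :, k]
    img = sections[1].pixels
    assert img[plane_labels == 4].mean() > img[plane_labels == 0].mean()


def test_distortion_spec_validation():
    with pytest.raises(ValueError):
        DistortionSpec(perspective_affine=np.zeros((2, 3)))
    with pytest.raises(ValueError):
        DistortionSpec(vertical_jitter_sd_mm=-1.0)
    with pytest.raises(ValueError):
        DistortionSpec(depth_weights=(0.7, 0.5))
    with pytest.raises(ValueError):
        HistologyDeformationSpec(smoothness_mm=0.0)


def test_depth_contamination_mixes_deeper_planes(scene):
    spec = DistortionSpec(depth_weights=(0.3,), seed=2)
    stack, gt = render_blockface_stack(scene, spec)
    clean, _ = render_blockface_stack(scene, DistortionSpec(seed=2))
    k = scene.shape[2] // 2
    expected = 0.7 * clean.slices[k] + 0.3 * clean.slices[k + 1]
    assert np.allclose(stack.slices[k], expected)
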