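"""Shared fixtures: a small deterministic phantom scene and its renderings."""

import numpy as np
import pytest

from bbq.phantom import (DistortionSpec, HistologyDeformationSpec,
                         make_phantom, render_blockface_stack,
                         render_calibration_grid, render_histology_sections,
                         render_mri, MRI_INTENSITY)


@pytest.fixture(scope="session")
def scene():
    return make_phantom((48, 48, 48), 0.1, 2, seed=7)


@pytest.fixture(scope="session")
def mri_clean(scene):
    vol, _ = render_mri(scene, MRI_INTENSITY, noise_sd=0.0, seed=1)
    return vol


@pytest.fixture(scope="session")
def mri_noisy(scene):
    vol, gt = render_mri(scene, MRI_INTENSITY, noise_sd=1.0, seed=1,
                         bias_amplitude=0.02)
    return vol, gt


@pytest.fixture(scope="session")
def distorted_stack(scene):
    spec = DistortionSpec(
        perspective_affine=np.array([[0.9, 0.05, 0.0], [0.0, 1.0, 0.0]]),
        vertical_jitter_sd_mm=0.05,
        line_gain_amplitude=0.15,
        bias_gradient_amplitude=0.1,
        noise_sd=1.0,
        seed=3,
    )
    stack, gt = render_blockface_stack(scene, spec)
    return stack, gt, spec


@pytest.fixture(scope="session")
def calibration_grid():
    spec = DistortionSpec(
        perspective_affine=np.array([[0.8, np.tan(np.deg2rad(5.0)), 0.0],
                                     [0.0, 1.0, 0.0]]),
        seed=5,
    )
    img, gt = render_calibration_grid(spec, dot_spacing_mm=5.0,
                                      grid_extent=(8, 8), pixel_size_mm=0.25,
                                      dot_sigma_px=2.0)
    return img, gt, spec


@pytest.fixture(scope="session")
def histology_sections(scene):
    spec = HistologyDeformationSpec(displacement_amplitude_mm=0.15,
                                    smoothness_mm=1.2, noise_sd=1.0, seed=9)
    sections, gt = render_histology_sections(scene, [12, 24, 36], spec)
    return sections, gt, spec
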