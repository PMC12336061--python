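"""End-to-end pipeline driver: simulate (or load), reconstruct, register in
3-D, extract corresponding slices, register in 2-D, evaluate.

The driver writes every intermediate artifact plus a run manifest (stage list,
seed, config hash) into the output directory, and is bit-reproducible for a
fixed config and seed.  A single global seed fans out to per-stage seeds by
fixed offsets so stages can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as bbq_io
from .blockface import detect_grid_points, estimate_calibration, reconstruct
from .core import LabelMap
from .metrics import evaluate_registration, reconstruct_histology_volume
from .phantom import (DistortionSpec, HistologyDeformationSpec, LABEL_NAMES,
                      make_phantom, render_blockface_stack,
                      render_calibration_grid, render_histology_sections,
                      render_mri, MRI_INTENSITY, BLOCKFACE_INTENSITY)
from .register import (RegistrationConfig, register, register_2d,
                       extract_corresponding_slice)
from .transforms import (RigidStage, ScaleStage, SpaceInfo, TransformChain,
                         apply_transform)

__all__ = ["PipelineConfig", "PhantomOptions", "BlockfaceOptions",
           "simulate_phantom", "run_pipeline", "PipelineError"]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "reconstruct", "register3d", "extract", "register2d",
          "evaluate")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PhantomOptions:
    """Study conditions for the synthetic specimen."""

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 0.1
    n_vessels: int = 2
    mri_noise_sd: float = 1.0
    mri_bias_amplitude: float = 0.02
    # blockface distortions (the defaults are "on")
    perspective_x_scale: float = 0.85
    perspective_shear_deg: float = 2.0
    vertical_jitter_sd_mm: float = 0.05
    line_gain_amplitude: float = 0.15
    line_gain_correlation_px: float = 1.0
    bias_gradient_amplitude: float = 0.10
    depth_weights: tuple[float, ...] = ()
    blockface_noise_sd: float = 1.0
    # histology
    n_histology_sections: int = 6
    histology_displacement_mm: float = 0.15
    histology_smoothness_mm: float = 1.2
    histology_noise_sd: float = 1.0
    # known MRI misalignment the 3-D registration must undo
    misalign_angles_deg: tuple[float, float, float] = (2.0, -1.5, 3.0)
    misalign_translation_mm: tuple[float, float, float] = (0.3, -0.25, 0.2)
    misalign_scale: float = 1.03
    # calibration grid (phantom-sized)
    grid_dot_spacing_mm: float = 0.6
    grid_extent: tuple[int, int] = (8, 8)

    def distortion_spec(self, seed: int) -> DistortionSpec:
        s = self.perspective_x_scale
        sh = np.tan(np.deg2rad(self.perspective_shear_deg))
        affine = np.array([[s, sh, 0.0], [0.0, 1.0, 0.0]])
        return DistortionSpec(
            perspective_affine=affine,
            vertical_jitter_sd_mm=self.vertical_jitter_sd_mm,
            line_gain_amplitude=self.line_gain_amplitude,
            line_gain_correlation_px=self.line_gain_correlation_px,
            bias_gradient_amplitude=self.bias_gradient_amplitude,
            depth_weights=self.depth_weights,
            noise_sd=self.blockface_noise_sd,
            seed=seed,
        )

    def histology_spec(self, seed: int) -> HistologyDeformationSpec:
        return HistologyDeformationSpec(
            displacement_amplitude_mm=self.histology_displacement_mm,
            smoothness_mm=self.histology_smoothness_mm,
            noise_sd=self.histology_noise_sd,
            seed=seed,
        )


@dataclass
class BlockfaceOptions:
    technique: str = "A"
    window_cols: int = 15
    band_halfwidth_bins: int = 1
    center_exclusion_bins: int = 3
    median_kernel: tuple[int, int, int] = (3, 3, 3)
    max_shift_mm: float = 0.5
    excluded_indices: tuple[int, ...] = ()
    crop_box_mm: tuple[float, float, float, float] | None = None
    target_pixel_mm: float | None = None


@dataclass
class PipelineConfig:
    """Everything a run needs; validated up front and copied to the output
    directory for provenance."""

    out_dir: str = "bbq_out"
    seed: int = 0
    phantom: PhantomOptions = field(default_factory=PhantomOptions)
    blockface: BlockfaceOptions = field(default_factory=BlockfaceOptions)
    reg3d: RegistrationConfig = field(default_factory=RegistrationConfig)
    reg2d: RegistrationConfig = field(default_factory=RegistrationConfig.default_2d)
    histology_fill: str = "linear"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.integer, np.floating)):
                return obj.item()
            return obj

        return clean(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kw = dict(raw)
        for key, sub in (("phantom", PhantomOptions),
                         ("blockface", BlockfaceOptions),
                         ("reg3d", RegistrationConfig),
                         ("reg2d", RegistrationConfig)):
            if key in kw and isinstance(kw[key], dict):
                sub_kw = {k: tuple(v) if isinstance(v, list) else v
                          for k, v in kw[key].items()}
                kw[key] = sub(**sub_kw)
        return cls(**kw)


def _identity_resample(labels: LabelMap, target: SpaceInfo) -> LabelMap:
    """Nearest-neighbour resample of a label map onto another grid (no
    geometric change beyond the grid)."""
    chain = TransformChain(target.ndim, [], fixed_space=target,
                           moving_space=SpaceInfo.of(labels))
    return apply_transform(labels, chain, interpolation="nearest")


def _misalignment_chain(opts: PhantomOptions, space: SpaceInfo) -> TransformChain:
    center = space.center()
    rigid = RigidStage(3, np.deg2rad(np.array(opts.misalign_angles_deg)),
                       np.array(opts.misalign_translation_mm), center)
    scale = ScaleStage(3, opts.misalign_scale, center)
    return TransformChain(3, [rigid, scale], fixed_space=space,
                          moving_space=space)


def simulate_phantom(config: PipelineConfig, write_to=None) -> dict:
    """Generate the synthetic specimen and every derived acquisition.

    Returns a dict of in-memory artifacts; with ``write_to`` set, the on-disk
    artifacts (MRI, labels, raw blockface stack, calibration grid) are written
    there as well.
    """
    seed = int(config.seed)
    po = config.phantom
    scene = make_phantom(po.shape, po.voxel_size_mm, po.n_vessels, seed)
    scene_labels = scene.label_map()
    mri, mri_gt = render_mri(scene, MRI_INTENSITY, po.mri_noise_sd,
                             seed + 3, po.mri_bias_amplitude)
    dist_spec = po.distortion_spec(seed + 1)
    stack, bf_gt = render_blockface_stack(scene, dist_spec, BLOCKFACE_INTENSITY)
    grid_img, grid_gt = render_calibration_grid(
        dist_spec, po.grid_dot_spacing_mm, po.grid_extent,
        pixel_size_mm=po.voxel_size_mm, dot_sigma_px=1.2)
    nz = scene.shape[2]
    hist_idx = sorted(set(np.linspace(nz // 6, nz - nz // 6 - 1,
                                      po.n_histology_sections).astype(int)
                          .tolist()))
    hist_spec = po.histology_spec(seed + 2)
    sections, hist_gt = render_histology_sections(scene, hist_idx, hist_spec)

    # misalign the MRI (and its labels) by a known transform, standing in
    # for the arbitrary orientation a real specimen scan arrives in
    mis = _misalignment_chain(po, SpaceInfo.of(mri))
    mri_moving = apply_transform(mri, mis)
    labels_moving = apply_transform(scene_labels, mis, interpolation="nearest")

    if write_to is not None:
        out = Path(write_to)
        out.mkdir(parents=True, exist_ok=True)
        bbq_io.write_volume(mri_moving, out / "mri.nii.gz")
        bbq_io.write_labels(labels_moving, out / "mri_labels.nii.gz")
        bbq_io.write_labels(scene_labels, out / "scene_labels.nii.gz")
        bbq_io.write_stack(stack, out / "blockface_raw")
        bbq_io.write_image2d(grid_img, out / "calibration_grid.tif")
        for sec in sections:
            bbq_io.write_image2d(sec, out / f"histology_{sec.section_index:05d}.tif")

    return {"scene": scene, "scene_labels": scene_labels,
            "mri": mri, "mri_gt": mri_gt,
            "mri_moving": mri_moving, "labels_moving": labels_moving,
            "misalignment": mis,
            "stack": stack, "blockface_gt": bf_gt,
            "grid_image": grid_img, "grid_gt": grid_gt,
            "sections": sections, "histology_gt": hist_gt,
            "histology_indices": hist_idx}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline on a synthetic specimen; returns the run
    manifest (also written to ``out_dir/manifest.json``).

    Any stage failure raises :class:`PipelineError` naming the stage; partial
    outputs already written are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    config.save(out / "config.yaml")
    manifest = {"seed": config.seed, "config_hash": config.config_hash(),
                "stages_complete": [], "objectives": {}}
    seed = int(config.seed)
    po = config.phantom

    stage = "simulate"
    try:
        sim = simulate_phantom(config, write_to=out)
        scene = sim["scene"]
        scene_labels = sim["scene_labels"]
        stack = sim["stack"]
        grid_img = sim["grid_image"]
        sections = sim["sections"]
        hist_gt = sim["histology_gt"]
        hist_idx = sim["histology_indices"]
        mri_moving = sim["mri_moving"]
        labels_moving = sim["labels_moving"]
        manifest["stages_complete"].append(stage)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "reconstruct"
    try:
        points = detect_grid_points(grid_img)
        cal = estimate_calibration(points, po.grid_dot_spacing_mm)
        with open(out / "calibration.json", "w") as fh:
            json.dump(cal.to_dict(), fh)
        log: list[str] = []
        bo = config.blockface
        bf_volume, bf_stack = reconstruct(
            stack, calibration=cal, excluded_indices=bo.excluded_indices,
            max_shift_mm=bo.max_shift_mm, crop_box_mm=bo.crop_box_mm,
            target_pixel_mm=bo.target_pixel_mm, technique=bo.technique,
            window_cols=bo.window_cols,
            band_halfwidth_bins=bo.band_halfwidth_bins,
            center_exclusion_bins=bo.center_exclusion_bins,
            median_kernel=bo.median_kernel, log=log)
        bbq_io.write_volume(bf_volume, out / "blockface_volume.nii.gz")
        pd.DataFrame({
            "section_index": bf_stack.section_indices,
            "vertical_offset_mm": bf_stack.vertical_offsets_mm,
            "excluded": bf_stack.excluded,
        }).to_csv(out / "blockface_offsets.csv", index=False)
        manifest["reconstruct_log"] = log
        manifest["stages_complete"].append(stage)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "register3d"
    try:
        chain3d = register(bf_volume, mri_moving, config.reg3d)
        chain3d.save(out / "chain3d.json")
        manifest["objectives"]["register3d"] = [
            [n, float(c)] for n, c in chain3d.stage_objectives]
        mri_in_bf = apply_transform(mri_moving, chain3d)
        bbq_io.write_volume(mri_in_bf, out / "mri_in_blockface.nii.gz")
        manifest["stages_complete"].append(stage)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "extract"
    try:
        mri_slices = {k: extract_corresponding_slice(mri_in_bf, bf_stack, k)
                      for k in hist_idx}
        for k, img in mri_slices.items():
            bbq_io.write_image2d(img, out / f"mri_slice_{k:05d}.tif")
        manifest["stages_complete"].append(stage)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "register2d"
    try:
        chains2d = {}
        registered_sections = []
        for sec in sections:
            k = sec.section_index
            chain2d = register_2d(mri_slices[k], sec, config.reg2d)
            chains2d[k] = chain2d
            chain2d.save(out / f"chain2d_{k:05d}.json")
            reg_sec = apply_transform(sec, chain2d)
            reg_sec.section_index = k
            registered_sections.append(reg_sec)
            bbq_io.write_image2d(reg_sec, out / f"histology_in_mri_{k:05d}.tif")
        manifest["stages_complete"].append(stage)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "evaluate"
    try:
        bf_space = SpaceInfo.of(bf_volume)
        fixed_labels_bf = _identity_resample(scene_labels, bf_space)
        report3d = evaluate_registration(fixed_labels_bf, labels_moving,
                                         chain3d)
        frame3d = report3d.to_frame()
        frame3d.insert(0, "comparison", "mri_vs_blockface_3d")

        # per-section scores compare the registered MRI's labels at each
        # section plane against the registered histology labels — the 2-D
        # analog of the 3-D MRI-vs-blockface comparison
        mri_labels_bf = apply_transform(labels_moving, chain3d,
                                        interpolation="nearest")
        rows_2d = []
        for sec in sections:
            k = sec.section_index
            fixed2d = LabelMap(mri_labels_bf.labels[:, :, k],
                               bf_space.spacing[:2], bf_space.origin[:2],
                               label_names=LABEL_NAMES)
            # histology-space labels: the scene plane warped exactly like the
            # rendered section was
            from .phantom import _warp_2d  # ground-truth warp utility
            hist_lab = _warp_2d(scene_labels.labels[:, :, k].astype(float),
                                hist_gt.histology_displacements_mm[k],
                                scene.voxel_size_mm, order=0)
            hist_lab = LabelMap(hist_lab.astype(int),
                                (scene.voxel_size_mm,) * 2,
                                label_names=LABEL_NAMES)
            rep = evaluate_registration(fixed2d, hist_lab, chains2d[k])
            f = rep.to_frame()
            f.insert(0, "comparison", f"mri_vs_histology_2d_{k:05d}")
            rows_2d.append(f)

        metrics = pd.concat([frame3d] + rows_2d, ignore_index=True)
        metrics.to_csv(out / "metrics.csv", index=False)

        hist_volume = reconstruct_histology_volume(registered_sections,
                                                   bf_stack,
                                                   fill=config.histology_fill)
        bbq_io.write_volume(hist_volume, out / "histology_volume.nii.gz")
        manifest["whole_tissue_dice_3d"] = float(report3d.whole_tissue_dice)
        manifest["whole_tissue_dice_2d"] = {
            int(sec.section_index): float(pd.concat(rows_2d)
                                          .query("comparison == "
                                                 f"'mri_vs_histology_2d_{sec.section_index:05d}'"
                                                 " and name == 'whole_tissue'")
                                          ["dice"].iloc[0])
            for sec in sections}
        manifest["stages_complete"].append(stage)
    except Exception as exc:
        raise PipelineError(stage, str(exc)) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
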