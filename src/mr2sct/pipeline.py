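"""End-to-end sCT pipeline: body -> air -> brain/CSF -> eyes -> bone ->
soft tissue -> electron-density mapping.

Conflicts between stage masks are resolved by a fixed label precedence
(earlier, more specific stages win)::

    AIR > CORTICAL_BONE > TRABECULAR_BONE > EYE > CSF > BRAIN
        > CONTRAST > FAT > MUSCLE > BACKGROUND

implemented by painting the label grid in reverse precedence order. The
pipeline is fully deterministic: identical inputs and config produce a
byte-identical sCT.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import air_mask as air_mod
from . import bone_seg, brain_csf, ed_mapping, eye_seg, io_formats, soft_tissue_seg
from .config import PipelineConfig
from .io_formats import ContourSet
from .volume_model import IntensityVolume, Label, LabelVolume, TissueStats, compute_region_stats

logger = logging.getLogger(__name__)

#: painting order = reverse precedence (later paints win)
_PAINT_ORDER = (
    Label.MUSCLE,
    Label.FAT,
    Label.CONTRAST,
    Label.BRAIN,
    Label.CSF,
    Label.EYE,
    Label.TRABECULAR_BONE,
    Label.CORTICAL_BONE,
    Label.AIR,
)


@dataclass
class PipelineResult:
    sct: IntensityVolume
    labels: LabelVolume
    masks: dict[str, np.ndarray]
    stats: dict[str, TissueStats]
    report: dict


def _brain_interior(brain0: np.ndarray, spacing, closing_mm: float) -> np.ndarray:
    footprint = brain_csf._ball_footprint(closing_mm, spacing)
    return ndimage.binary_fill_holes(
        ndimage.binary_closing(brain0, structure=footprint)
    )


def run_pipeline(
    mr: IntensityVolume,
    contours: ContourSet,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run all segmentation stages on an MR volume and assemble the sCT."""
    config = config or PipelineConfig()
    report: dict = {"config": config.to_dict(), "stages": {}}
    masks: dict[str, np.ndarray] = {}
    stats: dict[str, TissueStats] = {}
    stage = "air statistics"
    try:
        air_roi = air_mod.interpolate_contours(contours, mr)
        stats["air"] = air_mod.estimate_air_stats(mr, air_roi, config.air)

        stage = "body contour"
        body = soft_tissue_seg.external_body_contour(
            mr, stats["air"], config.soft, air_sigma=config.air.subtract_sigma
        )
        masks["body"] = body

        stage = "air mask"
        masks["air"] = air_mod.build_air_mask(mr, air_roi, stats["air"], config.air) & body

        stage = "white-matter reference"
        ref = brain_csf.find_wm_reference(mr, body, config.brain)
        report["wm_reference"] = {
            "voxel": list(ref.wm_voxel),
            "wm_intensity": ref.wm_intensity,
        }

        stage = "edge detection"
        edges = brain_csf.detect_and_close_edges(mr, ref, config.canny)

        stage = "initial brain"
        brain0 = brain_csf.segment_brain_initial(mr, ref, edges)

        stage = "CSF reference"
        csf_stats, csf_seeds = brain_csf.find_csf_reference(
            mr, brain0, ref, config.csf, stat_lo=config.brain.stat_lo
        )
        stats["csf"] = csf_stats

        stage = "skull mask"
        # nothing inside the (closed) initial brain territory can be skull:
        # narrow CSF channels must stay available for CSF growing
        interior = _brain_interior(brain0, mr.spacing_mm, config.csf.closing_mm)
        skull = brain_csf.build_skull_mask(
            mr, body, brain0, csf_stats, stats["air"], edges,
            config=config.skull, protect=interior,
        )
        skull_grown = skull.grown
        skull_full = skull.mask & ~interior
        masks["skull"] = skull_full

        stage = "CSF segmentation"
        csf = brain_csf.segment_csf(
            mr, csf_stats, skull_full, csf_seeds, sigma=config.csf.sigma
        )
        masks["csf"] = csf

        stage = "final brain"
        brain = brain_csf.segment_brain_final(mr, ref, brain0, csf, skull_full)
        masks["brain"] = brain
        assert not (brain & csf).any()
        assert not (brain & skull_full).any()
        stats["brain"] = compute_region_stats(mr, brain)

        stage = "eye segmentation"
        eyes, eye_components = eye_seg.segment_eyes(mr, brain, ref, config.eye)
        eyes &= ~(brain | csf | masks["air"])
        masks["eyes"] = eyes

        stage = "cortical bone"
        cortical = bone_seg.segment_cortical_bone(
            mr, body, masks["air"], stats["air"], config.bone,
            rim_cm=config.skull.rim_cm,
        )
        cortical &= ~(brain | csf | eyes)
        masks["cortical"] = cortical
        stats["cortical"] = compute_region_stats(mr, cortical)

        stage = "trabecular bone"
        # the cranial interior is brain territory, not diploic space; the
        # grown skull core holds CSF-dark voxels absorbed during skull
        # growing (e.g. the peripheral CSF film) which are no reference;
        # voxels at or below CSF-level intensity are cortical bone, air or
        # CSF the earlier stages missed under noise, never diploe
        low_thr = max(
            stats["air"].mean + config.bone.air_sigma * stats["air"].sd,
            csf_stats.mean + config.skull.csf_sigma * csf_stats.sd,
        )
        trab_exclude = (
            ndimage.binary_fill_holes(brain | csf)
            | eyes | masks["air"] | skull_grown | ~body
            | (mr.data <= low_thr)
        )
        trab_stats, trab_reference = bone_seg.estimate_trabecular_stats(
            mr, cortical, exclude=trab_exclude
        )
        stats["trabecular"] = trab_stats
        trabecular = bone_seg.recover_trabecular_bone(
            mr, cortical, trab_stats, reference=trab_reference,
            exclude=trab_exclude | masks["air"], config=config.bone,
        )
        trabecular &= body & ~(brain | csf | eyes | masks["air"])
        masks["trabecular"] = trabecular

        stage = "soft tissue"
        residual = body & ~(
            masks["air"] | cortical | trabecular | brain | csf | eyes
        )
        slice_stats, soft_global = soft_tissue_seg.per_slice_soft_stats(
            mr, residual, config.soft
        )
        stats["soft"] = soft_global
        soft_labels = soft_tissue_seg.classify_soft_tissue(
            mr, residual, slice_stats, config.soft
        )

        stage = "label assembly"
        label_grid = np.zeros(mr.shape, dtype=np.uint8)
        stage_masks = {
            Label.MUSCLE: soft_labels == int(Label.MUSCLE),
            Label.FAT: soft_labels == int(Label.FAT),
            Label.CONTRAST: soft_labels == int(Label.CONTRAST),
            Label.BRAIN: brain,
            Label.CSF: csf,
            Label.EYE: eyes,
            Label.TRABECULAR_BONE: trabecular,
            Label.CORTICAL_BONE: cortical,
            Label.AIR: masks["air"],
        }
        for label in _PAINT_ORDER:
            label_grid[stage_masks[label]] = int(label)
        # every body voxel must carry a tissue label (partition invariant)
        assert not (body & (label_grid == 0)).any(), "unlabeled body voxels"
        labels = LabelVolume(labels=label_grid, spacing_mm=mr.spacing_mm)

        stage = "electron-density mapping"
        sct = ed_mapping.assemble_sct(mr, labels, stats, config=config.mapping)
    except Exception as err:
        report["failed_stage"] = stage
        report["error"] = str(err)
        logger.error("pipeline failed at stage %r: %s", stage, err)
        raise PipelineError(stage, err, report) from err

    report["stages"] = {
        name: int(np.asarray(m).sum()) for name, m in masks.items()
    }
    report["tissue_stats"] = {
        name: {"mean": s.mean, "sd": s.sd, "min": s.min, "n": s.n}
        for name, s in stats.items()
    }
    report["eyes"] = [
        {"side": c.side, "volume_cm3": c.volume_cm3} for c in eye_components
    ]
    return PipelineResult(sct=sct, labels=labels, masks=masks, stats=stats, report=report)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the partial report."""

    def __init__(self, stage: str, cause: Exception, report: dict):
        super().__init__(f"pipeline failed at stage {stage!r}: {cause}")
        self.stage = stage
        self.report = report


def run_pipeline_files(
    mr_path, contours_path, output_dir, config: PipelineConfig | None = None
) -> PipelineResult:
    """File-based entry point: read inputs, run, write sCT + labels + report."""
    os.makedirs(output_dir, exist_ok=True)
    mr = io_formats.read_volume(mr_path, modality="MR")
    if not os.path.exists(contours_path):
        raise FileNotFoundError(
            f"air contour file not found: {contours_path} — the air stage "
            "needs manual air contours (JSON or RTSTRUCT)"
        )
    contours = io_formats.read_air_contours(contours_path, mr)
    try:
        result = run_pipeline(mr, contours, config)
    except PipelineError as err:
        manifest = {"status": "failed", **err.report}
        with open(os.path.join(output_dir, "MANIFEST.json"), "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise
    io_formats.write_sct(result.sct, os.path.join(output_dir, "sct.nii"))
    io_formats.write_labels(result.labels, os.path.join(output_dir, "labels.nii"))
    with open(os.path.join(output_dir, "report.json"), "w") as fh:
        json.dump({"status": "ok", **result.report}, fh, indent=2)
    with open(os.path.join(output_dir, "MANIFEST.json"), "w") as fh:
        json.dump(
            {"status": "ok", "outputs": ["sct.nii", "labels.nii", "report.json"]},
            fh, indent=2,
        )
    return result
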