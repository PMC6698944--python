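"""Geometric and electron-density evaluation of a synthetic CT against CT.

* external-skull contour distance: on the axial / coronal / sagittal slice
  with the largest bone width, the directed mean distance (mm) from each
  sCT external bone-contour voxel to the nearest CT contour voxel
  (bone = HU >= 200);
* Dice similarity coefficient 2|A n B| / (|A| + |B|);
* ME = mean(CT - sCT) and MAE = mean|CT - sCT| over a region;
* standard evaluation regions: whole body (> -400 HU in both volumes),
  air (< -800 HU in both), soft tissue (CT in [-100, 200) HU inside the
  body) and bone (CT >= 200 HU).
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .volume_model import IntensityVolume, Label, LabelVolume

BONE_HU = 200.0
BODY_HU = -400.0
AIR_HU = -800.0

#: (name, slice axis, (in-plane axes), horizontal in-plane axis)
_VIEWS = (
    ("axial", 0, (1, 2), 2),
    ("coronal", 1, (0, 2), 2),
    ("sagittal", 2, (0, 1), 1),
)


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice similarity coefficient; two empty masks count as identical (1.0)."""
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.shape != mask_b.shape:
        raise ValueError("mask shapes differ")
    denom = int(mask_a.sum()) + int(mask_b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((mask_a & mask_b).sum()) / denom


def ed_errors(
    sct: IntensityVolume, ct: IntensityVolume, region: np.ndarray
) -> tuple[float, float]:
    """Mean error and mean absolute error (HU), CT minus sCT, over a region."""
    region = np.asarray(region, dtype=bool)
    if sct.shape != ct.shape or region.shape != ct.shape:
        raise ValueError("volumes and region must share a grid")
    if not region.any():
        raise ValueError("empty region")
    diff = ct.data[region].astype(np.float64) - sct.data[region].astype(np.float64)
    me = float(diff.mean())
    mae = float(np.abs(diff).mean())
    assert mae >= abs(me) - 1e-12
    return me, mae


def _largest_component_2d(mask2d: np.ndarray) -> np.ndarray:
    labeled, n = ndimage.label(mask2d)
    if n == 0:
        return mask2d
    largest = int(np.argmax(np.bincount(labeled.ravel())[1:])) + 1
    return labeled == largest


def _external_contour_2d(mask2d: np.ndarray) -> np.ndarray:
    """Outer boundary of the largest component (holes filled first)."""
    comp = ndimage.binary_fill_holes(_largest_component_2d(mask2d))
    eroded = ndimage.binary_erosion(
        comp, structure=ndimage.generate_binary_structure(2, 1)
    )
    return comp & ~eroded


def _bone_width(mask2d: np.ndarray, horiz: int) -> int:
    if not mask2d.any():
        return 0
    proj = mask2d.any(axis=1 - horiz)
    idx = np.flatnonzero(proj)
    return int(idx[-1] - idx[0] + 1)


def external_bone_contour_distance(
    sct: IntensityVolume, ct: IntensityVolume, bone_hu: float = BONE_HU
) -> dict[str, float]:
    """Directed sCT -> CT external bone contour distances (mm).

    For each view, each volume contributes the slice maximising its own
    bone mask's in-plane width along the view's horizontal axis (the two
    scans may be shifted against each other, so a shared slice index is
    not meaningful); on those slices the external contour of the largest
    bone component is extracted and each sCT contour voxel contributes its
    in-plane distance to the nearest CT contour voxel. Returns per-view
    means and their average under ``"mean"``. The measure is directed
    (sCT to CT), matching how the skull-contour agreement is reported
    clinically.
    """
    if sct.shape != ct.shape:
        raise ValueError("sCT and CT must share a grid")
    bone_s = sct.data >= bone_hu
    bone_c = ct.data >= bone_hu
    if not bone_s.any() or not bone_c.any():
        raise ValueError("no bone voxels above threshold")
    spacing = np.asarray(sct.spacing_mm)

    def widest(bone, axis, horiz_local):
        widths = [
            _bone_width(bone.take(idx, axis=axis), horiz_local)
            for idx in range(bone.shape[axis])
        ]
        return int(np.argmax(widths))

    out: dict[str, float] = {}
    for name, axis, inplane, horiz in _VIEWS:
        horiz_local = inplane.index(horiz)
        s_slice = bone_s.take(widest(bone_s, axis, horiz_local), axis=axis)
        c_slice = bone_c.take(widest(bone_c, axis, horiz_local), axis=axis)
        if not s_slice.any() or not c_slice.any():
            raise ValueError(f"no bone on the selected {name} slice")
        contour_s = np.argwhere(_external_contour_2d(s_slice)).astype(float)
        contour_c = np.argwhere(_external_contour_2d(c_slice)).astype(float)
        scale = spacing[list(inplane)]
        tree = cKDTree(contour_c * scale)
        dists, _ = tree.query(contour_s * scale)
        out[name] = float(np.mean(dists))
    out["mean"] = float(np.mean([out[n] for n, *_ in _VIEWS]))
    return out


def build_eval_regions(
    sct: IntensityVolume,
    ct: IntensityVolume,
    labels: LabelVolume | None = None,
) -> dict[str, np.ndarray]:
    """Named evaluation regions on the common grid.

    ``whole_body`` is the overlap of the two > -400 HU body masks; ``air``
    requires < -800 HU in *both* volumes (patient setup moves air
    cavities); ``soft_tissue`` is CT in [-100, 200) HU inside the body;
    ``bone`` is CT >= 200 HU (the 200 HU boundary belongs to bone). With a
    label map, per-tissue regions from the sCT segmentation restricted to
    the body overlap are added as ``label:<name>``.
    """
    if sct.shape != ct.shape:
        raise ValueError("sCT and CT must share a grid")
    body = (sct.data > BODY_HU) & (ct.data > BODY_HU)
    if not body.any():
        raise ValueError("empty whole-body overlap")
    regions = {
        "whole_body": body,
        "air": (sct.data < AIR_HU) & (ct.data < AIR_HU),
        "soft_tissue": body & (ct.data >= -100.0) & (ct.data < BONE_HU),
        "bone": ct.data >= BONE_HU,
    }
    if labels is not None:
        for label in (Label.BRAIN, Label.MUSCLE, Label.FAT,
                      Label.CORTICAL_BONE, Label.TRABECULAR_BONE):
            regions[f"label:{label.name.lower()}"] = labels.mask(label) & body
    return regions


@dataclass
class EvaluationReport:
    contour_distance_mm: dict[str, float]
    dice: dict[str, float]
    ed_errors: dict[str, dict[str, float]]

    def to_dict(self) -> dict:
        return {
            "contour_distance_mm": self.contour_distance_mm,
            "dice": self.dice,
            "ed_errors": self.ed_errors,
        }


def evaluate(
    sct: IntensityVolume,
    ct: IntensityVolume,
    labels: LabelVolume | None = None,
) -> EvaluationReport:
    """Full metric set: contour distances, bone Dice, per-region ME/MAE."""
    regions = build_eval_regions(sct, ct, labels)
    errors = {}
    for name, region in regions.items():
        if region.any():
            me, mae = ed_errors(sct, ct, region)
            errors[name] = {"me_hu": me, "mae_hu": mae, "n_voxels": int(region.sum())}
    dices = {"bone": dice(sct.data >= BONE_HU, ct.data >= BONE_HU)}
    return EvaluationReport(
        contour_distance_mm=external_bone_contour_distance(sct, ct),
        dice=dices,
        ed_errors=errors,
    )


def write_report(report: EvaluationReport, json_path, csv_path=None) -> None:
    with open(json_path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    if csv_path is not None:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["region", "me_hu", "mae_hu", "n_voxels"])
            for name, vals in report.ed_errors.items():
                writer.writerow([name, vals["me_hu"], vals["mae_hu"], vals["n_voxels"]])
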