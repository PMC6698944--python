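"""Eye detection by intensity, location, size and sphericity rules.

Eyes are darker than brain on contrast-enhanced T1 images and sit in the
anterior hemisphere of the head. The detector thresholds below
``0.7 x wmIntensity`` inside an anatomical search box around the widest
anterior-posterior brain slice and filters connected components by
midline contact, volume (relative to a 4 cm diameter typical eye) and an
axis-extent sphericity rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .brain_csf import BrainReference
from .config import EyeConfig
from .volume_model import IntensityVolume, connected_components

logger = logging.getLogger(__name__)


@dataclass
class EyeComponent:
    """A detected eye candidate."""

    side: str  # "left" or "right"
    mask: np.ndarray
    volume_cm3: float
    extents_mm: tuple[float, float, float]

    @property
    def extent_spread_mm(self) -> float:
        return max(self.extents_mm) - min(self.extents_mm)


def _widest_ap_slice(brain: np.ndarray) -> int:
    """Axial slice index where the brain's anterior-posterior width peaks."""
    any_row = brain.any(axis=2)  # (k, row)
    rows = np.arange(brain.shape[1])
    first = np.where(any_row, rows[None, :], brain.shape[1]).min(axis=1)
    last = np.where(any_row, rows[None, :], -1).max(axis=1)
    width = np.where(last >= first, last - first + 1, 0)
    return int(np.argmax(width))


def segment_eyes(
    volume: IntensityVolume,
    brain: np.ndarray,
    ref: BrainReference,
    config: EyeConfig | None = None,
) -> tuple[np.ndarray, list[EyeComponent]]:
    """Detect left and right eyes; returns (mask, components).

    The search box spans ``box_sup_cm`` superior to ``box_inf_cm`` inferior
    of the widest-AP brain slice and the anterior hemisphere (rows anterior
    of the brain centroid). Components below ``0.7 x wmIntensity`` are
    rejected when they touch a 3-voxel mid-sagittal slab, when their volume
    is outside [1/2, 2] x the volume of a ``diameter_cm`` sphere, or when
    their axis-aligned extents differ by more than ``sphericity_cm``.
    Survivors are labelled left/right by their position relative to the
    brain midline. More than two survivors keeps the two most spherical
    (with a warning); zero survivors returns an empty mask (with a warning).
    """
    config = config or EyeConfig()
    brain = np.asarray(brain, dtype=bool)
    if not brain.any():
        raise ValueError("brain mask is empty")
    dz, dy, dx = volume.spacing_mm

    k_wide = _widest_ap_slice(brain)
    k_lo = max(0, k_wide - int(round(config.box_inf_cm * 10.0 / dz)))
    k_hi = min(volume.shape[0], k_wide + int(round(config.box_sup_cm * 10.0 / dz)) + 1)
    centroid = ndimage.center_of_mass(brain)
    row_mid = int(round(centroid[1]))
    col_mid = int(round(centroid[2]))

    box = np.zeros(volume.shape, dtype=bool)
    box[k_lo:k_hi, row_mid:, :] = True  # anterior hemisphere
    dark = box & (volume.data < config.threshold_coeff * ref.wm_intensity)

    labeled, sizes = connected_components(dark, connectivity=6)
    voxel_cm3 = volume.voxel_volume_mm3() / 1000.0
    typical_cm3 = (math.pi / 6.0) * config.diameter_cm**3
    if config.size_rule == "volume":
        vol_lo, vol_hi = 0.5 * typical_cm3, 2.0 * typical_cm3
    elif config.size_rule == "diameter":
        vol_lo = (math.pi / 6.0) * (config.diameter_cm / 2.0) ** 3
        vol_hi = (math.pi / 6.0) * (config.diameter_cm * 2.0) ** 3
    else:
        raise ValueError(f"unknown eye size rule {config.size_rule!r}")

    slab = slice(max(0, col_mid - 1), col_mid + 2)  # 3-voxel mid-sagittal slab
    midline_ids = set(np.unique(labeled[:, :, slab]).tolist())
    survivors: list[EyeComponent] = []
    objects = ndimage.find_objects(labeled)
    for comp_id, size in sizes.items():
        vol_cm3 = size * voxel_cm3
        if not vol_lo <= vol_cm3 <= vol_hi:
            continue
        sl = objects[comp_id - 1]
        comp_local = labeled[sl] == comp_id
        if comp_id in midline_ids:
            continue
        extents = tuple(
            (s.stop - s.start) * sp for s, sp in zip(sl, (dz, dy, dx))
        )
        if max(extents) - min(extents) > config.sphericity_cm * 10.0:
            continue
        mask = np.zeros(volume.shape, dtype=bool)
        mask[sl] = comp_local
        col_center = ndimage.center_of_mass(comp_local)[2] + sl[2].start
        side = "left" if col_center > col_mid else "right"
        survivors.append(
            EyeComponent(side=side, mask=mask, volume_cm3=vol_cm3, extents_mm=extents)
        )

    if len(survivors) > 2:
        logger.warning(
            "%d eye candidates survived filtering; keeping the two most spherical",
            len(survivors),
        )
        survivors.sort(key=lambda c: c.extent_spread_mm)
        survivors = survivors[:2]
    if not survivors:
        logger.warning("no eye candidates survived filtering")
        return np.zeros(volume.shape, dtype=bool), []

    eye_mask = np.zeros(volume.shape, dtype=bool)
    for comp in survivors:
        eye_mask |= comp.mask
    return eye_mask, survivors
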