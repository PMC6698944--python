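"""Cortical and trabecular bone segmentation.

Cortical bone shares the air noise floor on T1-weighted images, so it is
grown from the skull rim seeds with the air intensity window, inside the
body and excluding the manually contoured air. Trabecular (spongy) bone
overlaps brain and fat in intensity; its reference statistics come from
cavities enclosed in the cortical mask, and further trabecular voxels are
recovered in a small neighbourhood of cortical bone within mu +/- 2 sigma.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .brain_csf import skull_seed_mask
from .config import BoneConfig, SkullConfig
from .volume_model import IntensityVolume, IntensityWindow, TissueStats, region_grow


def segment_cortical_bone(
    volume: IntensityVolume,
    body: np.ndarray,
    air_mask: np.ndarray,
    air_stats: TissueStats,
    config: BoneConfig | None = None,
    rim_cm: float = 1.0,
) -> np.ndarray:
    """Region growing with the air intensity window from the skull rim seeds."""
    config = config or BoneConfig()
    body = np.asarray(body, dtype=bool)
    air_mask = np.asarray(air_mask, dtype=bool)
    window = IntensityWindow(0.0, air_stats.mean + config.air_sigma * air_stats.sd)
    barrier = ~body | air_mask
    seeds = skull_seed_mask(
        volume, body, air_stats,
        SkullConfig(rim_cm=rim_cm, air_sigma=config.air_sigma),
    )
    seeds &= ~barrier & (volume.data >= window.lo) & (volume.data <= window.hi)
    if not seeds.any():
        raise ValueError("no skull seed voxels for bone growing")
    return region_grow(volume, seeds, window, barrier=barrier, connectivity=6)


def _fill_2d_slices(mask: np.ndarray) -> np.ndarray:
    out = np.zeros_like(mask)
    for k in range(mask.shape[0]):
        if mask[k].any():
            out[k] = ndimage.binary_fill_holes(mask[k])
    return out


def enclosed_cavities(
    cortical: np.ndarray, exclude: np.ndarray | None = None
) -> np.ndarray:
    """Non-cortical voxels enclosed by the cortical mask.

    A voxel counts as enclosed when it is unreachable from the volume
    border without crossing cortical bone, either in 3D or within its own
    axial slice (slice-wise enclosure catches the diploic space even where
    a defect breaks the 3D enclosure). ``exclude`` removes voxels already
    claimed by other tissues.
    """
    cortical = np.asarray(cortical, dtype=bool)
    fill3d = ndimage.binary_fill_holes(cortical)
    fill2d = _fill_2d_slices(cortical)
    enclosed = (fill3d | fill2d) & ~cortical
    if exclude is not None:
        enclosed &= ~np.asarray(exclude, dtype=bool)
    return enclosed


def estimate_trabecular_stats(
    volume: IntensityVolume,
    cortical: np.ndarray,
    exclude: np.ndarray | None = None,
    robust: bool = True,
) -> tuple[TissueStats, np.ndarray]:
    """Reference trabecular statistics over cavities enclosed in cortical bone.

    With ``robust`` (default) the statistics are computed after a
    median/MAD trim (values within 4 robust SDs of the median): enclosed
    cavities can contain stray voxels of other tissues (partial-volume
    bone-air interfaces, CSF pockets) that would otherwise inflate the
    spread and make the mu +/- 2 sigma recovery window meaningless.

    Returns the statistics and the trimmed reference voxel mask. Raises
    ``ValueError("no trabecular reference")`` when the cortical mask
    encloses no cavity.
    """
    reference = enclosed_cavities(cortical, exclude)
    if not reference.any():
        raise ValueError("no trabecular reference")
    data = volume.data
    if robust:
        values = data[reference].astype(np.float64)
        med = float(np.median(values))
        sd_hat = 1.4826 * float(np.median(np.abs(values - med)))
        if sd_hat > 0:
            reference = reference & (
                (data >= med - 4.0 * sd_hat) & (data <= med + 4.0 * sd_hat)
            )
    values = data[reference].astype(np.float64)
    stats = TissueStats(
        mean=float(values.mean()),
        sd=float(values.std()),
        min=float(values.min()),
        n=int(values.size),
    )
    return stats, reference


def recover_trabecular_bone(
    volume: IntensityVolume,
    cortical: np.ndarray,
    trab_stats: TissueStats,
    reference: np.ndarray | None = None,
    exclude: np.ndarray | None = None,
    config: BoneConfig | None = None,
) -> np.ndarray:
    """Trabecular bone near cortical bone within mu +/- trab_sigma * sigma.

    Voxels within ``trab_window_mm`` of any cortical voxel whose intensity
    falls in the trabecular window are labelled trabecular (unless
    excluded); the enclosed reference voxels are always included.
    """
    config = config or BoneConfig()
    cortical = np.asarray(cortical, dtype=bool)
    window = trab_stats.window(config.trab_sigma)
    dist = ndimage.distance_transform_edt(~cortical, sampling=volume.spacing_mm)
    near = dist <= config.trab_window_mm
    recovered = (
        near
        & ~cortical
        & (volume.data >= window.lo)
        & (volume.data <= window.hi)
    )
    if exclude is not None:
        recovered &= ~np.asarray(exclude, dtype=bool)
    if reference is not None:
        recovered |= np.asarray(reference, dtype=bool) & ~cortical
    return recovered
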