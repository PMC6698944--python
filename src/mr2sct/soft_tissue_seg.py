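"""External body contour and muscle / fat / contrast classification.

Residual soft tissue (body minus air, bone, brain, CSF and eyes) is split
per voxel using per-axial-slice statistics with adjacent-slice context —
the slice-local statistics absorb the slow intensity drift of the receive
field. With ``min_soft`` the global residual minimum and ``mu, sigma`` the
slice statistics:

* muscle:   min_soft <= I <= mu
* fat:      mu < I <= mu + 2 sigma
* contrast: I > mu + 2 sigma

which partitions the residual exactly (boundary I = mu goes to muscle).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .config import SoftConfig
from .volume_model import IntensityVolume, Label, TissueStats

logger = logging.getLogger(__name__)


def _ball_footprint(radius_mm: float, spacing) -> np.ndarray:
    radii = [max(1, int(round(radius_mm / s))) for s in spacing]
    grids = np.ogrid[tuple(slice(-r, r + 1) for r in radii)]
    return sum((g / r) ** 2 for g, r in zip(grids, radii)) <= 1.0


def external_body_contour(
    volume: IntensityVolume,
    air_stats: TissueStats | None = None,
    config: SoftConfig | None = None,
    air_sigma: float = 3.0,
) -> np.ndarray:
    """Body mask: largest bright component, closed and slice-wise hole-filled.

    MR volumes threshold above ``mu_air + air_sigma * sigma_air`` (requires
    ``air_stats``); CT volumes threshold above -400 HU. Internal cavities
    (sinuses, airway) are filled so the mask is the full head cross-section.
    """
    config = config or SoftConfig()
    if volume.modality == "CT":
        fg = volume.data > -400.0
    else:
        if air_stats is None:
            raise ValueError("air statistics required for an MR body contour")
        fg = volume.data > air_stats.mean + air_sigma * air_stats.sd
    if not fg.any():
        raise ValueError("empty body mask")
    fg = ndimage.binary_closing(
        fg, structure=_ball_footprint(config.body_closing_mm, volume.spacing_mm)
    )
    labeled, n = ndimage.label(fg)
    if n == 0:
        raise ValueError("empty body mask")
    largest = int(np.argmax(np.bincount(labeled.ravel())[1:])) + 1
    body = labeled == largest
    for k in range(body.shape[0]):
        if body[k].any():
            body[k] = ndimage.binary_fill_holes(body[k])
    return body


def per_slice_soft_stats(
    volume: IntensityVolume,
    residual_soft: np.ndarray,
    config: SoftConfig | None = None,
) -> tuple[list[TissueStats], TissueStats]:
    """Per-axial-slice soft-tissue statistics with adjacent-slice context.

    Slice ``k`` pools residual voxels from slices ``k - c .. k + c``
    (``c = context_slices``, clipped at the volume ends). Slices whose
    context holds no residual voxel copy the nearest valid slice's
    statistics (logged). Also returns the global residual statistics,
    whose ``min`` is the global ``min_soft``.
    """
    config = config or SoftConfig()
    residual_soft = np.asarray(residual_soft, dtype=bool)
    if not residual_soft.any():
        raise ValueError("empty region")
    data = volume.data.astype(np.float64, copy=False)
    c = int(config.context_slices)
    nz = volume.shape[0]
    stats: list[TissueStats | None] = []
    for k in range(nz):
        lo, hi = max(0, k - c), min(nz, k + c + 1)
        values = data[lo:hi][residual_soft[lo:hi]]
        if values.size:
            stats.append(
                TissueStats(
                    float(values.mean()), float(values.std()),
                    float(values.min()), int(values.size),
                )
            )
        else:
            stats.append(None)
    valid = [k for k, s in enumerate(stats) if s is not None]
    if len(valid) < nz:
        logger.info(
            "%d axial slices without residual soft tissue; copying nearest stats",
            nz - len(valid),
        )
        valid_arr = np.asarray(valid)
        for k in range(nz):
            if stats[k] is None:
                nearest = valid_arr[np.argmin(np.abs(valid_arr - k))]
                stats[k] = stats[nearest]
    all_values = data[residual_soft]
    global_stats = TissueStats(
        float(all_values.mean()), float(all_values.std()),
        float(all_values.min()), int(all_values.size),
    )
    return stats, global_stats


def classify_soft_tissue(
    volume: IntensityVolume,
    residual_soft: np.ndarray,
    slice_stats: list[TissueStats],
    config: SoftConfig | None = None,
) -> np.ndarray:
    """Label every residual voxel MUSCLE, FAT or CONTRAST (exact partition)."""
    config = config or SoftConfig()
    residual_soft = np.asarray(residual_soft, dtype=bool)
    if len(slice_stats) != volume.shape[0]:
        raise ValueError("need one TissueStats per axial slice")
    mu = np.asarray([s.mean for s in slice_stats])[:, None, None]
    sd = np.asarray([s.sd for s in slice_stats])[:, None, None]
    fat_hi = mu + config.fat_sigma * sd
    data = volume.data
    labels = np.zeros(volume.shape, dtype=np.uint8)
    labels[residual_soft & (data <= mu)] = int(Label.MUSCLE)
    labels[residual_soft & (data > mu) & (data <= fat_hi)] = int(Label.FAT)
    labels[residual_soft & (data > fat_hi)] = int(Label.CONTRAST)
    return labels
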