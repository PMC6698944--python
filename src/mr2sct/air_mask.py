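"""Air mask from sparse manual contours.

Air and cortical bone are indistinguishable by intensity on T1-weighted
images, so the air cavities (sinuses, airway) are outlined manually on a
handful of axial slices. This module turns those sparse outlines into a 3D
air region (shape-based interpolation of signed distance transforms),
estimates the MR noise-floor statistics of air, and removes any soft
tissue enclosed in the outlined region by thresholding at
``mu_air + k * sigma_air``.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .config import AirConfig
from .io_formats import ContourSet
from .volume_model import IntensityVolume, TissueStats


def _signed_distance(mask: np.ndarray, spacing) -> np.ndarray:
    """Positive inside the mask, negative outside (mm)."""
    if mask.any():
        inside = ndimage.distance_transform_edt(mask, sampling=spacing)
        outside = ndimage.distance_transform_edt(~mask, sampling=spacing)
        return inside - outside
    return np.full(mask.shape, -np.inf)


def interpolate_contours(contours: ContourSet, frame: IntensityVolume) -> np.ndarray:
    """Rasterize the contoured slices and fill the slices in between.

    Contoured slices are rasterized exactly; a slice between two contoured
    slices gets the zero level set of the linearly interpolated signed
    distance transforms of its two neighbours. Slices outside the contoured
    span stay empty.
    """
    if not contours.contours:
        raise ValueError("contour set is empty")
    roi = np.zeros(frame.shape, dtype=bool)
    ks = contours.slice_indices()
    rasterized = {k: contours.rasterize_slice(k) for k in ks}
    for k in ks:
        roi[k] = rasterized[k]
    spacing2d = frame.spacing_mm[1:]
    for k0, k1 in zip(ks[:-1], ks[1:]):
        if k1 - k0 < 2:
            continue
        phi0 = _signed_distance(rasterized[k0], spacing2d)
        phi1 = _signed_distance(rasterized[k1], spacing2d)
        for k in range(k0 + 1, k1):
            t = (k - k0) / (k1 - k0)
            roi[k] = ((1.0 - t) * phi0 + t * phi1) > 0
    return roi


def estimate_air_stats(
    volume: IntensityVolume, air_roi: np.ndarray, config: AirConfig | None = None
) -> TissueStats:
    """Robust air noise-floor statistics over the contoured ROI.

    The contour encloses some mucosa/soft tissue, so plain statistics over
    the ROI would inflate the air mean. The estimator starts from the
    darkest ``stats_fraction`` of ROI voxels and then iteratively refits
    over all ROI voxels below ``mean + refit_sigma * sd`` until the
    selection is stable: for a pure noise floor this converges to the full
    floor statistics, while bright enclosed tissue stays excluded.
    """
    config = config or AirConfig()
    air_roi = np.asarray(air_roi, dtype=bool)
    values = np.asarray(volume.data[air_roi], dtype=np.float64)
    if values.size == 0:
        raise ValueError("empty region")
    values = np.sort(values)
    n0 = max(1, int(round(values.size * config.stats_fraction)))
    selected = values[:n0]
    for _ in range(20):
        cutoff = selected.mean() + config.refit_sigma * selected.std()
        new = values[values <= cutoff]
        if new.size == 0:
            new = selected
        if new.size == selected.size:
            selected = new
            break
        selected = new
    return TissueStats(
        mean=float(selected.mean()),
        sd=float(selected.std()),
        min=float(selected.min()),
        n=int(selected.size),
    )


def build_air_mask(
    volume: IntensityVolume,
    air_roi: np.ndarray,
    air_stats: TissueStats,
    config: AirConfig | None = None,
) -> np.ndarray:
    """Subtract enclosed soft tissue: keep ROI voxels at the air noise floor.

    A voxel of the interpolated ROI is air when its intensity is at most
    ``mu_air + subtract_sigma * sigma_air``; brighter voxels (mucosa, other
    soft tissue inside the outline) are excluded. The mask is therefore
    always a subset of the ROI.
    """
    config = config or AirConfig()
    air_roi = np.asarray(air_roi, dtype=bool)
    threshold = air_stats.mean + config.subtract_sigma * air_stats.sd
    return air_roi & (volume.data <= threshold)
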