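"""Automated brain and CSF segmentation.

The chain is anchored on a white-matter reference found by an intensity
uniformity search (U = mean/SD in a 1 cm x 1 cm in-plane window on the
middle coronal slice). Every subsequent intensity window is expressed
relative to the reference intensity ``wmIntensity``, which makes the whole
chain invariant to a global rescaling of the MR intensities:

* statistical brain range  [0.53, 1.35] x wmIntensity,
* initial brain growing    [0.70, 1.20] x wmIntensity,
* CSF reference            max-uniformity 5 mm window below 0.53 x wmIntensity,
* skull seeds              [0, mu_air + 3 sigma_air] within 1 cm of the body
  surface, grown with [0, mu_csf + 2 sigma_csf],
* final brain              growing with the statistical range, barred by the
  skull mask.

Canny edges (per axial and sagittal slice, after zeroing intensities
outside the statistical brain range) are closed with discrete straight
segments and act as leak barriers for the region growing steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.draw import line as draw_line
from skimage.feature import canny
from skimage.morphology import skeletonize

from .config import BrainConfig, CannyConfig, CsfConfig, SkullConfig
from .volume_model import (
    IntensityVolume,
    IntensityWindow,
    TissueStats,
    region_grow,
    window_mm_to_voxels,
)


@dataclass
class BrainReference:
    """White-matter reference voxel and the brain windows derived from it."""

    wm_voxel: tuple[int, int, int]
    wm_intensity: float
    window_stat: IntensityWindow
    window_grow: IntensityWindow


def _ball_footprint(radius_mm: float, spacing) -> np.ndarray:
    """Ellipsoidal structuring element with a physical radius."""
    radii = [max(1, int(round(radius_mm / s))) for s in spacing]
    grids = np.ogrid[tuple(slice(-r, r + 1) for r in radii)]
    dist = sum((g / r) ** 2 for g, r in zip(grids, radii))
    return dist <= 1.0


def _local_mean_sd(plane: np.ndarray, size) -> tuple[np.ndarray, np.ndarray]:
    plane = plane.astype(np.float64, copy=False)
    m = ndimage.uniform_filter(plane, size=size)
    m2 = ndimage.uniform_filter(plane * plane, size=size)
    var = np.maximum(m2 - m * m, 0.0)
    sd = np.sqrt(var)
    # exactly constant windows must rank as perfectly uniform
    const = ndimage.maximum_filter(plane, size=size) == ndimage.minimum_filter(
        plane, size=size
    )
    sd[const] = 0.0
    return m, sd


def _uniformity(mean: np.ndarray, sd: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        u = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.inf)
    return u


def find_wm_reference(
    volume: IntensityVolume,
    body: np.ndarray,
    config: BrainConfig | None = None,
) -> BrainReference:
    """Locate the white-matter reference voxel on the middle coronal slice.

    Candidate centers are body voxels whose intensity is at least the
    slice's median body intensity (air and CSF are dark but can be just as
    uniform as white matter) and whose full in-plane window fits in the
    grid. The center with the largest uniformity wins; ties are broken by
    the larger window mean, then the lowest (k, col) index.
    """
    config = config or BrainConfig()
    body = np.asarray(body, dtype=bool)
    row = volume.shape[1] // 2
    plane = volume.data[:, row, :].astype(np.float64)
    body_sl = body[:, row, :]
    if not body_sl.any():
        raise ValueError("body mask empty on the middle coronal slice")

    dz, _, dx = volume.spacing_mm
    wz, _, wx = window_mm_to_voxels(
        (config.uniformity_window_mm, 0.0, config.uniformity_window_mm),
        volume.spacing_mm,
    )
    mean, sd = _local_mean_sd(plane, (wz, wx))
    u = _uniformity(mean, sd)

    median = float(np.median(plane[body_sl]))
    candidates = body_sl & (plane >= median)
    hz, hx = wz // 2, wx // 2
    inset = np.zeros_like(candidates)
    if plane.shape[0] > 2 * hz and plane.shape[1] > 2 * hx:
        inset[hz : plane.shape[0] - hz, hx : plane.shape[1] - hx] = True
    candidates &= inset
    if not candidates.any():
        raise ValueError("no candidate voxels for the white-matter search")

    u_c = np.where(candidates, u, -np.inf)
    best_u = u_c.max()
    tied = candidates & (u_c == best_u)
    mean_c = np.where(tied, mean, -np.inf)
    flat = int(np.argmax(mean_c))  # first (lowest k, col) among max-mean ties
    k, col = np.unravel_index(flat, plane.shape)

    window = plane[
        max(0, k - hz) : k + hz + 1, max(0, col - hx) : col + hx + 1
    ]
    wm_intensity = float(np.mean(window))
    if wm_intensity <= 0:
        raise ValueError("non-positive white-matter reference intensity")
    return BrainReference(
        wm_voxel=(int(k), int(row), int(col)),
        wm_intensity=wm_intensity,
        window_stat=IntensityWindow(
            config.stat_lo * wm_intensity, config.stat_hi * wm_intensity
        ),
        window_grow=IntensityWindow(
            config.grow_lo * wm_intensity, config.grow_hi * wm_intensity
        ),
    )


# ---------------------------------------------------------------------------
# edge detection with gap closing


def _canny_slice(img: np.ndarray, config: CannyConfig) -> np.ndarray:
    if img.size == 0 or img.max() == img.min():
        return np.zeros(img.shape, dtype=bool)
    smoothed = ndimage.gaussian_filter(img, config.sigma, mode="constant")
    grad = np.hypot(
        ndimage.sobel(smoothed, axis=0, mode="constant"),
        ndimage.sobel(smoothed, axis=1, mode="constant"),
    )
    gmax = float(grad.max())
    if gmax <= 0:
        return np.zeros(img.shape, dtype=bool)
    return canny(
        img,
        sigma=config.sigma,
        low_threshold=config.low * gmax,
        high_threshold=config.high * gmax,
    )


def close_edge_gaps_2d(edge: np.ndarray, max_gap_vox: float) -> np.ndarray:
    """Bridge gaps in a 2D edge set with discrete straight segments.

    Open curve endpoints (edge pixels with at most one 8-neighbour) are
    connected to their nearest edge pixel that is not part of their own
    local branch, provided the gap is larger than one voxel and at most
    ``max_gap_vox``.
    """
    edge = edge.copy()
    if edge.sum() < 2:
        return edge
    # endpoints are found on the skeleton: raw Canny output can be locally
    # 2 voxels wide, which hides the tips of an open curve
    skel = skeletonize(edge)
    coords = np.argwhere(skel)
    if len(coords) < 2:
        return edge
    kernel = np.ones((3, 3), dtype=np.uint8)
    kernel[1, 1] = 0
    nbrs = ndimage.convolve(skel.astype(np.uint8), kernel, mode="constant")
    endpoints = np.argwhere(skel & (nbrs <= 1))
    if len(endpoints) == 0:
        return edge
    tree = cKDTree(coords)
    coord_set = {tuple(c) for c in coords}
    for p in map(tuple, endpoints):
        own = _trace_branch(coord_set, p, depth=8)
        k = min(len(coords), 64)
        dists, idxs = tree.query(p, k=k)
        dists, idxs = np.atleast_1d(dists), np.atleast_1d(idxs)
        for d, i in zip(dists, idxs):
            q = tuple(coords[i])
            if q in own:
                continue
            if d > max_gap_vox:
                break
            rr, cc = draw_line(p[0], p[1], q[0], q[1])
            edge[rr, cc] = True
            break
    return edge


def _trace_branch(coord_set: set, start: tuple, depth: int) -> set:
    """Edge pixels within ``depth`` steps of ``start`` along the edge graph."""
    frontier = {start}
    seen = {start}
    for _ in range(depth):
        nxt = set()
        for r, c in frontier:
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    q = (r + dr, c + dc)
                    if q not in seen and q in coord_set:
                        nxt.add(q)
                        seen.add(q)
        if not nxt:
            break
        frontier = nxt
    return seen


def detect_and_close_edges(
    volume: IntensityVolume,
    ref: BrainReference,
    config: CannyConfig | None = None,
) -> np.ndarray:
    """Brain-boundary edge voxels used as leak barriers.

    Intensities outside the statistical brain range are zeroed, 2D Canny is
    run per axial and per sagittal slice (hysteresis thresholds are
    fractions of each slice's maximum gradient, so the result is invariant
    to intensity rescaling) and the union is gap-closed per axial slice.
    """
    config = config or CannyConfig()
    data = volume.data.astype(np.float64, copy=False)
    windowed = np.where(
        (data >= ref.window_stat.lo) & (data <= ref.window_stat.hi), data, 0.0
    )
    edges = np.zeros(volume.shape, dtype=bool)
    for k in range(volume.shape[0]):
        edges[k] |= _canny_slice(windowed[k], config)
    for x in range(volume.shape[2]):
        edges[:, :, x] |= _canny_slice(windowed[:, :, x], config)
    max_gap = config.max_gap_mm / min(volume.spacing_mm[1:])
    for k in range(volume.shape[0]):
        if edges[k].any():
            edges[k] = close_edge_gaps_2d(edges[k], max_gap)
    return edges


# ---------------------------------------------------------------------------
# region-growing stages


def segment_brain_initial(
    volume: IntensityVolume,
    ref: BrainReference,
    edges: np.ndarray,
) -> np.ndarray:
    """3D region growing from the WM reference within [0.7, 1.2] x wmIntensity."""
    barrier = np.asarray(edges, dtype=bool)
    if barrier[ref.wm_voxel]:
        barrier = barrier.copy()
        barrier[ref.wm_voxel] = False
    return region_grow(
        volume, [ref.wm_voxel], ref.window_grow, barrier=barrier, connectivity=6
    )


def find_csf_reference(
    volume: IntensityVolume,
    brain0: np.ndarray,
    ref: BrainReference,
    config: CsfConfig | None = None,
    stat_lo: float = 0.53,
) -> tuple[TissueStats, np.ndarray]:
    """CSF statistics from the most uniform dark 5 mm window inside the brain.

    The search region is the initial brain mask after a small morphological
    closing and hole filling, so ventricles and other CSF spaces enclosed
    by (or communicating narrowly with) the segmented brain are searchable.
    Candidate windows must lie fully inside the region and have a center
    intensity below ``stat_lo * wmIntensity``. Returns the statistics over
    the winning window together with its voxel mask (used as CSF seeds).
    """
    config = config or CsfConfig()
    brain0 = np.asarray(brain0, dtype=bool)
    if not brain0.any():
        raise ValueError("initial brain mask is empty")
    footprint = _ball_footprint(config.closing_mm, volume.spacing_mm)
    region = ndimage.binary_closing(brain0, structure=footprint)
    region = ndimage.binary_fill_holes(region)

    counts = window_mm_to_voxels(config.window_mm, volume.spacing_mm)
    inside = (
        ndimage.minimum_filter(
            region.astype(np.uint8), size=counts, mode="constant", cval=0
        )
        == 1
    )
    data = volume.data.astype(np.float64, copy=False)
    centers = inside & (data < stat_lo * ref.wm_intensity)
    if not centers.any():
        raise ValueError("no CSF reference found")

    mean = ndimage.uniform_filter(data, size=counts)
    m2 = ndimage.uniform_filter(data * data, size=counts)
    sd = np.sqrt(np.maximum(m2 - mean * mean, 0.0))
    const = ndimage.maximum_filter(data, size=counts) == ndimage.minimum_filter(
        data, size=counts
    )
    sd[const] = 0.0
    u = _uniformity(mean, sd)
    u_c = np.where(centers, u, -np.inf)
    flat = int(np.argmax(u_c))  # first max = lowest (k, row, col)
    center = np.unravel_index(flat, volume.shape)

    slices = tuple(
        slice(c - n // 2, c + n // 2 + 1) for c, n in zip(center, counts)
    )
    window_values = data[slices]
    stats = TissueStats(
        mean=float(window_values.mean()),
        sd=float(window_values.std()),
        min=float(window_values.min()),
        n=int(window_values.size),
    )
    seed_mask = np.zeros(volume.shape, dtype=bool)
    seed_mask[slices] = True
    return stats, seed_mask


def skull_seed_mask(
    volume: IntensityVolume,
    body: np.ndarray,
    air_stats: TissueStats,
    config: SkullConfig | None = None,
) -> np.ndarray:
    """Air-dark voxels within ``rim_cm`` of the external body contour."""
    config = config or SkullConfig()
    body = np.asarray(body, dtype=bool)
    depth = ndimage.distance_transform_edt(body, sampling=volume.spacing_mm)
    threshold = air_stats.mean + config.air_sigma * air_stats.sd
    return body & (depth <= config.rim_cm * 10.0) & (volume.data <= threshold)


@dataclass
class SkullMask:
    """Skull exclusion zone: grown core plus everything external to it."""

    mask: np.ndarray  #: full exclusion zone
    grown: np.ndarray  #: region-grown core (dark skull + absorbed dark voxels)
    seeds: np.ndarray


def _rays_blocked(
    candidates: np.ndarray,
    target_vox: np.ndarray,
    obstacle: np.ndarray,
    step_vox: float,
    chunk: int = 65536,
) -> np.ndarray:
    """For each candidate voxel: does the straight segment to ``target_vox``
    pass through ``obstacle``? Sampled at ``step_vox`` voxel increments."""
    shape = obstacle.shape
    coords = np.argwhere(candidates).astype(np.float64)
    blocked = np.zeros(len(coords), dtype=bool)
    flat_obstacle = obstacle.ravel()
    for start in range(0, len(coords), chunk):
        pts = coords[start : start + chunk]
        delta = target_vox[None, :] - pts
        span = np.abs(delta).max()
        n_steps = max(1, int(np.ceil(span / step_vox)))
        hit = np.zeros(len(pts), dtype=bool)
        for i in range(1, n_steps + 1):
            t = i / n_steps
            sample = np.rint(pts + t * delta).astype(np.intp)
            for ax in range(3):
                np.clip(sample[:, ax], 0, shape[ax] - 1, out=sample[:, ax])
            flat = (sample[:, 0] * shape[1] + sample[:, 1]) * shape[2] + sample[:, 2]
            hit |= flat_obstacle[flat]
        blocked[start : start + len(pts)] = hit
    out = np.zeros(shape, dtype=bool)
    out[tuple(np.argwhere(candidates).T)] = blocked
    return out


def build_skull_mask(
    volume: IntensityVolume,
    body: np.ndarray,
    brain0: np.ndarray,
    csf_stats: TissueStats,
    air_stats: TissueStats,
    edges: np.ndarray,
    csf: np.ndarray | None = None,
    config: SkullConfig | None = None,
    protect: np.ndarray | None = None,
) -> SkullMask:
    """Grow the skull from rim seeds and add everything external to it.

    Seeds are body voxels within ``rim_cm`` of the body surface at air-dark
    intensity; growing uses the window [0, mu_csf + 2 sigma_csf] inside the
    body, barred by the initial brain, any CSF segmented so far and the
    edge voxels. Afterwards every remaining body voxel whose straight path
    to the brain centroid crosses the grown skull is added, which turns the
    mask into an exclusion zone covering the scalp and face.

    ``protect`` (typically the filled brain interior) is removed from the
    grown core before the path test: CSF spaces that communicate with the
    periphery can otherwise be absorbed during growing and would then
    shadow the brain interior itself.
    """
    config = config or SkullConfig()
    body = np.asarray(body, dtype=bool)
    brain0 = np.asarray(brain0, dtype=bool)
    csf = np.zeros_like(body) if csf is None else np.asarray(csf, dtype=bool)

    window = IntensityWindow(0.0, csf_stats.mean + config.csf_sigma * csf_stats.sd)
    barrier = brain0 | csf | np.asarray(edges, dtype=bool) | ~body
    seeds = skull_seed_mask(volume, body, air_stats, config)
    seeds &= (volume.data >= window.lo) & (volume.data <= window.hi) & ~barrier
    if not seeds.any():
        raise ValueError("no skull seed voxels")
    grown = region_grow(volume, seeds, window, barrier=barrier, connectivity=6)
    if protect is not None:
        grown &= ~np.asarray(protect, dtype=bool)

    centroid = np.asarray(ndimage.center_of_mass(brain0), dtype=np.float64)
    candidates = body & ~brain0 & ~csf & ~grown
    added = _rays_blocked(candidates, centroid, grown, config.ray_step_vox)
    return SkullMask(mask=grown | added, grown=grown, seeds=seeds)


def segment_csf(
    volume: IntensityVolume,
    csf_stats: TissueStats,
    skull_mask: np.ndarray,
    csf_seeds: np.ndarray,
    sigma: float = 2.0,
) -> np.ndarray:
    """Region growing from the CSF reference window, barred by the skull mask."""
    skull_mask = np.asarray(skull_mask, dtype=bool)
    csf_seeds = np.asarray(csf_seeds, dtype=bool)
    if (csf_seeds & skull_mask).any():
        raise ValueError("seed in skull mask")
    window = csf_stats.window(sigma)
    in_window = (volume.data >= window.lo) & (volume.data <= window.hi)
    seeds = csf_seeds & in_window
    if not seeds.any():
        raise ValueError("no CSF seeds inside the growing window")
    return region_grow(volume, seeds, window, barrier=skull_mask, connectivity=6)


def segment_brain_final(
    volume: IntensityVolume,
    ref: BrainReference,
    brain0: np.ndarray,
    csf: np.ndarray,
    skull_mask: np.ndarray,
) -> np.ndarray:
    """Recover gray matter in sulci: grow the statistical brain range from
    the initial brain, barred by the skull mask and CSF; union with brain0."""
    brain0 = np.asarray(brain0, dtype=bool)
    csf = np.asarray(csf, dtype=bool)
    skull_mask = np.asarray(skull_mask, dtype=bool)
    barrier = (skull_mask | csf) & ~brain0
    in_window = (volume.data >= ref.window_stat.lo) & (
        volume.data <= ref.window_stat.hi
    )
    seeds = brain0 & in_window
    if seeds.any():
        grown = region_grow(
            volume, seeds, ref.window_stat, barrier=barrier, connectivity=6
        )
    else:
        grown = np.zeros_like(brain0)
    return (grown | brain0) & ~csf & ~skull_mask
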