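"""Digital head phantom: paired T1-MR-like and ground-truth CT volumes.

The phantom emulates the anatomy the segmentation chain relies on:

* a scalp of fat over muscle;
* a three-layer braincase — outer cortical table, trabecular (diploic)
  layer, inner cortical table — with cortical pillars bridging the tables
  (as diploic septa do), so bone is one connected dark structure;
* a subarachnoid CSF film between the inner table and the cortical gray
  matter, lateral ventricles inside the white matter, and a narrow CSF
  channel connecting ventricles to the film (aqueduct-like);
* uniform white matter (the most uniform tissue), a gray-matter rind at
  0.7 x the WM intensity, trabecular bone overlapping brain/fat in MR
  intensity, cortical bone at the air noise floor;
* two spherical eyes embedded in orbital fat sockets that carve into the
  anterior skull;
* a frontal sinus continuous with an airway that opens at the inferior
  head surface;
* optionally a small bright contrast-enhancing lesion in the white matter
  and a surgical skull defect.

Ground-truth CT numbers sit at the midpoint of each tissue's target HU
interval. MR degradation is a smooth multiplicative bias field plus
Rician noise (magnitude images have a non-zero noise floor in air, which
is exactly what the air statistics estimator has to cope with).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage.measure import find_contours

from .io_formats import ContourSet
from .volume_model import IntensityVolume, Label, LabelVolume

#: internal region codes (finer than the tissue labels: WM/GM both -> BRAIN)
REGIONS = {
    "background": 0,
    "muscle": 1,
    "fat": 2,
    "cortical": 3,
    "trabecular": 4,
    "csf": 5,
    "gm": 6,
    "wm": 7,
    "eye": 8,
    "air": 9,
    "contrast": 10,
}

_REGION_TO_LABEL = {
    "background": Label.BACKGROUND,
    "muscle": Label.MUSCLE,
    "fat": Label.FAT,
    "cortical": Label.CORTICAL_BONE,
    "trabecular": Label.TRABECULAR_BONE,
    "csf": Label.CSF,
    "gm": Label.BRAIN,
    "wm": Label.BRAIN,
    "eye": Label.EYE,
    "air": Label.AIR,
    "contrast": Label.CONTRAST,
}

#: MR means in arbitrary units (WM = 1000); cortical bone sits on the air
#: noise floor — the two are indistinguishable on T1 images.
DEFAULT_MR = {
    "background": 15.0,
    "air": 15.0,
    "cortical": 15.0,
    "trabecular": 640.0,
    "wm": 1000.0,
    "gm": 700.0,
    "csf": 200.0,
    "eye": 450.0,
    "muscle": 500.0,
    "fat": 1300.0,
    "contrast": 2500.0,
}

#: ground-truth HU: midpoint of each tissue's target CT interval
DEFAULT_HU = {
    "background": -1000.0,
    "air": -1000.0,
    "cortical": 900.0,
    "trabecular": 600.0,
    "wm": 57.5,
    "gm": 57.5,
    "csf": 45.0,
    "eye": 45.0,
    "muscle": 50.0,
    "fat": -45.0,
    "contrast": 0.0,
}


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (192, 192, 192)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    #: Rician noise sigma in MR units (default 2% of the WM intensity)
    noise_sigma: float = 20.0
    #: multiplicative bias field amplitude (field spans [1 - a, 1 + a])
    bias_amplitude: float = 0.05
    lesion: bool = True
    skull_defect: bool = False
    mr_means: dict = field(default_factory=lambda: dict(DEFAULT_MR))
    hu_values: dict = field(default_factory=lambda: dict(DEFAULT_HU))
    max_contour_slices: int = 12


@dataclass
class PhantomResult:
    mr: IntensityVolume
    ct: IntensityVolume
    truth: LabelVolume
    contours: ContourSet
    regions: np.ndarray  #: REGIONS codes, finer than the truth labels


def _mm_grids(shape, spacing):
    """Coordinate grids in mm relative to the volume center."""
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)
    ]
    return np.meshgrid(*axes, indexing="ij", sparse=True)


def _ellipsoid(grids, center, semi):
    z, y, x = grids
    cz, cy, cx = center
    az, ay, ax = semi
    return (
        ((z - cz) / az) ** 2 + ((y - cy) / ay) ** 2 + ((x - cx) / ax) ** 2
    ) <= 1.0


def _sphere(grids, center, radius):
    return _ellipsoid(grids, center, (radius,) * 3)


def build_regions(config: PhantomConfig) -> np.ndarray:
    """Paint the anatomical region map (later structures overwrite earlier)."""
    shape, spacing = config.shape, config.spacing_mm
    if min(n * s for n, s in zip(shape, spacing)) < 180.0:
        raise ValueError("grid too small: the head does not fit")
    g = _mm_grids(shape, spacing)
    z, y, x = g
    R = np.zeros(shape, dtype=np.uint8)

    def paint(mask, name):
        R[mask] = REGIONS[name]

    bc = (4.0, -14.0, 0.0)  # braincase center (superior, posterior shift)
    head = _ellipsoid(g, (0, 0, 0), (88, 78, 66))
    paint(head, "fat")
    paint(_ellipsoid(g, (0, 0, 0), (82, 72, 60)), "muscle")
    # braincase tables: outer cortical / trabecular diploe; the scalp over
    # the cranium is <= ~8 mm so the skull sits within the 1 cm seed rim
    paint(_ellipsoid(g, bc, (76, 60, 58)), "cortical")
    paint(_ellipsoid(g, bc, (72, 56, 54)), "trabecular")
    # orbital fat sockets and eyes; the orbit carves into the outer table
    # and the diploe but never through the inner table (painted later)
    eye_centers = [(-24.0, 48.0, side * 23.0) for side in (-1.0, 1.0)]
    for center in eye_centers:
        paint(_sphere(g, center, 19.0) & head, "fat")
    # frontal sinus continuous with the airway, opening inferiorly
    paint(_sphere(g, (-50.0, 30.0, 0.0), 7.0), "air")
    paint(((y - 30.0) ** 2 + x**2 <= 36.0) & (z - bc[0] <= -56.0) & head, "air")
    # inner table and the cranial content (repainted over any carving)
    paint(_ellipsoid(g, bc, (68, 52, 50)), "cortical")
    paint(_ellipsoid(g, bc, (64, 48, 46)), "csf")  # subarachnoid film
    paint(_ellipsoid(g, bc, (61, 45, 43)), "gm")
    paint(_ellipsoid(g, bc, (55, 39, 37)), "wm")
    # diploic pillars: cortical bridges between the two tables
    trab = R == REGIONS["trabecular"]
    beam_y = (np.abs(x - bc[2]) <= 4.0) & (np.abs(z - bc[0]) <= 4.0)
    beam_x = (np.abs(y - bc[1]) <= 4.0) & (np.abs(z - bc[0]) <= 4.0)
    paint(trab & (beam_y | beam_x), "cortical")
    # ventricles + aqueduct-like channel to the inferior subarachnoid film
    for side in (-1.0, 1.0):
        paint(_ellipsoid(g, (bc[0], bc[1] - 2, side * 10.0), (14, 8, 8)), "csf")
    channel = (
        ((y - (bc[1] - 2.0)) ** 2 + (x - bc[2]) ** 2 <= 12.25)
        & (z - bc[0] >= -63.0)
        & (z - bc[0] <= 0.0)
    )
    paint(channel & (R != REGIONS["cortical"]) & (R != REGIONS["trabecular"]), "csf")
    if config.lesion:
        paint(_sphere(g, (12.0, 0.0, -20.0), 6.0), "contrast")
    for center in eye_centers:
        paint(_sphere(g, center, 17.0), "eye")
    if config.skull_defect:
        defect = (
            (np.abs(x - bc[2]) <= 8.0)
            & (np.abs(y - bc[1]) <= 8.0)
            & (z >= bc[0] + 30.0)
        )
        bone = (R == REGIONS["cortical"]) | (R == REGIONS["trabecular"])
        paint(defect & bone, "muscle")
    return R


def _lut(mapping: dict, regions: np.ndarray) -> np.ndarray:
    lut = np.zeros(max(REGIONS.values()) + 1, dtype=np.float64)
    for name, code in REGIONS.items():
        lut[code] = mapping[name]
    return lut[regions]


def bias_field(shape, amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field spanning exactly [1 - a, 1 + a]."""
    coarse = rng.standard_normal((5, 5, 5))
    zoom = [n / c for n, c in zip(shape, coarse.shape)]
    f = ndimage.zoom(coarse, zoom, order=3, mode="nearest", grid_mode=True)
    lo, hi = f.min(), f.max()
    if hi == lo:
        return np.ones(shape)
    return 1.0 + amplitude * (2.0 * (f - lo) / (hi - lo) - 1.0)


def degrade(
    mr: IntensityVolume,
    bias_amplitude: float,
    noise_sigma: float,
    seed: int,
) -> IntensityVolume:
    """Apply a multiplicative bias field and Rician noise (deterministic).

    With both parameters zero the input data is returned unchanged.
    Rician noise models magnitude MR reconstruction:
    ``sqrt((I + n1)^2 + n2^2)`` with independent Gaussian n1, n2.
    """
    if bias_amplitude < 0 or noise_sigma < 0:
        raise ValueError("bias amplitude and noise sigma must be >= 0")
    data = mr.data.astype(np.float64, copy=True)
    rng = np.random.default_rng(seed)
    if bias_amplitude > 0:
        data *= bias_field(mr.shape, bias_amplitude, rng)
    if noise_sigma > 0:
        n1 = rng.normal(0.0, noise_sigma, size=mr.shape)
        n2 = rng.normal(0.0, noise_sigma, size=mr.shape)
        data = np.hypot(data + n1, n2)
    return replace(mr, data=data)


def _component_contour_slices(
    areas: dict[int, np.ndarray], budget: int
) -> dict[int, list[int]]:
    """Allocate contoured slices to air components within a total budget.

    Each component starts with its end slices; the remaining budget is
    spent greedily on the slice whose cross-sectional area is worst
    predicted by linear interpolation between the slices chosen so far
    (a proxy for the shape-based interpolation error). Components with a
    constant cross-section thus need only their end slices.
    """
    chosen: dict[int, list[int]] = {}
    remaining = budget
    for cid, profile in areas.items():
        zs = np.flatnonzero(profile)
        chosen[cid] = sorted({int(zs[0]), int(zs[-1])})
        remaining -= len(chosen[cid])

    def worst_slice(cid):
        profile = areas[cid]
        picks = chosen[cid]
        best = (0.0, None)
        for k0, k1 in zip(picks[:-1], picks[1:]):
            for k in range(k0 + 1, k1):
                t = (k - k0) / (k1 - k0)
                predicted = (1 - t) * profile[k0] + t * profile[k1]
                err = abs(profile[k] - predicted)
                if err > best[0]:
                    best = (err, k)
        return best

    for _ in range(max(0, remaining)):
        errs = {cid: worst_slice(cid) for cid in chosen}
        cid = max(errs, key=lambda c: errs[c][0])
        err, k = errs[cid]
        if k is None or err <= 0:
            break
        chosen[cid] = sorted(set(chosen[cid]) | {k})
    return chosen


def auto_air_contours(
    air: np.ndarray, shape, spacing, budget: int = 12
) -> ContourSet:
    """Trace closed outlines of the true air cavities on <= ``budget`` slices."""
    labeled, n = ndimage.label(air)
    areas = {}
    for cid in range(1, n + 1):
        areas[cid] = (labeled == cid).sum(axis=(1, 2)).astype(np.float64)
    allocation = _component_contour_slices(areas, budget)
    contours = []
    for cid, slices in allocation.items():
        for k in slices:
            mask = np.pad(labeled[k] == cid, 1)
            for curve in find_contours(mask.astype(float), 0.5):
                verts = curve[::2] - 1.0  # undo padding, thin the polygon
                if len(verts) >= 3:
                    contours.append((k, verts))
    return ContourSet(contours, shape, spacing)


def generate_phantom(
    config: PhantomConfig | None = None, seed: int = 0
) -> PhantomResult:
    """Build the paired MR / ground-truth CT / label map / air contours."""
    config = config or PhantomConfig()
    regions = build_regions(config)
    mr_clean = IntensityVolume(
        data=_lut(config.mr_means, regions),
        spacing_mm=config.spacing_mm,
        modality="MR",
    )
    mr = degrade(mr_clean, config.bias_amplitude, config.noise_sigma, seed)
    ct = IntensityVolume(
        data=_lut(config.hu_values, regions),
        spacing_mm=config.spacing_mm,
        modality="CT",
    )
    label_lut = np.zeros(max(REGIONS.values()) + 1, dtype=np.uint8)
    for name, code in REGIONS.items():
        label_lut[code] = int(_REGION_TO_LABEL[name])
    truth = LabelVolume(labels=label_lut[regions], spacing_mm=config.spacing_mm)
    contours = auto_air_contours(
        regions == REGIONS["air"],
        config.shape,
        config.spacing_mm,
        config.max_contour_slices,
    )
    return PhantomResult(mr=mr, ct=ct, truth=truth, contours=contours, regions=regions)
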