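"""Core grid types and shared numeric primitives.

Conventions used throughout the package:

* volumes are indexed ``(k, row, col)`` with ``k`` the axial slice index
  (increasing toward the top of the head), ``row`` increasing anterior and
  ``col`` increasing toward the patient's left;
* all physical thresholds are given in mm/cm and converted to voxels via
  the header spacing;
* intensity windows are closed intervals;
* standard deviations are population SDs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage


class Label(IntEnum):
    """Tissue classes assigned by the segmentation pipeline."""

    BACKGROUND = 0
    AIR = 1
    CORTICAL_BONE = 2
    TRABECULAR_BONE = 3
    BRAIN = 4
    CSF = 5
    EYE = 6
    MUSCLE = 7
    FAT = 8
    CONTRAST = 9


@dataclass
class IntensityVolume:
    """A 3D scalar grid: MR intensities (arbitrary units) or CT numbers (HU).

    Parameters
    ----------
    data
        3D array indexed ``(k, row, col)``.
    spacing_mm
        Voxel spacing ``(dz, dy, dx)`` in mm, strictly positive.
    modality
        ``"MR"`` or ``"CT"``.
    origin_mm
        Physical position of voxel (0, 0, 0); used when converting
        structure-set coordinates to grid indices.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    modality: str = "MR"
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        if min(self.data.shape) < 1:
            raise ValueError("all three extents must be >= 1")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("voxel spacing must be strictly positive")
        if self.modality not in ("MR", "CT"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.modality == "CT" and not np.all(np.isfinite(self.data)):
            raise ValueError("CT values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume_mm3(self) -> float:
        dz, dy, dx = self.spacing_mm
        return dz * dy * dx


@dataclass
class LabelVolume:
    """Integer tissue-label grid aligned to a parent :class:`IntensityVolume`."""

    labels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        valid = {int(v) for v in Label}
        present = set(np.unique(self.labels).tolist())
        if not present <= valid:
            raise ValueError(f"unknown label codes: {sorted(present - valid)}")

    def mask(self, label: Label) -> np.ndarray:
        return self.labels == int(label)


@dataclass
class TissueStats:
    """Per-tissue intensity statistics (population SD)."""

    mean: float
    sd: float
    min: float
    n: int

    def window(self, n_sigma: float, lo_floor: float | None = None) -> "IntensityWindow":
        """The ``mean ± n_sigma * sd`` window, optionally floored below."""
        lo = self.mean - n_sigma * self.sd
        hi = self.mean + n_sigma * self.sd
        if lo_floor is not None:
            lo = max(lo, lo_floor)
        return IntensityWindow(lo, hi)


@dataclass
class IntensityWindow:
    """Closed intensity interval ``[lo, hi]``."""

    lo: float
    hi: float

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"window lo {self.lo} > hi {self.hi}")

    def contains(self, value: float | np.ndarray) -> bool | np.ndarray:
        return (value >= self.lo) & (value <= self.hi)


def compute_region_stats(volume: IntensityVolume, mask: np.ndarray) -> TissueStats:
    """Mean, population SD and minimum of ``volume`` over ``mask``.

    Raises ``ValueError("empty region")`` when the mask selects no voxel.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != volume.shape:
        raise ValueError("mask shape does not match volume")
    values = volume.data[mask]
    if values.size == 0:
        raise ValueError("empty region")
    values = values.astype(np.float64, copy=False)
    return TissueStats(
        mean=float(values.mean()),
        sd=float(values.std()),
        min=float(values.min()),
        n=int(values.size),
    )


def window_mm_to_voxels(
    window_mm: float | Sequence[float], spacing_mm: Sequence[float]
) -> tuple[int, int, int]:
    """Convert a physical window extent to odd per-axis voxel counts (>= 1).

    A scalar applies to all three axes; an entry of 0 collapses that axis to
    a single voxel (used for in-plane 2D windows).
    """
    if np.isscalar(window_mm):
        window_mm = (float(window_mm),) * 3
    counts = []
    for w, s in zip(window_mm, spacing_mm):
        n = max(1, round(float(w) / float(s)))
        if n % 2 == 0:  # round to nearest odd
            n += 1 if (float(w) / float(s)) > n else -1
        counts.append(max(1, n))
    return tuple(counts)


def _window_slices(
    center: Sequence[int], counts: Sequence[int], shape: Sequence[int]
) -> tuple[slice, slice, slice]:
    slices = []
    for c, n, ext in zip(center, counts, shape):
        h = n // 2
        slices.append(slice(max(0, c - h), min(ext, c + h + 1)))
    return tuple(slices)


def compute_uniformity(
    volume: IntensityVolume,
    center: Sequence[int],
    window_mm: float | Sequence[float],
) -> float:
    """Uniformity U = mean / SD of intensities in a window around ``center``.

    The window extent is physical (mm), converted per axis via the spacing
    and clipped to the grid. A perfectly uniform window (SD = 0) returns
    ``inf``: it is maximally uniform.
    """
    center = tuple(int(c) for c in center)
    for c, ext in zip(center, volume.shape):
        if not 0 <= c < ext:
            raise ValueError(f"center {center} outside grid {volume.shape}")
    counts = window_mm_to_voxels(window_mm, volume.spacing_mm)
    values = volume.data[_window_slices(center, counts, volume.shape)]
    mean = float(np.mean(values))
    sd = float(np.std(values))
    if sd == 0.0:
        return math.inf
    return mean / sd


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    if connectivity == 26:
        return ndimage.generate_binary_structure(3, 3)
    raise ValueError("connectivity must be 6 or 26")


def region_grow(
    volume: IntensityVolume,
    seeds: Iterable[Sequence[int]] | np.ndarray,
    window: IntensityWindow,
    barrier: np.ndarray | None = None,
    connectivity: int = 6,
) -> np.ndarray:
    """Flood fill from ``seeds`` through in-window, non-barrier voxels.

    ``seeds`` is either a boolean mask or an iterable of voxel indices.
    Returns the union of connected components of the admissible set that
    touch at least one seed. Seeds outside the intensity window raise
    ``ValueError("seed outside intensity window")``; seeds on a barrier
    voxel raise ``ValueError("seed inside barrier")``.
    """
    data = volume.data
    if isinstance(seeds, np.ndarray) and seeds.dtype == bool:
        if seeds.shape != data.shape:
            raise ValueError("seed mask shape does not match volume")
        seed_mask = seeds
    else:
        seed_mask = np.zeros(data.shape, dtype=bool)
        for s in seeds:
            s = tuple(int(v) for v in s)
            for c, ext in zip(s, data.shape):
                if not 0 <= c < ext:
                    raise ValueError(f"seed {s} outside grid")
            seed_mask[s] = True
    if not seed_mask.any():
        raise ValueError("no seed voxels")

    admissible = (data >= window.lo) & (data <= window.hi)
    if not admissible[seed_mask].all():
        raise ValueError("seed outside intensity window")
    if barrier is not None:
        barrier = np.asarray(barrier, dtype=bool)
        if barrier.shape != data.shape:
            raise ValueError("barrier shape does not match volume")
        if barrier[seed_mask].any():
            raise ValueError("seed inside barrier")
        admissible &= ~barrier

    labeled, _ = ndimage.label(admissible, structure=_structure(connectivity))
    hit = np.unique(labeled[seed_mask])
    hit = hit[hit > 0]
    return np.isin(labeled, hit)


def connected_components(
    mask: np.ndarray, connectivity: int = 6
) -> tuple[np.ndarray, dict[int, int]]:
    """Label maximal connected true-regions; return (labels, sizes in voxels).

    Works on 2D or 3D masks; connectivity 6 means face-connected (4-connected
    in 2D) and 26 means fully connected (8-connected in 2D).
    """
    mask = np.asarray(mask, dtype=bool)
    if connectivity not in (6, 26):
        raise ValueError("connectivity must be 6 or 26")
    structure = ndimage.generate_binary_structure(
        mask.ndim, 1 if connectivity == 6 else mask.ndim
    )
    labeled, n = ndimage.label(mask, structure=structure)
    sizes = {}
    if n:
        counts = np.bincount(labeled.ravel())
        sizes = {i: int(counts[i]) for i in range(1, n + 1)}
    return labeled, sizes
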