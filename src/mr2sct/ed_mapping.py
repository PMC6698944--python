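"""Electron-density mapping: tissue labels + MR intensities -> HU.

Each tissue maps through one of three transforms:

* ``bulk``            a single CT number regardless of intensity,
* ``linear``          HU = hu_lo + (I - lo) / (hi - lo) * (hu_hi - hu_lo),
* ``inverse_linear``  HU = hu_hi - (I - lo) / (hi - lo) * (hu_hi - hu_lo),

with the MR window instantiated per patient from the segmentation
statistics (e.g. cortical bone mu +/- 2 sigma). Intensities outside the
window are clipped to it first — partial-volume voxels routinely fall
outside mu +/- 2 sigma and still deserve an in-range CT number.

Default table (T1-weighted MR -> CT):

=================  =============================  ==============  ==========
tissue             MR window                      transform       HU
=================  =============================  ==============  ==========
air / background   all                            bulk            -1000
cortical bone      mu_cbone +/- 2 sigma           inverse linear  [700, 1100]
trabecular bone    mu_trab +/- 2 sigma            inverse linear  [500, 700]
brain              mu_brain +/- 2 sigma           linear          [40, 75]
CSF                all                            bulk            45
eye                all                            bulk            45 (config)
muscle             [min_soft, mu_soft + sigma]    inverse linear  [20, 80]
fat                [mu_soft + s, mu_soft + 2 s]   inverse linear  [-70, -20]
contrast           all                            bulk            0
=================  =============================  ==============  ==========

The inverse-linear direction encodes the T1 anticorrelation between MR
intensity and density for bone and fatty tissue: the darker the voxel,
the denser the assigned tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import MappingConfig
from .volume_model import (
    IntensityVolume,
    IntensityWindow,
    Label,
    LabelVolume,
    TissueStats,
)

HU_AIR = -1000.0
HU_CSF = 45.0
HU_CONTRAST = 0.0


@dataclass
class MapEntry:
    """One tissue row of the mapping table.

    ``window=None`` means "all intensities" and is only valid for bulk
    entries; bulk entries must have ``hu_lo == hu_hi``.
    """

    tissue: Label
    transform: str  # "bulk" | "linear" | "inverse_linear"
    hu_lo: float
    hu_hi: float
    window: IntensityWindow | None = None

    def __post_init__(self) -> None:
        if self.hu_lo > self.hu_hi:
            raise ValueError("hu_lo > hu_hi")
        if self.transform == "bulk":
            if self.hu_lo != self.hu_hi:
                raise ValueError("bulk entries need hu_lo == hu_hi")
        elif self.transform in ("linear", "inverse_linear"):
            if self.window is None:
                raise ValueError(f"{self.transform} entry needs an MR window")
        else:
            raise ValueError(f"unknown transform {self.transform!r}")


MappingSpec = dict[Label, MapEntry]


def default_mapping_spec(
    stats: dict[str, TissueStats], config: MappingConfig | None = None
) -> MappingSpec:
    """Instantiate the default table from per-patient tissue statistics.

    ``stats`` needs keys ``cortical``, ``trabecular``, ``brain`` and
    ``soft`` (the global residual soft-tissue statistics providing
    min_soft / mu_soft / sigma_soft).
    """
    config = config or MappingConfig()
    soft = stats["soft"]
    muscle_hi = soft.mean + soft.sd
    fat_hi = soft.mean + 2.0 * soft.sd
    spec: MappingSpec = {
        Label.BACKGROUND: MapEntry(Label.BACKGROUND, "bulk", HU_AIR, HU_AIR),
        Label.AIR: MapEntry(Label.AIR, "bulk", HU_AIR, HU_AIR),
        Label.CORTICAL_BONE: MapEntry(
            Label.CORTICAL_BONE, "inverse_linear", 700.0, 1100.0,
            stats["cortical"].window(2.0),
        ),
        Label.TRABECULAR_BONE: MapEntry(
            Label.TRABECULAR_BONE, "inverse_linear", 500.0, 700.0,
            stats["trabecular"].window(2.0),
        ),
        Label.BRAIN: MapEntry(
            Label.BRAIN, "linear", 40.0, 75.0, stats["brain"].window(2.0)
        ),
        Label.CSF: MapEntry(Label.CSF, "bulk", HU_CSF, HU_CSF),
        Label.EYE: MapEntry(Label.EYE, "bulk", config.eye_hu, config.eye_hu),
        Label.MUSCLE: MapEntry(
            Label.MUSCLE, "inverse_linear", 20.0, 80.0,
            IntensityWindow(min(soft.min, muscle_hi), muscle_hi),
        ),
        Label.FAT: MapEntry(
            Label.FAT, "inverse_linear", -70.0, -20.0,
            IntensityWindow(muscle_hi, fat_hi),
        ),
        Label.CONTRAST: MapEntry(Label.CONTRAST, "bulk", HU_CONTRAST, HU_CONTRAST),
    }
    return spec


def map_voxel(intensity, entry: MapEntry):
    """Map MR intensity (scalar or array) through one table entry.

    Out-of-window intensities are clipped to the window; a degenerate
    window (lo == hi) maps to the midpoint HU.
    """
    intensity = np.asarray(intensity, dtype=np.float64)
    if entry.transform == "bulk":
        out = np.full(intensity.shape, entry.hu_lo)
        return float(out) if out.ndim == 0 else out
    lo, hi = entry.window.lo, entry.window.hi
    if hi == lo:
        out = np.full(intensity.shape, 0.5 * (entry.hu_lo + entry.hu_hi))
        return float(out) if out.ndim == 0 else out
    t = (np.clip(intensity, lo, hi) - lo) / (hi - lo)
    if entry.transform == "inverse_linear":
        out = entry.hu_hi - t * (entry.hu_hi - entry.hu_lo)
    else:
        out = entry.hu_lo + t * (entry.hu_hi - entry.hu_lo)
    return float(out) if out.ndim == 0 else out


def assemble_sct(
    volume: IntensityVolume,
    labels: LabelVolume,
    stats: dict[str, TissueStats] | None = None,
    spec: MappingSpec | None = None,
    config: MappingConfig | None = None,
) -> IntensityVolume:
    """Build the synthetic CT from a complete label map.

    Either a ready ``spec`` or the ``stats`` to instantiate the default
    table must be given. Every grid voxel must carry a label with a table
    entry.
    """
    if spec is None:
        if stats is None:
            raise ValueError("either spec or stats must be provided")
        spec = default_mapping_spec(stats, config)
    lab = np.asarray(labels.labels)
    if lab.shape != volume.shape:
        raise ValueError("label grid does not match the volume")
    present = set(np.unique(lab).tolist())
    missing = present - {int(e.tissue) for e in spec.values()}
    if missing:
        raise ValueError(f"no mapping entry for labels {sorted(missing)}")
    hu = np.empty(volume.shape, dtype=np.float64)
    for entry in spec.values():
        sel = lab == int(entry.tissue)
        if not sel.any():
            continue
        hu[sel] = map_voxel(volume.data[sel], entry)
    return IntensityVolume(
        data=hu,
        spacing_mm=volume.spacing_mm,
        modality="CT",
        origin_mm=volume.origin_mm,
    )
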