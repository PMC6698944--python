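"""Reading and writing volumes, contours, synthetic CTs and label maps.

Supported formats: NIfTI (via nibabel, reoriented to a canonical RAS-like
layout on load), DICOM MR/CT series (via pydicom, slices sorted by
position, rescale slope/intercept applied), DICOM RTSTRUCT (read-only, an
ROI named "AIR" in any case), and a documented JSON contour schema::

    {"contours": [{"slice": 10, "vertices": [[row, col], ...]}, ...]}

Vertices are in grid (row, col) coordinates on the given axial slice.
"""

from __future__ import annotations

import json
import logging
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from skimage.draw import polygon2mask

from .volume_model import IntensityVolume, LabelVolume

logger = logging.getLogger(__name__)

HU_MIN, HU_MAX = -1024, 3071

#: warn when more slices than this carry manual air contours
MAX_CONTOURED_SLICES = 12


@dataclass
class ContourSet:
    """Per-slice closed planar polygons annotating an MR volume.

    ``contours`` is a list of ``(slice_index, vertices)`` where ``vertices``
    is an ``(n, 2)`` float array of (row, col) points; the polygon is closed
    (first vertex repeated at the end if needed on construction).
    """

    contours: list[tuple[int, np.ndarray]]
    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        closed = []
        for k, verts in self.contours:
            verts = np.asarray(verts, dtype=float)
            if verts.ndim != 2 or verts.shape[1] != 2:
                raise ValueError("contour vertices must be an (n, 2) array")
            if np.allclose(verts[0], verts[-1]) and len(verts) > 1:
                verts = verts[:-1]
            if len(verts) < 3:
                raise ValueError("polygon with < 3 vertices")
            k = int(k)
            if not 0 <= k < self.shape[0]:
                raise ValueError(f"slice index {k} outside grid")
            closed.append((k, verts))
        self.contours = closed
        n_slices = len(self.slice_indices())
        if n_slices > MAX_CONTOURED_SLICES:
            warnings.warn(
                f"{n_slices} contoured slices (> {MAX_CONTOURED_SLICES} expected "
                "for manual air contours)",
                stacklevel=2,
            )

    def slice_indices(self) -> list[int]:
        return sorted({k for k, _ in self.contours})

    def rasterize_slice(self, k: int) -> np.ndarray:
        """Union of the slice's polygons as a boolean (rows, cols) mask."""
        mask = np.zeros(self.shape[1:], dtype=bool)
        for ks, verts in self.contours:
            if ks == k:
                mask |= polygon2mask(self.shape[1:], verts)
        return mask


# ---------------------------------------------------------------------------
# volume reading


def read_volume(path, modality: str | None = None) -> IntensityVolume:
    """Read a NIfTI file or a DICOM series directory.

    NIfTI volumes are reoriented to the closest canonical (RAS) layout and
    stored ``(k, row, col)``. DICOM slices are sorted by position along the
    slice normal and CT rescale slope/intercept is applied so values are HU.
    MR intensities are shifted so that the minimum is >= 0.
    """
    path = os.fspath(path)
    if os.path.isdir(path):
        vol = _read_dicom_series(path)
    else:
        vol = _read_nifti(path, modality or "MR")
    if modality is not None:
        vol.modality = modality
    if vol.modality == "MR":
        lo = float(vol.data.min())
        if lo < 0:
            vol.data = vol.data - lo
    return vol


def _read_nifti(path: str, modality: str) -> IntensityVolume:
    img = nib.as_closest_canonical(nib.load(path))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise ValueError("expected a 3D NIfTI volume")
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise ValueError("missing spacing in NIfTI header")
    origin = img.affine[:3, 3]
    return IntensityVolume(
        data=np.ascontiguousarray(data.transpose(2, 1, 0)),
        spacing_mm=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
        modality=modality,
        origin_mm=(float(origin[2]), float(origin[1]), float(origin[0])),
    )


def _read_dicom_series(path: str) -> IntensityVolume:
    files = sorted(
        os.path.join(path, f) for f in os.listdir(path) if not f.startswith(".")
    )
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM image slices found in {path}")

    orientations = {tuple(np.round(np.asarray(ds.ImageOrientationPatient, float), 5))
                    for ds in slices}
    if len(orientations) != 1:
        raise ValueError("mixed-orientation DICOM series")
    orient = np.asarray(slices[0].ImageOrientationPatient, dtype=float)
    normal = np.cross(orient[:3], orient[3:])

    def position(ds):
        return float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal))

    slices.sort(key=position)
    if "PixelSpacing" not in slices[0]:
        raise ValueError("missing spacing in DICOM series")
    dy, dx = (float(v) for v in slices[0].PixelSpacing)
    if len(slices) > 1:
        dz = abs(position(slices[1]) - position(slices[0]))
    else:
        dz = float(getattr(slices[0], "SliceThickness", 0) or 0)
    if dz <= 0:
        raise ValueError("missing slice spacing in DICOM series")

    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0) or 1.0)
        intercept = float(getattr(ds, "RescaleIntercept", 0.0) or 0.0)
        planes.append(arr * slope + intercept)
    data = np.stack(planes, axis=0)
    modality = str(getattr(slices[0], "Modality", "MR"))
    ipp = np.asarray(slices[0].ImagePositionPatient, dtype=float)
    return IntensityVolume(
        data=data,
        spacing_mm=(dz, dy, dx),
        modality="CT" if modality == "CT" else "MR",
        origin_mm=(float(ipp[2]), float(ipp[1]), float(ipp[0])),
    )


# ---------------------------------------------------------------------------
# contour reading


def read_air_contours(path, frame: IntensityVolume) -> ContourSet:
    """Read manual air contours from a JSON file or a DICOM RTSTRUCT.

    RTSTRUCT files must contain an ROI named ``AIR`` (case-insensitive);
    its contour points (patient mm) are converted to grid (row, col)
    coordinates using the frame volume's spacing and origin.
    """
    path = os.fspath(path)
    if path.lower().endswith((".json",)):
        return _read_json_contours(path, frame)
    ds = pydicom.dcmread(path)
    if getattr(ds, "Modality", "") == "RTSTRUCT":
        return _read_rtstruct_contours(ds, frame)
    raise ValueError(f"unsupported contour file: {path}")


def _read_json_contours(path: str, frame: IntensityVolume) -> ContourSet:
    with open(path) as fh:
        payload = json.load(fh)
    entries = payload["contours"] if isinstance(payload, dict) else payload
    contours = [(int(e["slice"]), np.asarray(e["vertices"], float)) for e in entries]
    return ContourSet(contours, frame.shape, frame.spacing_mm)


def _read_rtstruct_contours(ds, frame: IntensityVolume) -> ContourSet:
    roi_number = None
    for roi in getattr(ds, "StructureSetROISequence", []):
        if str(roi.ROIName).strip().lower() == "air":
            roi_number = roi.ROINumber
            break
    if roi_number is None:
        raise ValueError("RTSTRUCT has no ROI named 'AIR'")
    oz, oy, ox = frame.origin_mm
    dz, dy, dx = frame.spacing_mm
    contours = []
    for rc in getattr(ds, "ROIContourSequence", []):
        if rc.ReferencedROINumber != roi_number:
            continue
        for cs in getattr(rc, "ContourSequence", []):
            pts = np.asarray(cs.ContourData, dtype=float).reshape(-1, 3)
            rows = (pts[:, 1] - oy) / dy
            cols = (pts[:, 0] - ox) / dx
            ks = np.round((pts[:, 2] - oz) / dz).astype(int)
            if len(np.unique(ks)) != 1:
                raise ValueError("RTSTRUCT contour is not planar-axial")
            contours.append((int(ks[0]), np.column_stack([rows, cols])))
    if not contours:
        raise ValueError("RTSTRUCT AIR ROI has no contours")
    return ContourSet(contours, frame.shape, frame.spacing_mm)


# ---------------------------------------------------------------------------
# writing


def _canonical_affine(volume: IntensityVolume) -> np.ndarray:
    dz, dy, dx = volume.spacing_mm
    oz, oy, ox = volume.origin_mm
    affine = np.diag([dx, dy, dz, 1.0])
    affine[:3, 3] = (ox, oy, oz)
    return affine


def write_sct(volume: IntensityVolume, path, dialect: str = "nifti") -> None:
    """Write an HU volume as int16 NIfTI or a per-slice DICOM CT series.

    HU values outside [-1024, 3071] are clipped with a logged warning.
    NIfTI uses identity scaling; DICOM stores RescaleSlope 1 /
    RescaleIntercept -1024.
    """
    if volume.modality != "CT":
        raise ValueError("write_sct expects a CT (HU) volume")
    data = np.asarray(volume.data, dtype=np.float64)
    if data.min() < HU_MIN or data.max() > HU_MAX:
        logger.warning(
            "HU values outside [%d, %d] clipped on write", HU_MIN, HU_MAX
        )
        data = np.clip(data, HU_MIN, HU_MAX)
    data = np.rint(data).astype(np.int16)
    if dialect == "nifti":
        img = nib.Nifti1Image(
            np.ascontiguousarray(data.transpose(2, 1, 0)), _canonical_affine(volume)
        )
        img.header.set_slope_inter(1.0, 0.0)
        nib.save(img, path)
    elif dialect == "dicom":
        _write_dicom_series(data, volume, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def _write_dicom_series(data: np.ndarray, volume: IntensityVolume, outdir) -> None:
    os.makedirs(outdir, exist_ok=True)
    dz, dy, dx = volume.spacing_mm
    oz, oy, ox = volume.origin_mm
    series_uid = generate_uid()
    study_uid = generate_uid()
    stored = (data.astype(np.int32) + 1024).astype(np.uint16)
    for k in range(data.shape[0]):
        ds = Dataset()
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = meta
        ds.SOPClassUID = meta.MediaStorageSOPClassUID
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = k + 1
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.ImagePositionPatient = [ox, oy, oz + k * dz]
        ds.PixelSpacing = [dy, dx]
        ds.SliceThickness = dz
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = -1024.0
        ds.Rows, ds.Columns = data.shape[1:]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = stored[k].tobytes()
        ds.save_as(os.path.join(outdir, f"slice_{k:04d}.dcm"), enforce_file_format=True)


def write_labels(labels: LabelVolume, path, spacing_mm=None) -> None:
    """Write a label map as a uint8 NIfTI volume."""
    spacing = spacing_mm or labels.spacing_mm
    dz, dy, dx = spacing
    affine = np.diag([dx, dy, dz, 1.0])
    data = np.asarray(labels.labels, dtype=np.uint8)
    img = nib.Nifti1Image(np.ascontiguousarray(data.transpose(2, 1, 0)), affine)
    nib.save(img, path)


def read_labels(path) -> LabelVolume:
    img = nib.as_closest_canonical(nib.load(path))
    data = np.asarray(img.get_fdata()).astype(np.int64)
    zooms = img.header.get_zooms()[:3]
    return LabelVolume(
        labels=np.ascontiguousarray(data.transpose(2, 1, 0)),
        spacing_mm=(float(zooms[2]), float(zooms[1]), float(zooms[0])),
    )


def write_contours_json(contours: ContourSet, path) -> None:
    """Write contours in the package's JSON schema."""
    payload = {
        "contours": [
            {"slice": int(k), "vertices": np.asarray(v, float).tolist()}
            for k, v in contours.contours
        ]
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
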