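"""Reading and writing radiotherapy DICOM objects and the internal format.

Supports the two DICOM objects the pipeline touches — RT-Dose (3D dose grid)
and RT Structure Set (planar ROI contours) — plus a compact internal
``.npz`` container for synthetic cohorts.  Axis convention on the way in/out:
DICOM stores frames as (z, y, x) with patient coordinates (x, y, z); all
in-memory arrays follow the package (z, y, x) convention.

Unsupported dialects (tilted orientation, non-uniform frame offsets, dose
units that are not Gy/cGy) are rejected loudly rather than approximated.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Union

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from skimage import measure

from .core import Grid, DoseGrid, RoiMask, StructureSet

RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"

_AXIAL_ORIENTATION = [1.0, 0.0, 0.0, 0.0, 1.0, 0.0]


class DicomFormatError(ValueError):
    """Raised when a DICOM object cannot be interpreted safely."""


@dataclass
class Contour:
    """One closed planar polygon in patient coordinates (mm)."""

    vertices: np.ndarray  # (N, 3) array of (x, y, z)
    plane_z_mm: float

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("contour vertices must be an (N, 3) array")
        if len(self.vertices) < 3:
            raise ValueError("a contour needs at least 3 vertices")


@dataclass
class ContourSet:
    """Planar contours per ROI, as stored in an RT Structure Set."""

    rois: Dict[str, List[Contour]] = field(default_factory=dict)
    roi_numbers: Dict[str, int] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# RT-Dose
# --------------------------------------------------------------------------

def read_rtdose(path: Union[str, Path]) -> DoseGrid:
    """Read an RT-Dose object into a :class:`DoseGrid` (values in Gy)."""
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", None) != "RTDOSE":
        raise DicomFormatError(
            f"expected RTDOSE modality, got {getattr(ds, 'Modality', None)!r}"
        )
    units = getattr(ds, "DoseUnits", "GY").upper()
    if units == "GY":
        unit_factor = 1.0
    elif units == "CGY":
        unit_factor = 0.01
    else:
        raise DicomFormatError(f"dose units {units!r} are not convertible to Gy")
    if "DoseGridScaling" not in ds:
        raise DicomFormatError("RT-Dose object has no DoseGridScaling attribute")
    orientation = [float(v) for v in ds.ImageOrientationPatient]
    if not np.allclose(orientation, _AXIAL_ORIENTATION, atol=1e-6):
        raise DicomFormatError("only axial, untilted dose grids are supported")

    offsets = np.asarray([float(v) for v in ds.GridFrameOffsetVector])
    if len(offsets) < 2:
        raise DicomFormatError("dose grid must have >= 2 frames")
    dz = np.diff(offsets)
    if not np.allclose(dz, dz[0], atol=1e-6):
        raise DicomFormatError("non-uniform frame offsets are not supported")

    scaling = float(ds.DoseGridScaling) * unit_factor
    values = ds.pixel_array.astype(np.float64) * scaling
    ipp = [float(v) for v in ds.ImagePositionPatient]  # (x, y, z)
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)  # (y, x)
    grid = Grid(
        shape=values.shape,
        spacing_mm=(float(dz[0]), row_sp, col_sp),
        origin_mm=(ipp[2] + offsets[0], ipp[1], ipp[0]),
    )
    return DoseGrid(values=values, grid=grid)


def _base_dataset(sop_class: str, modality: str) -> Dataset:
    file_meta = FileMetaDataset()
    file_meta.MediaStorageSOPClassUID = sop_class
    file_meta.MediaStorageSOPInstanceUID = generate_uid()
    file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = file_meta
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = file_meta.MediaStorageSOPInstanceUID
    ds.Modality = modality
    ds.PatientName = "Phantom^Synthetic"
    ds.PatientID = "DOSETEX"
    now = datetime.datetime(2000, 1, 1)
    ds.ContentDate = now.strftime("%Y%m%d")
    ds.ContentTime = now.strftime("%H%M%S")
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = generate_uid()
    return ds


def write_rtdose(dose: DoseGrid, path: Union[str, Path]) -> None:
    """Write a standards-conformant RT-Dose file (quantisation <= 0.001 Gy)."""
    max_dose = dose.max()
    scaling = max_dose / (2**32 - 1) if max_dose > 0 else 1.0
    scaling = max(scaling, 1e-9)
    if max_dose / scaling > 2**32 - 1:
        raise ValueError("dose exceeds the representable range")
    stored = np.round(dose.values / scaling).astype(np.uint32)

    ds = _base_dataset(RTDOSE_SOP_CLASS, "RTDOSE")
    nz, ny, nx = dose.grid.shape
    sz, sy, sx = dose.grid.spacing_mm
    oz, oy, ox = dose.grid.origin_mm
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.NumberOfFrames = nz
    ds.Rows = ny
    ds.Columns = nx
    ds.PixelSpacing = [sy, sx]
    ds.ImagePositionPatient = [ox, oy, oz]
    ds.ImageOrientationPatient = _AXIAL_ORIENTATION
    ds.GridFrameOffsetVector = [i * sz for i in range(nz)]
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.PixelData = stored.tobytes()
    ds.save_as(str(path), enforce_file_format=True)


# --------------------------------------------------------------------------
# RT Structure Set
# --------------------------------------------------------------------------

def read_rtstruct(path: Union[str, Path]) -> ContourSet:
    """Read an RT Structure Set into planar polygon contours."""
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", None) != "RTSTRUCT":
        raise DicomFormatError(
            f"expected RTSTRUCT modality, got {getattr(ds, 'Modality', None)!r}"
        )
    names = {}
    for roi in getattr(ds, "StructureSetROISequence", []):
        names[int(roi.ROINumber)] = str(roi.ROIName)

    out = ContourSet()
    for roi_contour in getattr(ds, "ROIContourSequence", []):
        number = int(roi_contour.ReferencedROINumber)
        name = names.get(number, f"ROI_{number}")
        contours: List[Contour] = []
        for item in getattr(roi_contour, "ContourSequence", []):
            data = np.asarray([float(v) for v in item.ContourData]).reshape(-1, 3)
            if len(data) < 3:
                continue
            contours.append(Contour(vertices=data, plane_z_mm=float(data[0, 2])))
        if not contours:
            out.warnings.append(f"ROI {name!r} has no contours")
        out.rois[name] = contours
        out.roi_numbers[name] = number
    return out


def _mask_to_contours(roi: RoiMask) -> List[Contour]:
    """Planar closed polygons from mask slice boundaries (marching squares)."""
    grid = roi.grid
    sz, sy, sx = grid.spacing_mm
    oz, oy, ox = grid.origin_mm
    contours: List[Contour] = []
    for k in range(grid.shape[0]):
        sl = roi.mask[k]
        if not sl.any():
            continue
        z = oz + k * sz
        for poly in measure.find_contours(sl.astype(float), 0.5):
            if len(poly) < 3:
                continue
            # poly rows are (y_index, x_index); drop the closing duplicate
            if np.allclose(poly[0], poly[-1]):
                poly = poly[:-1]
            if len(poly) < 3:
                continue
            verts = np.column_stack(
                [ox + poly[:, 1] * sx, oy + poly[:, 0] * sy, np.full(len(poly), z)]
            )
            contours.append(Contour(vertices=verts, plane_z_mm=z))
    return contours


def write_rtstruct(
    structs: Union[StructureSet, ContourSet], path: Union[str, Path]
) -> None:
    """Write an RT Structure Set from masks (contoured slice-wise) or contours."""
    if isinstance(structs, StructureSet):
        contour_set = ContourSet()
        for i, (name, roi) in enumerate(structs.rois.items(), start=1):
            contour_set.rois[name] = _mask_to_contours(roi)
            contour_set.roi_numbers[name] = i
    else:
        contour_set = structs

    ds = _base_dataset(RTSTRUCT_SOP_CLASS, "RTSTRUCT")
    ds.StructureSetLabel = "dosetex"
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for name, contours in contour_set.rois.items():
        number = contour_set.roi_numbers.get(name, len(ds.StructureSetROISequence) + 1)
        roi_item = Dataset()
        roi_item.ROINumber = number
        roi_item.ROIName = name
        roi_item.ReferencedFrameOfReferenceUID = ds.FrameOfReferenceUID
        roi_item.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(roi_item)

        rc = Dataset()
        rc.ReferencedROINumber = number
        rc.ContourSequence = []
        for contour in contours:
            item = Dataset()
            item.ContourGeometricType = "CLOSED_PLANAR"
            item.NumberOfContourPoints = len(contour.vertices)
            item.ContourData = [float(v) for v in contour.vertices.ravel()]
            rc.ContourSequence.append(item)
        ds.ROIContourSequence.append(rc)
    ds.save_as(str(path), enforce_file_format=True)


# --------------------------------------------------------------------------
# Internal array format
# --------------------------------------------------------------------------

def save_internal(dose: DoseGrid, path: Union[str, Path]) -> None:
    """Save a dose grid as a compressed array with a JSON geometry sidecar."""
    path = Path(path)
    np.savez_compressed(path.with_suffix(".npz"), values=dose.values)
    sidecar = {
        "shape": list(dose.grid.shape),
        "spacing_mm": list(dose.grid.spacing_mm),
        "origin_mm": list(dose.grid.origin_mm),
        "axis_order": dose.axis_order,
        "units": "Gy",
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_internal(path: Union[str, Path]) -> DoseGrid:
    """Exact round-trip counterpart of :func:`save_internal`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as data:
        values = data["values"]
    grid = Grid(
        shape=tuple(meta["shape"]),
        spacing_mm=tuple(meta["spacing_mm"]),
        origin_mm=tuple(meta["origin_mm"]),
    )
    return DoseGrid(values=values, grid=grid)
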