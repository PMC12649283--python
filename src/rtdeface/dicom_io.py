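"""Reading and writing DICOM CT series, RT Structure Sets and RT Dose.

Only the attributes the defacing pipeline needs are interpreted; stored
pixel values are never rescaled on read, and writing regenerates series
and SOP instance identifiers (optionally from a seed, for reproducible
output) while preserving the frame of reference so the defaced objects
remain spatially linked but do not collide with the originals.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .contours import DEFAULT_ROLE_PATTERNS, RoiContour, StructureSet, assign_role
from .geometry import DoseGrid, GeometryError, GridGeometry, ImageVolume

logger = logging.getLogger(__name__)

__all__ = ["read_ct_series", "read_structure_set", "read_dose", "write_outputs", "DicomIOError"]

CT_STORAGE = "1.2.840.10008.5.1.4.1.1.2"
RTSTRUCT_STORAGE = "1.2.840.10008.5.1.4.1.1.481.3"
RTDOSE_STORAGE = "1.2.840.10008.5.1.4.1.1.481.2"

_SLICE_GAP_TOL = 0.01  # mm, allowed deviation from uniform spacing


class DicomIOError(IOError):
    """Raised for malformed or unsupported DICOM inputs."""


def _uid(seed: int | None, tag: str) -> str:
    if seed is None:
        return generate_uid()
    return generate_uid(entropy_srcs=[f"rtdeface-{seed}-{tag}"])


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_ct_series(path: str | Path) -> ImageVolume:
    """Read a single-series axial CT directory into an :class:`ImageVolume`.

    Slices are sorted inferior to superior regardless of on-disk order.
    Raises :class:`DicomIOError` for mixed series, fewer than two slices,
    non-uniform slice gaps, or a non head-first-supine orientation.
    """
    path = Path(path)
    datasets = []
    for f in sorted(path.iterdir()):
        if not f.is_file():
            continue
        try:
            ds = pydicom.dcmread(f)
        except Exception:
            continue
        if getattr(ds, "SOPClassUID", None) == CT_STORAGE or getattr(ds, "Modality", "") == "CT":
            datasets.append(ds)
    if len(datasets) < 2:
        raise DicomIOError(f"insufficient slices: found {len(datasets)} CT slice(s) in {path}")
    series = {ds.SeriesInstanceUID for ds in datasets}
    if len(series) != 1:
        raise DicomIOError(f"mixed series in {path}: {sorted(series)}")

    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    first = datasets[0]
    orientation = tuple(float(v) for v in first.ImageOrientationPatient)
    if not np.allclose(orientation, (1, 0, 0, 0, 1, 0), atol=1e-4):
        raise DicomIOError(
            f"unsupported orientation {orientation}: only axis-aligned "
            "head-first-supine series are handled"
        )
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    gaps = np.diff(zs)
    if np.any(gaps <= 0):
        raise DicomIOError("duplicate or non-monotonic slice positions")
    if np.ptp(gaps) > _SLICE_GAP_TOL:
        raise DicomIOError(f"non-uniform slice gap: gaps range {gaps.min():.4f}..{gaps.max():.4f} mm")
    for ds in datasets:
        if not np.allclose(
            [float(v) for v in ds.ImagePositionPatient[:2]], first.ImagePositionPatient[:2], atol=1e-4
        ):
            raise DicomIOError("slices are not axially stacked (x/y origin varies)")

    pixels = np.stack([ds.pixel_array for ds in datasets], axis=-1)
    geometry = GridGeometry(
        origin=(
            float(first.ImagePositionPatient[0]),
            float(first.ImagePositionPatient[1]),
            float(zs[0]),
        ),
        pixel_spacing=(float(first.PixelSpacing[0]), float(first.PixelSpacing[1])),
        slice_positions=zs,
        rows=int(first.Rows),
        cols=int(first.Columns),
        orientation=orientation,
        frame_of_reference_id=str(first.FrameOfReferenceUID),
    )
    return ImageVolume(
        stored_values=pixels,
        geometry=geometry,
        rescale_slope=float(getattr(first, "RescaleSlope", 1.0)),
        rescale_intercept=float(getattr(first, "RescaleIntercept", 0.0)),
        bits_stored=int(getattr(first, "BitsStored", 16)),
        pixel_representation=int(getattr(first, "PixelRepresentation", 1)),
        series_id=str(first.SeriesInstanceUID),
        per_slice_instance_ids=tuple(str(ds.SOPInstanceUID) for ds in datasets),
    )


def read_structure_set(
    path: str | Path, name_config: dict[str, str] | None = None
) -> StructureSet:
    """Read an RT Structure Set, assigning each ROI a role by name.

    ``name_config`` maps role -> regex (case-insensitive substring
    search); defaults cover common clinical naming.  ROIs declared
    without contour data are kept with empty polygon lists (a warning is
    logged).
    """
    ds = pydicom.dcmread(path)
    if getattr(ds, "SOPClassUID", None) != RTSTRUCT_STORAGE and getattr(ds, "Modality", "") != "RTSTRUCT":
        raise DicomIOError(f"{path} is not an RT Structure Set")
    patterns = name_config if name_config is not None else DEFAULT_ROLE_PATTERNS

    names: dict[int, str] = {}
    frame_of_reference = ""
    for item in ds.StructureSetROISequence:
        names[int(item.ROINumber)] = str(item.ROIName)
        frame_of_reference = str(
            getattr(item, "ReferencedFrameOfReferenceUID", frame_of_reference)
        )

    contours: dict[int, list[np.ndarray]] = {n: [] for n in names}
    for item in getattr(ds, "ROIContourSequence", []):
        num = int(item.ReferencedROINumber)
        for c in getattr(item, "ContourSequence", []):
            data = np.asarray(c.ContourData, dtype=float).reshape(-1, 3)
            if data.shape[0] >= 3:
                contours.setdefault(num, []).append(data)

    rois = []
    for num, name in names.items():
        polys = contours.get(num, [])
        if not polys:
            logger.warning("ROI %r has no contour data; kept with empty polygons", name)
        rois.append(
            RoiContour(name=name, roi_number=num, role=assign_role(name, patterns), polygons=polys)
        )

    referenced_series = ""
    for ref_for in getattr(ds, "ReferencedFrameOfReferenceSequence", []):
        for study in getattr(ref_for, "RTReferencedStudySequence", []):
            for series in getattr(study, "RTReferencedSeriesSequence", []):
                referenced_series = str(series.SeriesInstanceUID)
    return StructureSet(
        rois=rois,
        referenced_frame_of_reference_id=frame_of_reference or str(getattr(ds, "FrameOfReferenceUID", "")),
        referenced_series_id=referenced_series,
    )


def read_dose(path: str | Path) -> DoseGrid:
    """Read an RT Dose file into physical units (Gy)."""
    ds = pydicom.dcmread(path)
    if getattr(ds, "SOPClassUID", None) != RTDOSE_STORAGE and getattr(ds, "Modality", "") != "RTDOSE":
        raise DicomIOError(f"{path} is not an RT Dose object")
    if "DoseGridScaling" not in ds:
        raise DicomIOError("RT Dose is missing DoseGridScaling")
    scaling = float(ds.DoseGridScaling)
    if scaling <= 0:
        raise DicomIOError(f"invalid DoseGridScaling {scaling}")
    frames = ds.pixel_array  # (frames, rows, cols)
    if frames.ndim != 3:
        raise DicomIOError("RT Dose must contain a 3D grid")
    dose = frames.astype(np.float64).transpose(1, 2, 0) * scaling
    offsets = np.asarray(ds.GridFrameOffsetVector, dtype=float)
    z0 = float(ds.ImagePositionPatient[2])
    geometry = GridGeometry(
        origin=(float(ds.ImagePositionPatient[0]), float(ds.ImagePositionPatient[1]), z0),
        pixel_spacing=(float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1])),
        slice_positions=z0 + offsets,
        rows=int(ds.Rows),
        cols=int(ds.Columns),
        orientation=tuple(float(v) for v in ds.ImageOrientationPatient),
        frame_of_reference_id=str(ds.FrameOfReferenceUID),
    )
    return DoseGrid(dose_values=dose, geometry=geometry)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _file_meta(sop_class: str, sop_instance: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_instance
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def _common_tags(ds: Dataset, seed: int | None) -> None:
    ds.PatientName = "Phantom^Synthetic"
    ds.PatientID = "RTDEFACE"
    ds.StudyInstanceUID = _uid(seed, "study")
    ds.StudyID = "1"
    ds.StudyDate = "20200101"
    ds.StudyTime = "000000"
    ds.AccessionNumber = ""
    ds.ReferringPhysicianName = ""
    ds.PatientBirthDate = ""
    ds.PatientSex = "O"


def write_outputs(
    volume: ImageVolume,
    ss: StructureSet | None,
    dose: DoseGrid | None,
    path: str | Path,
    seed: int | None = None,
) -> dict[str, list[str]]:
    """Write a CT series plus optional RTSTRUCT / RTDOSE to a directory.

    Fresh series and SOP instance identifiers are generated (derived from
    ``seed`` when given, so repeat runs are bit-identical); the frame of
    reference and all geometry are preserved, and the structure set's
    image references point at the freshly written CT instances.

    Returns a mapping of object kind to the written file names.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if ss is not None and ss.referenced_frame_of_reference_id != volume.frame_of_reference_id:
        raise DicomIOError("structure set frame of reference does not match CT")
    if dose is not None and dose.frame_of_reference_id != volume.frame_of_reference_id:
        raise DicomIOError("dose frame of reference does not match CT")

    written: dict[str, list[str]] = {"ct": [], "rtstruct": [], "rtdose": []}
    geom = volume.geometry
    series_uid = _uid(seed, "ct-series")
    slice_uids = [_uid(seed, f"ct-{k}") for k in range(geom.n_slices)]

    dtype = np.int16 if volume.pixel_representation == 1 else np.uint16
    for k in range(geom.n_slices):
        ds = Dataset()
        ds.file_meta = _file_meta(CT_STORAGE, slice_uids[k])
        _common_tags(ds, seed)
        ds.SOPClassUID = CT_STORAGE
        ds.SOPInstanceUID = slice_uids[k]
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.SeriesNumber = 1
        ds.InstanceNumber = k + 1
        ds.FrameOfReferenceUID = geom.frame_of_reference_id
        ds.PositionReferenceIndicator = ""
        ds.ImageOrientationPatient = [float(v) for v in geom.orientation]
        ds.ImagePositionPatient = [
            geom.origin[0],
            geom.origin[1],
            float(geom.slice_positions[k]),
        ]
        ds.PixelSpacing = [geom.pixel_spacing[0], geom.pixel_spacing[1]]
        ds.SliceThickness = geom.slice_gap
        ds.Rows = geom.rows
        ds.Columns = geom.cols
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = volume.bits_stored
        ds.HighBit = volume.bits_stored - 1
        ds.PixelRepresentation = volume.pixel_representation
        ds.RescaleSlope = volume.rescale_slope
        ds.RescaleIntercept = volume.rescale_intercept
        ds.RescaleType = "HU"
        ds.PixelData = np.ascontiguousarray(volume.stored_values[:, :, k], dtype=dtype).tobytes()
        fname = f"ct_{k:04d}.dcm"
        ds.save_as(path / fname, enforce_file_format=True)
        written["ct"].append(fname)

    if ss is not None:
        fname = "rtstruct.dcm"
        _write_structure_set(ss, geom, series_uid, slice_uids, path / fname, seed)
        written["rtstruct"].append(fname)
    if dose is not None:
        fname = "rtdose.dcm"
        _write_dose(dose, path / fname, seed)
        written["rtdose"].append(fname)
    return written


def _write_structure_set(
    ss: StructureSet,
    ct_geom: GridGeometry,
    ct_series_uid: str,
    ct_slice_uids: list[str],
    out_path: Path,
    seed: int | None,
) -> None:
    ds = Dataset()
    sop_uid = _uid(seed, "rtstruct")
    ds.file_meta = _file_meta(RTSTRUCT_STORAGE, sop_uid)
    _common_tags(ds, seed)
    ds.SOPClassUID = RTSTRUCT_STORAGE
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTSTRUCT"
    ds.SeriesInstanceUID = _uid(seed, "rtstruct-series")
    ds.SeriesNumber = 2
    ds.StructureSetLabel = "Defaced" if seed is not None else "StructureSet"
    ds.StructureSetDate = "20200101"
    ds.StructureSetTime = "000000"

    contour_image_items = []
    for uid in ct_slice_uids:
        item = Dataset()
        item.ReferencedSOPClassUID = CT_STORAGE
        item.ReferencedSOPInstanceUID = uid
        contour_image_items.append(item)
    series_item = Dataset()
    series_item.SeriesInstanceUID = ct_series_uid
    series_item.ContourImageSequence = contour_image_items
    study_item = Dataset()
    study_item.ReferencedSOPClassUID = "1.2.840.10008.3.1.2.3.1"
    study_item.ReferencedSOPInstanceUID = _uid(seed, "study")
    study_item.RTReferencedSeriesSequence = [series_item]
    for_item = Dataset()
    for_item.FrameOfReferenceUID = ss.referenced_frame_of_reference_id
    for_item.RTReferencedStudySequence = [study_item]
    ds.ReferencedFrameOfReferenceSequence = [for_item]

    roi_seq, contour_seq, obs_seq = [], [], []
    for roi in ss.rois:
        item = Dataset()
        item.ROINumber = roi.roi_number
        item.ROIName = roi.name
        item.ReferencedFrameOfReferenceUID = ss.referenced_frame_of_reference_id
        item.ROIGenerationAlgorithm = "AUTOMATIC"
        roi_seq.append(item)

        citem = Dataset()
        citem.ReferencedROINumber = roi.roi_number
        contour_items = []
        for poly in roi.polygons:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            c.NumberOfContourPoints = poly.shape[0]
            c.ContourData = [float(v) for v in poly.ravel()]
            k = ct_geom.slice_index_of(float(poly[0, 2]))
            if k is not None:
                img = Dataset()
                img.ReferencedSOPClassUID = CT_STORAGE
                img.ReferencedSOPInstanceUID = ct_slice_uids[k]
                c.ContourImageSequence = [img]
            contour_items.append(c)
        citem.ContourSequence = contour_items
        contour_seq.append(citem)

        oitem = Dataset()
        oitem.ObservationNumber = roi.roi_number
        oitem.ReferencedROINumber = roi.roi_number
        oitem.ROIObservationLabel = roi.name
        oitem.RTROIInterpretedType = "PTV" if roi.role == "ptv" else "ORGAN"
        oitem.ROIInterpreter = ""
        obs_seq.append(oitem)

    ds.StructureSetROISequence = roi_seq
    ds.ROIContourSequence = contour_seq
    ds.RTROIObservationsSequence = obs_seq
    ds.save_as(out_path, enforce_file_format=True)


def _write_dose(dose: DoseGrid, out_path: Path, seed: int | None) -> None:
    geom = dose.geometry
    max_dose = float(dose.dose_values.max())
    scaling = max_dose / (2**32 - 1) if max_dose > 0 else 1.0e-8
    stored = np.round(dose.dose_values / scaling).astype(np.uint32)

    ds = Dataset()
    sop_uid = _uid(seed, "rtdose")
    ds.file_meta = _file_meta(RTDOSE_STORAGE, sop_uid)
    _common_tags(ds, seed)
    ds.SOPClassUID = RTDOSE_STORAGE
    ds.SOPInstanceUID = sop_uid
    ds.Modality = "RTDOSE"
    ds.SeriesInstanceUID = _uid(seed, "rtdose-series")
    ds.SeriesNumber = 3
    ds.InstanceNumber = 1
    ds.FrameOfReferenceUID = geom.frame_of_reference_id
    ds.PositionReferenceIndicator = ""
    ds.ImageOrientationPatient = [float(v) for v in geom.orientation]
    ds.ImagePositionPatient = [geom.origin[0], geom.origin[1], float(geom.slice_positions[0])]
    ds.PixelSpacing = [geom.pixel_spacing[0], geom.pixel_spacing[1]]
    ds.GridFrameOffsetVector = [float(z - geom.slice_positions[0]) for z in geom.slice_positions]
    ds.FrameIncrementPointer = pydicom.tag.Tag(0x3004, 0x000C)
    ds.NumberOfFrames = geom.n_slices
    ds.Rows = geom.rows
    ds.Columns = geom.cols
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.PixelData = np.ascontiguousarray(stored.transpose(2, 0, 1)).tobytes()
    ds.save_as(out_path, enforce_file_format=True)
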