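"""DICOM-RT reading and phantom fixture writing.

Readers return the package's in-memory grid/structure types; the writer
emits a minimal but standards-shaped CT series, RTSTRUCT and RTDOSE for a
phantom patient so the loading path can be exercised end to end.  The
dose may be written on a coarser lattice than the CT to exercise the
alignment/resampling step.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .volume import StructureSet, VoxelGrid

CT_SOP = "1.2.840.10008.5.1.4.1.1.2"
RTSTRUCT_SOP = "1.2.840.10008.5.1.4.1.1.481.3"
RTDOSE_SOP = "1.2.840.10008.5.1.4.1.1.481.2"

CT_INTERCEPT = -1024.0


def _base_dataset(path: Path, sop_class: str, sop_uid: str) -> FileDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = sop_uid
    return ds


def write_dicom_fixture(patient, directory, spacing_mm,
                        dose_grid_factor: int = 1) -> dict[str, list[Path]]:
    """Write a CT series, RTSTRUCT and RTDOSE for one phantom patient.

    ``dose_grid_factor`` > 1 writes the dose on a lattice coarser by that
    integer factor.  Returns the written paths by modality.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sp = tuple(float(s) for s in spacing_mm)
    ct = np.asarray(patient.ct_volume)
    series_uid = generate_uid()
    frame_uid = generate_uid()
    written = {"ct": [], "rtstruct": [], "rtdose": []}

    for k in range(ct.shape[0]):
        path = directory / f"ct_{k:03d}.dcm"
        ds = _base_dataset(path, CT_SOP, generate_uid())
        ds.Modality = "CT"
        ds.PatientID = patient.patient_id
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [0.0, 0.0, k * sp[0]]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [sp[1], sp[2]]            # row (y), column (x)
        ds.SliceThickness = sp[0]
        ds.Rows, ds.Columns = ct.shape[1], ct.shape[2]
        ds.BitsAllocated = ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = CT_INTERCEPT
        stored = np.clip(np.rint(ct[k] - CT_INTERCEPT), 0, 65535).astype(np.uint16)
        ds.PixelData = stored.tobytes()
        ds.save_as(path, enforce_file_format=True)
        written["ct"].append(path)

    # RTSTRUCT with the three named ROIs
    path = directory / "rtstruct.dcm"
    ds = _base_dataset(path, RTSTRUCT_SOP, generate_uid())
    ds.Modality = "RTSTRUCT"
    ds.PatientID = patient.patient_id
    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for num, (name, entries) in enumerate(sorted(patient.structures.items()), start=1):
        roi = Dataset()
        roi.ROINumber = num
        roi.ROIName = name
        roi.ReferencedFrameOfReferenceUID = frame_uid
        ds.StructureSetROISequence.append(roi)
        rc = Dataset()
        rc.ReferencedROINumber = num
        rc.ContourSequence = []
        for z_mm, poly in entries:
            c = Dataset()
            c.ContourGeometricType = "CLOSED_PLANAR"
            pts = np.asarray(poly, dtype=float)
            c.NumberOfContourPoints = len(pts)
            data = np.column_stack([pts[:, 0], pts[:, 1],
                                    np.full(len(pts), float(z_mm))])
            c.ContourData = [f"{v:.4f}" for v in data.ravel()]
            rc.ContourSequence.append(c)
        ds.ROIContourSequence.append(rc)
    ds.save_as(path, enforce_file_format=True)
    written["rtstruct"].append(path)

    # RTDOSE, optionally on a coarser lattice
    f = int(dose_grid_factor)
    dose = np.asarray(patient.dose_volume)[::f, ::f, ::f]
    dose_sp = (sp[0] * f, sp[1] * f, sp[2] * f)
    path = directory / "rtdose.dcm"
    ds = _base_dataset(path, RTDOSE_SOP, generate_uid())
    ds.Modality = "RTDOSE"
    ds.PatientID = patient.patient_id
    ds.DoseUnits = "GY"
    ds.DoseSummationType = "PLAN"
    scaling = float(dose.max()) / (2 ** 31) if dose.max() > 0 else 1e-6
    scaling = max(scaling, 1e-6)
    stored = np.rint(dose / scaling).astype(np.uint32)
    ds.DoseGridScaling = scaling
    ds.NumberOfFrames = dose.shape[0]
    ds.GridFrameOffsetVector = [k * dose_sp[0] for k in range(dose.shape[0])]
    ds.ImagePositionPatient = [0.0, 0.0, 0.0]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [dose_sp[1], dose_sp[2]]
    ds.Rows, ds.Columns = dose.shape[1], dose.shape[2]
    ds.BitsAllocated = ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = stored.tobytes()
    ds.save_as(path, enforce_file_format=True)
    written["rtdose"].append(path)
    return written


def load_ct_series(directory) -> VoxelGrid:
    """Load one CT series: slices sorted by axial position, values in HU."""
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir()
                   if p.suffix.lower() == ".dcm")
    slices = []
    for p in files:
        ds = pydicom.dcmread(p)
        if getattr(ds, "Modality", "") == "CT":
            slices.append(ds)
    if not slices:
        raise ValueError(f"no CT slices found in {directory}")
    uids = {s.SeriesInstanceUID for s in slices}
    if len(uids) != 1:
        raise ValueError(f"mixed CT series in {directory}: {sorted(uids)}")
    spacings = {tuple(float(v) for v in s.PixelSpacing) for s in slices}
    if len(spacings) != 1:
        raise ValueError(f"non-uniform in-plane spacing: {sorted(spacings)}")
    slices.sort(key=lambda s: float(s.ImagePositionPatient[2]))
    zs = np.array([float(s.ImagePositionPatient[2]) for s in slices])
    if len(zs) > 1:
        dz = np.diff(zs)
        modal = float(np.median(dz))
        gaps = np.where(dz > 1.5 * modal)[0]
        if gaps.size:
            g = gaps[0]
            raise ValueError(
                f"missing CT slices: gap of {dz[g]:.2f} mm between z={zs[g]:.2f} "
                f"and z={zs[g + 1]:.2f} (modal spacing {modal:.2f} mm)")
        slice_sp = modal
    else:
        slice_sp = float(getattr(slices[0], "SliceThickness", 1.0))
    vol = np.stack([
        s.pixel_array.astype(np.float64) * float(s.RescaleSlope) + float(s.RescaleIntercept)
        for s in slices])
    row_sp, col_sp = next(iter(spacings))
    ipp = slices[0].ImagePositionPatient
    origin = (float(zs[0]), float(ipp[1]), float(ipp[0]))
    return VoxelGrid(vol, (slice_sp, row_sp, col_sp), origin)


def load_dose_grid(path) -> VoxelGrid:
    """Load an RTDOSE grid; values in Gy."""
    ds = pydicom.dcmread(path)
    if "DoseGridScaling" not in ds:
        raise ValueError("RTDOSE missing DoseGridScaling")
    arr = ds.pixel_array
    if arr.size == 0:
        raise ValueError("empty dose grid")
    if arr.ndim == 2:
        arr = arr[None]
    vals = arr.astype(np.float64) * float(ds.DoseGridScaling)
    offsets = [float(v) for v in ds.GridFrameOffsetVector]
    dz = offsets[1] - offsets[0] if len(offsets) > 1 else 1.0
    row_sp, col_sp = (float(v) for v in ds.PixelSpacing)
    ipp = ds.ImagePositionPatient
    origin = (float(ipp[2]) + offsets[0], float(ipp[1]), float(ipp[0]))
    return VoxelGrid(vals, (dz, row_sp, col_sp), origin)


def load_structure_set(path) -> StructureSet:
    """Load an RTSTRUCT into named planar contours."""
    ds = pydicom.dcmread(path)
    names = {int(r.ROINumber): str(r.ROIName) for r in ds.StructureSetROISequence}
    contours: dict[str, list] = {}
    for rc in ds.ROIContourSequence:
        name = names[int(rc.ReferencedROINumber)]
        entries = []
        for c in getattr(rc, "ContourSequence", []):
            data = np.asarray([float(v) for v in c.ContourData]).reshape(-1, 3)
            entries.append((float(data[0, 2]), data[:, :2].copy()))
        contours[name] = entries
    return StructureSet(contours)
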