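"""DICOM series I/O and the in-memory volume container.

A series directory of single-frame CT or PET files is read into a
:class:`VolumeGrid`: the stored integer pixel values plus the geometry
(voxel spacing, origin, direction cosines) that places voxel centers in the
DICOM patient coordinate system, and the rescale mapping to physical units
(HU for CT, Bq/mL for PET).  Values are kept in stored units throughout the
pipeline; decay correction acts on the rescale slope, never on pixels.

Indexing convention: ``values[i, j, k]`` with ``i`` the column (along the
image row direction), ``j`` the row, ``k`` the slice.  Indices are 0-based
and address voxel centers, so

    patient(i, j, k) = origin + orientation @ (spacing * (i, j, k))

with ``orientation`` columns being the row, column and slice-normal
direction cosines.  Feet-first and head-first acquisitions land in the same
patient frame because the transformation above uses each series' own
orientation tags, and slices are sorted by their position along the normal.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

__all__ = [
    "VolumeGrid",
    "SeriesMeta",
    "DicomReadError",
    "DicomWriteError",
    "read_series",
    "write_series",
    "write_stitched_series",
    "voxel_to_patient",
    "patient_to_voxel",
]

CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"
PET_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.128"

#: Maximum slice-interval spread tolerated within one series (mm).
SLICE_SPACING_TOL = 0.01

_DT_FMT = "%Y%m%d%H%M%S.%f"


class DicomReadError(RuntimeError):
    """A series directory could not be read into a consistent volume."""


class DicomWriteError(RuntimeError):
    """A volume could not be encoded as a DICOM series."""


@dataclass
class VolumeGrid:
    """A 3D scalar image with its patient-space geometry.

    Attributes
    ----------
    values : (ni, nj, nk) integer array
        Stored pixel values (pre-rescale), indexed (column, row, slice).
    spacing : (3,) float
        Voxel spacing (dx, dy, dz) in mm along the three index axes.
    origin : (3,) float
        Patient-space position (mm) of the center of voxel (0, 0, 0).
    orientation : (3, 3) float
        Direction-cosine matrix; columns are the unit vectors of the three
        index axes in patient space (orthonormal).
    modality : str
        "CT" or "PT".
    slope, intercept :
        Rescale mapping stored -> physical.  ``slope`` may be a scalar or a
        per-slice array of length nk (the stitched output carries different
        slopes above and below the seam).
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray
    modality: str = "CT"
    slope: float | np.ndarray = 1.0
    intercept: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.orientation = np.asarray(self.orientation, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3D array")
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.allclose(
            self.orientation.T @ self.orientation, np.eye(3), atol=1e-6
        ):
            raise ValueError("orientation must be orthonormal within 1e-6")
        if np.ndim(self.slope) == 1 and len(np.asarray(self.slope)) != self.shape[2]:
            raise ValueError("per-slice slope must have one entry per slice")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def normal(self) -> np.ndarray:
        """Unit slice normal (third index axis) in patient space."""
        return self.orientation[:, 2]

    def voxel_to_patient(self, index) -> np.ndarray:
        """Continuous voxel index (..., 3) -> patient-space mm."""
        idx = np.asarray(index, dtype=float)
        return (idx * self.spacing) @ self.orientation.T + self.origin

    def patient_to_voxel(self, point) -> np.ndarray:
        """Patient-space mm (..., 3) -> continuous voxel index."""
        p = np.asarray(point, dtype=float)
        return ((p - self.origin) @ self.orientation) / self.spacing

    def slice_positions(self) -> np.ndarray:
        """Positions of the slice centers along the slice normal (mm)."""
        base = float(self.origin @ self.normal)
        return base + np.arange(self.shape[2]) * self.spacing[2]

    def slope_per_slice(self) -> np.ndarray:
        """Rescale slope as a length-nk vector regardless of storage form."""
        s = np.asarray(self.slope, dtype=float)
        if s.ndim == 0:
            return np.full(self.shape[2], float(s))
        return s

    def physical(self) -> np.ndarray:
        """Values in physical units (HU or Bq/mL), float64."""
        s = np.asarray(self.slope, dtype=float)
        if s.ndim == 0:
            return self.values * float(s) + self.intercept
        return self.values * s[None, None, :] + self.intercept


def voxel_to_patient(grid: VolumeGrid, index) -> np.ndarray:
    """Module-level convenience wrapper for :meth:`VolumeGrid.voxel_to_patient`."""
    return grid.voxel_to_patient(index)


def patient_to_voxel(grid: VolumeGrid, point) -> np.ndarray:
    return grid.patient_to_voxel(point)


@dataclass(frozen=True)
class SeriesMeta:
    """Series-level attributes needed for decay correction and tag edits."""

    modality: str
    reference_time: _dt.datetime
    rescale_slope: float | np.ndarray = 1.0
    rescale_intercept: float = 0.0
    half_life: float | None = None
    series_description: str = ""
    number_of_slices: int = 0
    study_uid: str = ""
    series_uid: str = ""
    frame_uid: str = ""
    patient_id: str = "PHANTOM"
    uid_entropy: str | None = None  # deterministic UID seed (generator output)


def _parse_dicom_datetime(ds: Dataset) -> _dt.datetime:
    for date_tag, time_tag in (
        ("SeriesDate", "SeriesTime"),
        ("AcquisitionDate", "AcquisitionTime"),
    ):
        d = getattr(ds, date_tag, None)
        t = getattr(ds, time_tag, None)
        if d and t:
            t = str(t)
            if "." not in t:
                t += ".0"
            return _dt.datetime.strptime(str(d) + t, _DT_FMT)
    raise DicomReadError("series carries no usable date/time tags")


def _required(ds: Dataset, name: str):
    value = getattr(ds, name, None)
    if value is None:
        raise DicomReadError(f"missing geometry tag {name}")
    return value


def read_series(directory) -> tuple[VolumeGrid, SeriesMeta]:
    """Read one single-frame-per-file DICOM series into a volume.

    Slices are sorted by the projection of ImagePositionPatient onto the
    slice normal, so the file naming order is irrelevant.  Raises
    :class:`DicomReadError` for mixed series, missing geometry tags, or a
    non-uniform slice interval.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file() and not p.name.startswith("."))
    if not files:
        raise DicomReadError(f"no files in {directory}")
    datasets = [pydicom.dcmread(str(p)) for p in files]

    series_uids = {ds.SeriesInstanceUID for ds in datasets}
    if len(series_uids) != 1:
        raise DicomReadError(f"directory mixes {len(series_uids)} series")

    iop = np.asarray(_required(datasets[0], "ImageOrientationPatient"), dtype=float)
    u, v = iop[:3], iop[3:]
    w = np.cross(u, v)
    positions = np.array(
        [np.asarray(_required(ds, "ImagePositionPatient"), float) for ds in datasets]
    )
    proj = positions @ w
    order = np.argsort(proj)
    datasets = [datasets[i] for i in order]
    positions = positions[order]
    proj = proj[order]

    if len(datasets) > 1:
        intervals = np.diff(proj)
        if intervals.max() - intervals.min() > SLICE_SPACING_TOL:
            raise DicomReadError(
                f"non-uniform slice spacing (spread "
                f"{intervals.max() - intervals.min():.4f} mm exceeds "
                f"{SLICE_SPACING_TOL} mm)"
            )
        dz = float(intervals.mean())
    else:
        ds0 = datasets[0]
        dz = float(
            getattr(ds0, "SpacingBetweenSlices", None)
            or getattr(ds0, "SliceThickness", 1.0)
        )

    pixel_spacing = np.asarray(_required(datasets[0], "PixelSpacing"), dtype=float)
    spacing = np.array([pixel_spacing[1], pixel_spacing[0], dz])

    values = np.stack([ds.pixel_array.T for ds in datasets], axis=2)
    slopes = np.array([float(getattr(ds, "RescaleSlope", 1.0)) for ds in datasets])
    intercepts = np.array([float(getattr(ds, "RescaleIntercept", 0.0)) for ds in datasets])
    if np.ptp(intercepts) > 0:
        raise DicomReadError("RescaleIntercept varies within the series")
    slope: float | np.ndarray
    slope = float(slopes[0]) if np.ptp(slopes) == 0 else slopes

    grid = VolumeGrid(
        values=values,
        spacing=spacing,
        origin=positions[0],
        orientation=np.column_stack([u, v, w]),
        modality=str(datasets[0].Modality),
        slope=slope,
        intercept=float(intercepts[0]),
    )

    half_life = None
    rph = getattr(datasets[0], "RadiopharmaceuticalInformationSequence", None)
    if rph:
        hl = getattr(rph[0], "RadionuclideHalfLife", None)
        if hl is not None:
            half_life = float(hl)

    meta = SeriesMeta(
        modality=grid.modality,
        reference_time=_parse_dicom_datetime(datasets[0]),
        rescale_slope=slope,
        rescale_intercept=float(intercepts[0]),
        half_life=half_life,
        series_description=str(getattr(datasets[0], "SeriesDescription", "")),
        number_of_slices=len(datasets),
        study_uid=str(datasets[0].StudyInstanceUID),
        series_uid=str(datasets[0].SeriesInstanceUID),
        frame_uid=str(getattr(datasets[0], "FrameOfReferenceUID", "")),
        patient_id=str(getattr(datasets[0], "PatientID", "")),
    )
    return grid, meta


def _uid(entropy: str | None, *parts) -> str:
    if entropy is None:
        return generate_uid()
    return generate_uid(entropy_srcs=[entropy + "/" + "/".join(str(p) for p in parts)])


def _fmt_datetime(t: _dt.datetime) -> tuple[str, str]:
    return t.strftime("%Y%m%d"), t.strftime("%H%M%S.%f")


def write_series(vol: VolumeGrid, meta: SeriesMeta, directory) -> list[Path]:
    """Write a volume as a directory of single-frame DICOM files.

    Stored values go out as signed 16-bit integers; a value outside that
    range raises :class:`DicomWriteError` with the slope that would fit.
    Returns the written file paths in slice order.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    peak = float(np.abs(vol.values).max()) if vol.values.size else 0.0
    if peak > 32767:
        phys_peak = peak * float(np.max(vol.slope_per_slice()))
        raise DicomWriteError(
            f"stored value {peak:.0f} overflows int16; increase RescaleSlope "
            f"to at least {phys_peak / 32767:.6g} to fit"
        )
    is_pet = meta.modality == "PT"
    sop_class = PET_SOP_CLASS if is_pet else CT_SOP_CLASS
    slopes = vol.slope_per_slice()
    date_str, time_str = _fmt_datetime(meta.reference_time)
    ni, nj, nk = vol.shape
    paths = []
    for k in range(nk):
        ds = Dataset()
        ds.SOPClassUID = sop_class
        ds.SOPInstanceUID = _uid(meta.uid_entropy, meta.series_uid, "sop", k)
        ds.Modality = meta.modality
        ds.PatientName = meta.patient_id
        ds.PatientID = meta.patient_id
        ds.StudyInstanceUID = meta.study_uid
        ds.SeriesInstanceUID = meta.series_uid
        ds.FrameOfReferenceUID = meta.frame_uid
        ds.SeriesDescription = meta.series_description
        ds.SeriesNumber = 1
        ds.InstanceNumber = k + 1
        ds.StudyDate = date_str
        ds.SeriesDate = date_str
        ds.AcquisitionDate = date_str
        ds.ContentDate = date_str
        ds.StudyTime = time_str
        ds.SeriesTime = time_str
        ds.AcquisitionTime = time_str
        ds.ContentTime = time_str

        ds.ImageOrientationPatient = [float(x) for x in np.r_[vol.orientation[:, 0], vol.orientation[:, 1]]]
        ds.ImagePositionPatient = [float(x) for x in vol.voxel_to_patient([0, 0, k])]
        ds.PixelSpacing = [float(vol.spacing[1]), float(vol.spacing[0])]
        ds.SliceThickness = float(vol.spacing[2])
        ds.SpacingBetweenSlices = float(vol.spacing[2])
        ds.SliceLocation = float(vol.voxel_to_patient([0, 0, k]) @ vol.normal)

        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.Rows = nj
        ds.Columns = ni
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        ds.RescaleSlope = float(slopes[k])
        ds.RescaleIntercept = float(vol.intercept)
        ds.RescaleType = "US" if is_pet else "HU"

        if is_pet:
            ds.Units = "BQML"
            ds.DecayCorrection = "START"
            ds.ImageIndex = k + 1
            ds.NumberOfSlices = nk
            if meta.half_life is not None:
                rph = Dataset()
                rph.Radiopharmaceutical = "Fluorodeoxyglucose"
                rph.RadionuclideHalfLife = float(meta.half_life)
                ds.RadiopharmaceuticalInformationSequence = [rph]

        arr = np.ascontiguousarray(vol.values[:, :, k].T.astype(np.int16))
        ds.PixelData = arr.tobytes()

        file_meta = FileMetaDataset()
        file_meta.MediaStorageSOPClassUID = sop_class
        file_meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
        file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds.file_meta = file_meta

        path = directory / f"slice_{k + 1:04d}.dcm"
        pydicom.dcmwrite(str(path), ds, enforce_file_format=True)
        paths.append(path)
    return paths


def write_stitched_series(
    vol: VolumeGrid,
    template_meta: SeriesMeta,
    directory,
    series_description: str = "Whole-body stitched",
    uid_entropy: str | None = None,
) -> tuple[list[Path], SeriesMeta]:
    """Write the stitched volume with the tag edits the whole-body set needs.

    SliceLocation follows the (strictly monotonic, uniformly spaced) output
    slice positions; InstanceNumber and ImageIndex run consecutively from 1
    over the whole set; NumberOfSlices is the actual output slice count; the
    series description is uniform; the study UID is inherited from the
    template while series and instance UIDs are freshly generated so the
    output never collides with the inputs.  Per-slice RescaleSlope values
    (upper-segment slope above the seam, decay-corrected lower-segment slope
    at and below it) are taken from ``vol.slope``.
    """
    entropy = uid_entropy or template_meta.uid_entropy
    series_uid = _uid(entropy, template_meta.study_uid, "stitched", vol.modality)
    meta = replace(
        template_meta,
        series_uid=series_uid,
        series_description=series_description,
        number_of_slices=vol.shape[2],
        rescale_slope=vol.slope,
        rescale_intercept=vol.intercept,
        uid_entropy=entropy,
    )
    paths = write_series(vol, meta, directory)
    return paths, meta
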