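"""Reading and writing 4D dynamic contrast-enhanced MRI data.

A dynamic study is held in memory as a :class:`DceSeries`: a 4D array
indexed ``(t, z, y, x)`` where ``t`` runs over the dynamic acquisitions
(``t = 0`` is the precontrast scan) and ``z`` over the axial slices.
Series can be assembled from a DICOM series directory or from a 4D
NIfTI-1 file; analysis results are written as a JSON report plus
portable grayscale images.

Indexing is 0-based internally; every value surfaced in a report is
1-based (the first dynamic acquisition is reported as ``t = 1``).
"""

from __future__ import annotations

import dataclasses
import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

__all__ = [
    "DceSeries",
    "AnalysisReport",
    "read_dicom_series",
    "read_nifti_4d",
    "write_nifti_4d",
    "write_dicom_series",
    "write_report",
]

#: SOP class used for phantom exports (secondary capture).
_SC_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.7"


@dataclass
class DceSeries:
    """A 4D dynamic series: ``data[t, z, y, x]`` with t the acquisition index.

    Parameters
    ----------
    data
        Nonnegative finite intensities, shape ``(T, Z, Y, X)`` with ``T >= 2``.
        ``t = 0`` is the precontrast acquisition.
    voxel_spacing
        Optional ``(dz, dy, dx)`` in millimetres.
    acquisition_order
        Optional per-acquisition source identifiers (e.g. DICOM
        AcquisitionNumbers) in temporal order.
    patient_id
        Optional identifier carried through to reports.
    """

    data: np.ndarray
    voxel_spacing: tuple[float, float, float] | None = None
    acquisition_order: list[str] | None = None
    patient_id: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(
                f"DceSeries requires a 4D (t, z, y, x) array, got ndim={self.data.ndim}"
            )
        if self.data.shape[0] < 2:
            raise ValueError(
                f"a dynamic series needs at least 2 acquisitions, got {self.data.shape[0]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("series intensities must be finite")
        if self.data.min() < 0:
            raise ValueError("series intensities must be nonnegative")

    @property
    def n_acquisitions(self) -> int:
        return self.data.shape[0]

    @property
    def n_slices(self) -> int:
        return self.data.shape[1]

    @property
    def slice_shape(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def with_data(self, data: np.ndarray) -> "DceSeries":
        """A copy of this series carrying ``data`` and the same metadata."""
        return dataclasses.replace(self, data=data)


@dataclass
class AnalysisReport:
    """Outcome of one pipeline run; all indices 1-based.

    ``peak_mean`` / ``peak_std`` are the peak statistics of the mean and
    standard-deviation synthetic images (see
    :mod:`dcegrad.synthesis_classify`), serialised as plain dicts.
    ``parameters`` embeds every threshold and mode the run used, so a
    report is sufficient to reproduce itself.
    """

    selected_acquisition: int
    selected_slice: int
    peak_mean: Mapping[str, Any]
    peak_std: Mapping[str, Any]
    decision: str
    parameters: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.decision not in ("normal", "abnormal"):
            raise ValueError(f"decision must be 'normal' or 'abnormal', got {self.decision!r}")
        if self.selected_acquisition < 1 or self.selected_slice < 1:
            raise ValueError("reported indices are 1-based and must be >= 1")
        both = bool(self.peak_mean["is_peak"]) and bool(self.peak_std["is_peak"])
        if (self.decision == "abnormal") != both:
            raise ValueError("decision inconsistent with the two peak statistics (AND rule)")

    def to_dict(self) -> dict[str, Any]:
        return {
            "selected_acquisition": self.selected_acquisition,
            "selected_slice": self.selected_slice,
            "peak_mean": dict(self.peak_mean),
            "peak_std": dict(self.peak_std),
            "decision": self.decision,
            "parameters": dict(self.parameters),
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AnalysisReport":
        return cls(
            selected_acquisition=int(d["selected_acquisition"]),
            selected_slice=int(d["selected_slice"]),
            peak_mean=dict(d["peak_mean"]),
            peak_std=dict(d["peak_std"]),
            decision=str(d["decision"]),
            parameters=dict(d.get("parameters", {})),
        )


# ---------------------------------------------------------------------------
# NIfTI


def read_nifti_4d(path: str | Path) -> DceSeries:
    """Load a 4D NIfTI file as a :class:`DceSeries`.

    The file's 4th dimension is taken as time and the spatial axes
    ``(x, y, z)`` are transposed to the internal ``(z, y, x)`` order.
    A 3D file is rejected (use :func:`read_dicom_series` for single-frame
    series directories).
    """
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 4:
        raise ValueError(
            f"{path}: expected a 4D image (x, y, z, t), got ndim={arr.ndim}; "
            "for a directory of 2D DICOM slices use read_dicom_series"
        )
    data = np.transpose(arr, (3, 2, 1, 0)).astype(np.float64)
    zooms = img.header.get_zooms()
    spacing = None
    if len(zooms) >= 3:
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    return DceSeries(data=data, voxel_spacing=spacing)


def write_nifti_4d(series: DceSeries, path: str | Path) -> Path:
    """Write a series as a 4D NIfTI-1 file with (x, y, z, t) axis order."""
    arr = np.transpose(series.data, (3, 2, 1, 0))
    dz, dy, dx = series.voxel_spacing or (1.0, 1.0, 1.0)
    affine = np.diag([dx, dy, dz, 1.0])
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms((dx, dy, dz, 1.0))
    path = Path(path)
    nib.save(img, str(path))
    return path


# ---------------------------------------------------------------------------
# DICOM


def _acquisition_key(ds: Dataset) -> tuple[int, str]:
    """Temporal grouping key for one DICOM slice, with fallbacks.

    Preference order: AcquisitionNumber, TemporalPositionIdentifier,
    AcquisitionTime. Raises ``ValueError`` listing the fallbacks tried if
    none is present.
    """
    for attr in ("AcquisitionNumber", "TemporalPositionIdentifier"):
        value = getattr(ds, attr, None)
        if value is not None and str(value) != "":
            return int(value), attr
    value = getattr(ds, "AcquisitionTime", None)
    if value is not None and str(value) != "":
        # Cluster by exact time string; sub-second jitter within one
        # acquisition is not modelled for secondary-capture exports.
        return int(float(value)), "AcquisitionTime"
    raise ValueError(
        "no temporal metadata on slice: tried AcquisitionNumber, "
        "TemporalPositionIdentifier, AcquisitionTime"
    )


def _slice_position(ds: Dataset) -> float | None:
    """Position of the slice along the stack normal, if geometry is present."""
    ipp = getattr(ds, "ImagePositionPatient", None)
    iop = getattr(ds, "ImageOrientationPatient", None)
    if ipp is None:
        return None
    if iop is not None and len(iop) == 6:
        row = np.array(iop[:3], dtype=float)
        col = np.array(iop[3:], dtype=float)
        normal = np.cross(row, col)
        return float(np.dot(np.array(ipp, dtype=float), normal))
    return float(ipp[2])


def _slice_pixels(ds: Dataset) -> np.ndarray:
    """Decode one slice to float64, applying RescaleSlope/Intercept.

    Phantom exports store float64 samples in DoubleFloatPixelData so the
    write→read round trip is bit-exact; integer PixelData goes through
    pydicom's standard path.
    """
    if getattr(ds, "DoubleFloatPixelData", None) is not None:
        arr = np.frombuffer(ds.DoubleFloatPixelData, dtype="<f8")
        return arr.reshape(int(ds.Rows), int(ds.Columns)).copy()
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    return arr * slope + intercept


def read_dicom_series(directory: str | Path) -> DceSeries:
    """Assemble a 4D series from a directory of single-frame DICOM files.

    Slices are grouped into acquisitions by AcquisitionNumber (falling
    back to TemporalPositionIdentifier, then AcquisitionTime) and ordered
    within each acquisition by ImagePositionPatient projected on the
    slice normal (falling back to InstanceNumber). File names are
    ignored, so renaming or shuffling files does not change the volume.
    All acquisitions must agree in slice count and shape.
    """
    directory = Path(directory)
    datasets: list[Dataset] = []
    for p in sorted(directory.iterdir()):
        if not p.is_file():
            continue
        try:
            datasets.append(pydicom.dcmread(str(p)))
        except Exception:  # non-DICOM clutter is skipped
            continue
    if not datasets:
        raise ValueError(f"{directory}: no readable DICOM files")

    groups: dict[int, list[Dataset]] = defaultdict(list)
    for ds in datasets:
        key, _ = _acquisition_key(ds)
        groups[key].append(ds)

    acq_ids = sorted(groups)
    counts = {a: len(groups[a]) for a in acq_ids}
    if len(set(counts.values())) != 1:
        bad = max(acq_ids, key=lambda a: abs(counts[a] - np.median(list(counts.values()))))
        raise ValueError(
            f"unequal slice counts across acquisitions {counts}; "
            f"acquisition {bad} is inconsistent"
        )

    volumes = []
    for a in acq_ids:
        slices = groups[a]
        positions = [_slice_position(ds) for ds in slices]
        if all(p is not None for p in positions):
            order = np.argsort(positions, kind="stable")
        else:
            order = np.argsort([int(getattr(ds, "InstanceNumber", 0)) for ds in slices],
                               kind="stable")
        planes = [_slice_pixels(slices[i]) for i in order]
        shapes = {p.shape for p in planes}
        if len(shapes) != 1:
            raise ValueError(f"acquisition {a}: inconsistent slice shapes {shapes}")
        volumes.append(np.stack(planes))
    shapes = {v.shape for v in volumes}
    if len(shapes) != 1:
        bad = acq_ids[[v.shape for v in volumes].index(sorted(shapes)[-1])]
        raise ValueError(f"acquisition {bad}: slice geometry differs across acquisitions")

    ds0 = groups[acq_ids[0]][0]
    spacing = None
    ps = getattr(ds0, "PixelSpacing", None)
    st = getattr(ds0, "SliceThickness", None)
    if ps is not None and st is not None:
        spacing = (float(st), float(ps[0]), float(ps[1]))
    return DceSeries(
        data=np.stack(volumes),
        voxel_spacing=spacing,
        acquisition_order=[str(a) for a in acq_ids],
        patient_id=str(getattr(ds0, "PatientID", "")) or None,
    )


def write_dicom_series(
    series: DceSeries,
    directory: str | Path,
    patient_id: str = "PHANTOM",
) -> Path:
    """Write a series as one secondary-capture DICOM file per slice per acquisition.

    AcquisitionNumber (1-based t), InstanceNumber, ImagePositionPatient and
    ImageOrientationPatient are set so that :func:`read_dicom_series`
    reassembles the identical volume regardless of file naming. Samples
    are stored as float64 (DoubleFloatPixelData) to keep the round trip
    bit-exact.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    dz, dy, dx = series.voxel_spacing or (1.0, 1.0, 1.0)
    study_uid = generate_uid()
    series_uid = generate_uid()
    t_total, z_total = series.n_acquisitions, series.n_slices
    instance = 0
    for t in range(t_total):
        for z in range(z_total):
            instance += 1
            ds = Dataset()
            ds.file_meta = FileMetaDataset()
            ds.file_meta.MediaStorageSOPClassUID = _SC_SOP_CLASS
            ds.file_meta.MediaStorageSOPInstanceUID = generate_uid()
            ds.file_meta.TransferSyntaxUID = ExplicitVRLittleEndian
            ds.SOPClassUID = _SC_SOP_CLASS
            ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
            ds.StudyInstanceUID = study_uid
            ds.SeriesInstanceUID = series_uid
            ds.Modality = "MR"
            ds.PatientID = patient_id
            ds.PatientName = patient_id
            ds.AcquisitionNumber = t + 1
            ds.TemporalPositionIdentifier = t + 1
            ds.InstanceNumber = instance
            ds.ImagePositionPatient = [0.0, 0.0, float(z) * dz]
            ds.ImageOrientationPatient = [1.0, 0.0, 0.0, 0.0, 1.0, 0.0]
            ds.PixelSpacing = [dy, dx]
            ds.SliceThickness = dz
            plane = np.ascontiguousarray(series.data[t, z], dtype="<f8")
            ds.Rows, ds.Columns = plane.shape
            ds.SamplesPerPixel = 1
            ds.PhotometricInterpretation = "MONOCHROME2"
            ds.BitsAllocated = 64
            ds.DoubleFloatPixelData = plane.tobytes()
            ds.save_as(
                str(directory / f"t{t + 1:02d}_z{z + 1:04d}.dcm"),
                enforce_file_format=True,
            )
    return directory


# ---------------------------------------------------------------------------
# Reports


def _to_uint8(image: np.ndarray) -> np.ndarray:
    lo, hi = float(np.min(image)), float(np.max(image))
    if hi <= lo:
        return np.zeros(image.shape, dtype=np.uint8)
    return np.round((image - lo) / (hi - lo) * 255.0).astype(np.uint8)


def write_report(
    report: AnalysisReport,
    out_dir: str | Path,
    mean_image: np.ndarray | None = None,
    std_image: np.ndarray | None = None,
    selected_slice_image: np.ndarray | None = None,
) -> dict[str, Path]:
    """Write the report JSON plus grayscale PNG renderings of the images.

    Returns a mapping from artefact name to written path.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise ValueError(f"cannot create output directory {out_dir}: {exc}") from exc
    paths: dict[str, Path] = {}
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report.to_dict(), indent=2, sort_keys=True))
    paths["report"] = report_path
    for name, image in (
        ("mean_image", mean_image),
        ("std_image", std_image),
        ("selected_slice", selected_slice_image),
    ):
        if image is None:
            continue
        p = out_dir / f"{name}.png"
        iio.imwrite(p, _to_uint8(np.asarray(image)))
        paths[name] = p
    return paths
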