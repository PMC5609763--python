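"""DICOM import, CSI geometry, and the plain-text fixture format.

Three layers:

* :func:`scan_dicom_tree` walks a directory (including ``DICOMDIR``
  indexes) into a study -> series -> instance hierarchy, with a persistent
  per-directory cache in the system temp directory so warm rescans only
  re-read files whose size or mtime changed.
* :func:`read_spectroscopy` loads a Siemens MR spectroscopy file: the
  private CSA header block (CSA1 or CSA2) supplies dwell time, transmitter
  frequency and the number of spectral points; the private data element
  holds the complex FID samples as interleaved 32-bit floats.  Single
  voxels come back as :class:`~amaresfit.spectral_model.FidSeries`, CSI
  acquisitions as a :class:`CsiGrid` with full voxel geometry.
* :func:`read_fixture` / :func:`write_fixture` implement a versioned
  structured-text (JSON) format carrying the same information at full
  precision, so the entire test surface runs without any DICOM file.

:func:`write_synthetic_dicom` writes a *synthetic* Siemens-style
spectroscopy DICOM (CSA2 headers, float32 sample encoding) for round-trip
testing; it is a fixture generator, not an exporter of scanner data.
"""

from __future__ import annotations

import base64
import hashlib
import json
import logging
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.errors import InvalidDicomError
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .csa import build_csa2, csa_scalar, parse_csa
from .errors import NotSpectroscopyError, SchemaError, ValidationError
from .spectral_model import FidSeries

__all__ = [
    "CsiGeometry", "CsiGrid", "DicomTree", "Study", "Series", "Instance",
    "scan_dicom_tree", "read_spectroscopy", "voxel_to_patient",
    "read_fixture", "write_fixture", "write_synthetic_dicom",
    "write_synthetic_localizer",
]

logger = logging.getLogger(__name__)

FIXTURE_SCHEMA_VERSION = 1
TREE_CACHE_SCHEMA_VERSION = 1

MR_SPECTROSCOPY_SOP = "1.2.840.10008.5.1.4.1.1.4.2"
MR_IMAGE_SOP = "1.2.840.10008.5.1.4.1.1.4"

_CSA_CREATOR_TAG = (0x0029, 0x0010)
_CSA_IMAGE_TAG = (0x0029, 0x1010)
_CSA_SERIES_TAG = (0x0029, 0x1020)
_DATA_CREATOR_TAG = (0x7FE1, 0x0010)
_DATA_TAG = (0x7FE1, 0x1010)


# ---------------------------------------------------------------------------
# CSI geometry
# ---------------------------------------------------------------------------

@dataclass
class CsiGeometry:
    """Voxel-grid geometry in patient coordinates (mm).

    ``position`` is the centre of voxel (0, 0, 0); ``row_dir``, ``col_dir``
    and ``slice_dir`` are unit vectors along increasing i, j, k voxel
    indices; ``voxel_size`` are the step sizes (mm) along each.
    """

    position: np.ndarray
    row_dir: np.ndarray
    col_dir: np.ndarray
    slice_dir: np.ndarray
    voxel_size: np.ndarray

    def __post_init__(self):
        for name in ("position", "row_dir", "col_dir", "slice_dir", "voxel_size"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        dirs = np.stack([self.row_dir, self.col_dir, self.slice_dir])
        if not np.allclose(dirs @ dirs.T, np.eye(3), atol=1e-6):
            raise ValidationError("orientation vectors must be orthonormal")
        if np.any(self.voxel_size <= 0):
            raise ValidationError("voxel sizes must be positive")

    @property
    def affine(self) -> np.ndarray:
        """4x4 homogeneous map: voxel index (i, j, k, 1) -> patient mm."""
        m = np.eye(4)
        m[:3, 0] = self.row_dir * self.voxel_size[0]
        m[:3, 1] = self.col_dir * self.voxel_size[1]
        m[:3, 2] = self.slice_dir * self.voxel_size[2]
        m[:3, 3] = self.position
        return m


@dataclass
class CsiGrid:
    """A chemical-shift-imaging acquisition: one FID per voxel.

    Voxels are indexed 0-based as ``(i, j, k)`` with flat (row-major)
    order ``(k * ny + j) * nx + i`` — i varies fastest.
    """

    dims: tuple[int, int, int]
    fids: list[FidSeries]
    geometry: CsiGeometry

    def __post_init__(self):
        nx, ny, nz = self.dims
        if len(self.fids) != nx * ny * nz:
            raise ValidationError(
                f"grid {self.dims} needs {nx * ny * nz} FIDs, got {len(self.fids)}")

    @property
    def n_voxels(self) -> int:
        return len(self.fids)

    def flat_index(self, index: tuple[int, int, int]) -> int:
        i, j, k = index
        nx, ny, nz = self.dims
        if not (0 <= i < nx and 0 <= j < ny and 0 <= k < nz):
            raise ValidationError(f"voxel index {index} outside dims {self.dims}")
        return (k * ny + j) * nx + i

    def voxel(self, index: tuple[int, int, int]) -> FidSeries:
        return self.fids[self.flat_index(index)]

    def indices(self):
        """All voxel indices in flat order."""
        nx, ny, nz = self.dims
        for k in range(nz):
            for j in range(ny):
                for i in range(nx):
                    yield (i, j, k)


def voxel_to_patient(grid: CsiGrid, index: tuple[int, int, int]) -> np.ndarray:
    """Patient-space coordinates (mm) of a voxel centre."""
    grid.flat_index(index)  # bounds check
    g = grid.geometry
    i, j, k = index
    return (g.position + i * g.voxel_size[0] * g.row_dir
            + j * g.voxel_size[1] * g.col_dir
            + k * g.voxel_size[2] * g.slice_dir)


# ---------------------------------------------------------------------------
# Plain-text fixture format
# ---------------------------------------------------------------------------

_FID_FIELDS = ("dwell_time", "dead_time", "transmitter_freq",
               "reference_shift", "nucleus")


def _fid_to_doc(fid: FidSeries) -> dict:
    doc = {name: getattr(fid, name) for name in _FID_FIELDS}
    doc["n_points"] = fid.n
    if fid.samples is not None:
        doc["samples_b64"] = base64.b64encode(
            np.ascontiguousarray(fid.samples, dtype="<c16").tobytes()).decode()
    return doc


def _fid_from_doc(doc: dict, where: str) -> FidSeries:
    for name in _FID_FIELDS + ("n_points",):
        if name not in doc:
            raise SchemaError(f"{where}: missing required field {name!r}")
    samples = None
    if "samples_b64" in doc:
        samples = np.frombuffer(
            base64.b64decode(doc["samples_b64"]), dtype="<c16").copy()
        if samples.size != doc["n_points"]:
            raise SchemaError(
                f"{where}: samples_b64 holds {samples.size} points, "
                f"n_points says {doc['n_points']}")
    return FidSeries(samples=samples, n_points=doc["n_points"],
                     **{name: doc[name] for name in _FID_FIELDS})


def write_fixture(path: str | Path, obj: FidSeries | CsiGrid,
                  truth: dict | None = None) -> None:
    """Write an FID or CSI grid (plus optional ground truth) as JSON.

    Samples are stored as base64-encoded little-endian complex128, so the
    round trip through :func:`read_fixture` is bit-exact.
    """
    doc: dict = {"format": "amaresfit-fixture",
                 "schema_version": FIXTURE_SCHEMA_VERSION}
    if isinstance(obj, CsiGrid):
        g = obj.geometry
        doc["kind"] = "csi"
        doc["grid"] = {
            "dims": list(obj.dims),
            "geometry": {
                "position": g.position.tolist(),
                "row_dir": g.row_dir.tolist(),
                "col_dir": g.col_dir.tolist(),
                "slice_dir": g.slice_dir.tolist(),
                "voxel_size": g.voxel_size.tolist(),
            },
            "fids": [_fid_to_doc(f) for f in obj.fids],
        }
    else:
        doc["kind"] = "fid"
        doc["fid"] = _fid_to_doc(obj)
    if truth is not None:
        doc["truth"] = truth
    Path(path).write_text(json.dumps(doc))


def read_fixture(path: str | Path):
    """Read a fixture file; returns ``(FidSeries | CsiGrid, truth | None)``."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as err:
        raise SchemaError(f"{path}: not valid JSON: {err}")
    if doc.get("format") != "amaresfit-fixture":
        raise SchemaError(f"{path}: missing/wrong field 'format'")
    if doc.get("schema_version") != FIXTURE_SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: field 'schema_version' is {doc.get('schema_version')!r}, "
            f"reader supports {FIXTURE_SCHEMA_VERSION}")
    truth = doc.get("truth")
    if doc.get("kind") == "fid":
        return _fid_from_doc(doc["fid"], str(path)), truth
    if doc.get("kind") == "csi":
        grid = doc["grid"]
        geo = grid.get("geometry")
        if geo is None:
            raise SchemaError(f"{path}: missing required field 'geometry'")
        geometry = CsiGeometry(**geo)
        fids = [_fid_from_doc(d, f"{path} voxel {i}")
                for i, d in enumerate(grid["fids"])]
        return CsiGrid(dims=tuple(grid["dims"]), fids=fids,
                       geometry=geometry), truth
    raise SchemaError(f"{path}: field 'kind' must be 'fid' or 'csi'")


# ---------------------------------------------------------------------------
# DICOM tree scanning with a persistent cache
# ---------------------------------------------------------------------------

@dataclass
class Instance:
    path: str
    sop_instance_uid: str
    sop_class_uid: str
    instance_number: int
    acquisition_time: str = ""


@dataclass
class Series:
    series_uid: str
    series_number: int
    description: str
    instances: list[Instance] = field(default_factory=list)


@dataclass
class Study:
    study_uid: str
    description: str
    series: list[Series] = field(default_factory=list)


@dataclass
class DicomTree:
    root: str
    studies: list[Study] = field(default_factory=list)

    @property
    def n_instances(self) -> int:
        return sum(len(se.instances) for st in self.studies for se in st.series)

    def find_series(self, description_contains: str | None = None,
                    series_uid: str | None = None) -> list[Series]:
        out = []
        for st in self.studies:
            for se in st.series:
                if series_uid is not None and se.series_uid != series_uid:
                    continue
                if (description_contains is not None
                        and description_contains not in se.description):
                    continue
                out.append(se)
        return out


_SCAN_TAGS = ["StudyInstanceUID", "StudyDescription", "SeriesInstanceUID",
              "SeriesNumber", "SeriesDescription", "SOPInstanceUID",
              "SOPClassUID", "InstanceNumber", "AcquisitionTime"]


def _read_record(path: str) -> dict | None:
    try:
        ds = pydicom.dcmread(path, stop_before_pixels=True,
                             specific_tags=_SCAN_TAGS)
    except (InvalidDicomError, OSError, Exception) as err:  # noqa: BLE001
        if not isinstance(err, InvalidDicomError):
            logger.warning("skipping unreadable file %s: %s", path, err)
        return None
    return {
        "study_uid": str(getattr(ds, "StudyInstanceUID", "")),
        "study_desc": str(getattr(ds, "StudyDescription", "")),
        "series_uid": str(getattr(ds, "SeriesInstanceUID", "")),
        "series_number": int(getattr(ds, "SeriesNumber", 0) or 0),
        "series_desc": str(getattr(ds, "SeriesDescription", "")),
        "sop_uid": str(getattr(ds, "SOPInstanceUID", "")),
        "sop_class": str(getattr(ds, "SOPClassUID", "")),
        "instance_number": int(getattr(ds, "InstanceNumber", 0) or 0),
        "acq_time": str(getattr(ds, "AcquisitionTime", "")),
    }


def _dicomdir_references(path: str) -> list[str]:
    refs = []
    try:
        ds = pydicom.dcmread(path)
        base = os.path.dirname(path)
        for rec in getattr(ds, "DirectoryRecordSequence", []):
            file_id = getattr(rec, "ReferencedFileID", None)
            if file_id is None:
                continue
            parts = [file_id] if isinstance(file_id, str) else list(file_id)
            refs.append(os.path.join(base, *parts))
    except Exception as err:  # noqa: BLE001
        logger.warning("cannot parse DICOMDIR %s: %s", path, err)
    return refs


def _cache_path(directory: str) -> Path:
    digest = hashlib.sha1(os.path.abspath(directory).encode()).hexdigest()
    return Path(tempfile.gettempdir()) / f"amaresfit-dcmtree-{digest}.json"


def scan_dicom_tree(directory: str | Path, use_cache: bool = True) -> DicomTree:
    """Recursively scan ``directory`` into a study/series/instance tree.

    A versioned cache keyed by the directory path lives in the system temp
    directory; warm rescans only re-read files whose size or mtime
    changed.  Unreadable files are skipped with a warning; a corrupt cache
    is silently discarded and rebuilt.
    """
    directory = str(directory)
    cached_files: dict[str, dict] = {}
    cpath = _cache_path(directory)
    if use_cache and cpath.exists():
        try:
            payload = json.loads(cpath.read_text())
            if payload.get("schema") == TREE_CACHE_SCHEMA_VERSION:
                cached_files = payload.get("files", {})
        except (json.JSONDecodeError, OSError):
            logger.warning("discarding corrupt DICOM tree cache %s", cpath)

    candidates: list[str] = []
    for dirpath, _dirnames, filenames in os.walk(directory):
        for fname in sorted(filenames):
            fpath = os.path.join(dirpath, fname)
            if fname.upper() == "DICOMDIR":
                candidates.extend(_dicomdir_references(fpath))
            else:
                candidates.append(fpath)
    candidates = sorted({os.path.normpath(p) for p in candidates})

    files: dict[str, dict] = {}
    for fpath in candidates:
        try:
            stat = os.stat(fpath)
        except OSError:
            logger.warning("skipping vanished file %s", fpath)
            continue
        stamp = {"mtime": stat.st_mtime, "size": stat.st_size}
        cached = cached_files.get(fpath)
        if (cached is not None and cached.get("mtime") == stamp["mtime"]
                and cached.get("size") == stamp["size"]):
            files[fpath] = cached
            continue
        record = _read_record(fpath)
        files[fpath] = {**stamp, "record": record}

    if use_cache:
        try:
            cpath.write_text(json.dumps(
                {"schema": TREE_CACHE_SCHEMA_VERSION, "root": directory,
                 "files": files}))
        except OSError as err:
            logger.warning("cannot write DICOM tree cache %s: %s", cpath, err)

    studies: dict[str, Study] = {}
    series_map: dict[tuple[str, str], Series] = {}
    for fpath in sorted(files):
        rec = files[fpath].get("record")
        if rec is None or not rec["study_uid"]:
            continue
        st = studies.setdefault(rec["study_uid"],
                                Study(rec["study_uid"], rec["study_desc"]))
        key = (rec["study_uid"], rec["series_uid"])
        se = series_map.get(key)
        if se is None:
            se = Series(rec["series_uid"], rec["series_number"],
                        rec["series_desc"])
            series_map[key] = se
            st.series.append(se)
        se.instances.append(Instance(
            path=fpath, sop_instance_uid=rec["sop_uid"],
            sop_class_uid=rec["sop_class"],
            instance_number=rec["instance_number"],
            acquisition_time=rec["acq_time"]))

    tree = DicomTree(root=directory)
    for uid in sorted(studies):
        st = studies[uid]
        st.series.sort(key=lambda s: (s.series_number, s.series_uid))
        for se in st.series:
            se.instances.sort(key=lambda i: (i.instance_number, i.path))
        tree.studies.append(st)
    return tree


# ---------------------------------------------------------------------------
# Siemens spectroscopy reading and the synthetic fixture writer
# ---------------------------------------------------------------------------

def _csa_tags(ds: Dataset) -> dict[str, list]:
    merged: dict[str, list] = {}
    for tag in (_CSA_IMAGE_TAG, _CSA_SERIES_TAG):
        if tag in ds:
            merged.update(parse_csa(bytes(ds[tag].value)))
    return merged


def read_spectroscopy(path: str | Path) -> FidSeries | CsiGrid:
    """Load a Siemens MR spectroscopy DICOM file.

    Raises :class:`NotSpectroscopyError` for non-spectroscopy SOP classes
    (e.g. localizer images) and :class:`CsaParseError` for malformed CSA
    blocks.  Two fixture-extension CSA tags (``FixtureDeadTime``,
    ``FixtureReferenceShift``) are honoured when present and default to 0.
    """
    ds = pydicom.dcmread(str(path))
    sop = str(getattr(ds, "SOPClassUID", ""))
    if sop != MR_SPECTROSCOPY_SOP or _DATA_TAG not in ds:
        raise NotSpectroscopyError(sop or "<missing>")

    tags = _csa_tags(ds)
    n_points = int(csa_scalar(tags, "DataPointColumns", 0))
    dwell_ns = csa_scalar(tags, "RealDwellTime")
    f0 = csa_scalar(tags, "ImagingFrequency")
    if not n_points or dwell_ns is None or f0 is None:
        raise SchemaError(
            f"{path}: CSA header lacks DataPointColumns/RealDwellTime/"
            "ImagingFrequency")
    nucleus = str(csa_scalar(tags, "ImagedNucleus", "31P")).strip()
    dead_time = float(csa_scalar(tags, "FixtureDeadTime", 0.0))
    ref_shift = float(csa_scalar(tags, "FixtureReferenceShift", 0.0))

    raw = np.frombuffer(bytes(ds[_DATA_TAG].value), dtype="<f4")
    samples = (raw[0::2] + 1j * raw[1::2]).astype(np.complex128)

    nx = int(getattr(ds, "Columns", 1) or 1)
    ny = int(getattr(ds, "Rows", 1) or 1)
    nz = int(getattr(ds, "NumberOfFrames", 1) or 1)
    n_vox = nx * ny * nz
    if samples.size != n_points * n_vox:
        raise SchemaError(
            f"{path}: data element holds {samples.size} complex samples, "
            f"expected {n_points} x {n_vox} voxels")

    def make_fid(chunk):
        return FidSeries(samples=chunk, dwell_time=float(dwell_ns) * 1e-9,
                         transmitter_freq=float(f0), dead_time=dead_time,
                         reference_shift=ref_shift, nucleus=nucleus)

    if n_vox == 1:
        return make_fid(samples)

    pos = np.array([float(v) for v in ds.ImagePositionPatient])
    orient = np.array([float(v) for v in ds.ImageOrientationPatient])
    row_dir, col_dir = orient[:3], orient[3:]
    slice_dir = np.cross(row_dir, col_dir)
    spacing = [float(v) for v in ds.PixelSpacing]  # [between-rows, between-cols]
    thickness = float(getattr(ds, "SliceThickness", 1.0) or 1.0)
    geometry = CsiGeometry(position=pos, row_dir=row_dir, col_dir=col_dir,
                           slice_dir=slice_dir,
                           voxel_size=[spacing[1], spacing[0], thickness])
    fids = [make_fid(samples[v * n_points:(v + 1) * n_points])
            for v in range(n_vox)]
    return CsiGrid(dims=(nx, ny, nz), fids=fids, geometry=geometry)


def _base_dataset(sop_class: str) -> Dataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.PatientName = "SYNTHETIC^PHANTOM"
    ds.PatientID = "SYN000"
    ds.PatientBirthDate = ""
    ds.PatientSex = "O"
    ds.Modality = "MR"
    ds.StudyDate = "20200101"
    ds.StudyTime = "120000"
    ds.StudyID = "1"
    ds.AccessionNumber = ""
    ds.ReferringPhysicianName = ""
    return ds


def write_synthetic_dicom(path: str | Path, obj: FidSeries | CsiGrid,
                          study_uid: str | None = None,
                          series_uid: str | None = None,
                          series_desc: str = "csi_fid",
                          instance_number: int = 1) -> None:
    """Write a *synthetic* Siemens-style spectroscopy DICOM file.

    CSA2 private headers carry the acquisition parameters and the samples
    are interleaved real/imag float32 (the on-disk sample format), so the
    round trip through :func:`read_spectroscopy` inverts the float32-cast
    samples bit-exactly.  This writer exists to exercise the reader; it
    does not emulate every tag of a scanner export.
    """
    ds = _base_dataset(MR_SPECTROSCOPY_SOP)
    ds.StudyInstanceUID = study_uid or generate_uid()
    ds.SeriesInstanceUID = series_uid or generate_uid()
    ds.SeriesNumber = 1
    ds.SeriesDescription = series_desc
    ds.StudyDescription = "synthetic spectroscopy"
    ds.InstanceNumber = instance_number

    if isinstance(obj, CsiGrid):
        fids = obj.fids
        meta0 = fids[0]
        nx, ny, nz = obj.dims
        g = obj.geometry
        ds.Columns = nx
        ds.Rows = ny
        ds.NumberOfFrames = nz
        ds.ImagePositionPatient = [float(v) for v in g.position]
        ds.ImageOrientationPatient = [float(v) for v in g.row_dir] + \
            [float(v) for v in g.col_dir]
        ds.PixelSpacing = [float(g.voxel_size[1]), float(g.voxel_size[0])]
        ds.SliceThickness = float(g.voxel_size[2])
    else:
        fids = [obj]
        meta0 = obj
        ds.Columns = 1
        ds.Rows = 1
        ds.NumberOfFrames = 1

    csa = build_csa2({
        "ImagedNucleus": ("SH", [meta0.nucleus]),
        "ImagingFrequency": ("DS", [float(meta0.transmitter_freq)]),
        "RealDwellTime": ("DS", [float(meta0.dwell_time * 1e9)]),
        "DataPointColumns": ("IS", [int(meta0.n)]),
        "FixtureDeadTime": ("DS", [float(meta0.dead_time)]),
        "FixtureReferenceShift": ("DS", [float(meta0.reference_shift)]),
    })
    ds.add_new(_CSA_CREATOR_TAG, "LO", "SIEMENS CSA HEADER")
    ds.add_new(_CSA_SERIES_TAG, "OB", csa)

    stacked = np.concatenate([f.samples for f in fids])
    inter = np.empty(2 * stacked.size, dtype="<f4")
    inter[0::2] = stacked.real.astype("<f4")
    inter[1::2] = stacked.imag.astype("<f4")
    ds.add_new(_DATA_CREATOR_TAG, "LO", "SIEMENS CSA NON-IMAGE")
    ds.add_new(_DATA_TAG, "OB", inter.tobytes())

    ds.save_as(str(path), enforce_file_format=True)


def write_synthetic_localizer(path: str | Path,
                              study_uid: str | None = None,
                              series_uid: str | None = None,
                              series_desc: str = "localizer",
                              instance_number: int = 1) -> None:
    """Write a tiny synthetic MR localizer image (non-spectroscopy DICOM)."""
    ds = _base_dataset(MR_IMAGE_SOP)
    ds.StudyInstanceUID = study_uid or generate_uid()
    ds.SeriesInstanceUID = series_uid or generate_uid()
    ds.SeriesNumber = 99
    ds.SeriesDescription = series_desc
    ds.StudyDescription = "synthetic localizer"
    ds.InstanceNumber = instance_number
    ds.Rows = 4
    ds.Columns = 4
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = np.arange(16, dtype="<u2").tobytes()
    ds.save_as(str(path), enforce_file_format=True)
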