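"""Readers and writers: NIfTI volumes, TCK streamlines, plain-text formats,
transform files, JSON reports, and the navigation-compatible DICOM export.

Conventions
-----------
* Volumes and displacement fields are NIfTI-1; displacement fields are 4-D
  with the last dimension of size 3, in mm, RAS+.
* Streamlines are stored as TCK (world RAS+ mm, which is the package's
  internal representation) with per-streamline tags in a ``.tags.json``
  sidecar; a plain-text ``.txt`` dialect (one vertex per line, blank line
  between streamlines) exists for human-readable fixtures.
* Affines are 4x4 plain-text matrices (``numpy.savetxt``).
* DICOM export burns the label overlay into a secondary-capture-style series
  (one file per slice) whose geometry tags reproduce the NIfTI affine.
  DICOM patient coordinates are LPS+; the export flips X and Y accordingly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

from .atlas import LabelVolume, TDIVolume
from .grid import VolumeGrid
from .streamlines import StreamlineSet
from .transforms import SpatialTransform

# ------------------------------------------------------------------ volumes
def write_volume(path, data: np.ndarray, grid: VolumeGrid) -> None:
    img = nib.Nifti1Image(np.asarray(data), grid.affine)
    img.to_filename(str(path))


def read_volume(path) -> tuple[np.ndarray, VolumeGrid]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    affine = img.affine
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError(f"{path}: non-invertible affine")
    data = np.asanyarray(img.dataobj)
    return data, VolumeGrid(shape=data.shape[:3], affine=affine)


def write_label_volume(path, labels: LabelVolume) -> None:
    write_volume(path, labels.labels.astype(np.int16), labels.grid)


def read_label_volume(path) -> LabelVolume:
    data, grid = read_volume(path)
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError(
            f"{path}: label volumes must have an integer dtype, got {data.dtype}"
        )
    return LabelVolume(grid=grid, labels=data)


def write_tdi_volume(path, tdi: TDIVolume) -> None:
    write_volume(path, tdi.counts.astype(np.int32), tdi.grid)


def read_tdi_volume(path) -> TDIVolume:
    data, grid = read_volume(path)
    return TDIVolume(grid=grid, counts=data)


# --------------------------------------------------------------- transforms
def write_transform(t: SpatialTransform, affine_path, field_path=None) -> None:
    np.savetxt(str(affine_path), t.affine, fmt="%.10g",
               header="4x4 world->world affine (mm, RAS+)")
    if t.has_field:
        if field_path is None:
            raise ValueError("transform has a displacement field; field_path required")
        write_volume(field_path, t.displacement.astype(np.float32),
                     t.displacement_grid)


def read_transform(affine_path, field_path=None) -> SpatialTransform:
    affine = np.loadtxt(str(affine_path))
    if field_path is None:
        return SpatialTransform(affine=affine, metadata=str(affine_path))
    disp, grid = read_volume(field_path)
    if disp.ndim != 4 or disp.shape[-1] != 3:
        raise ValueError(f"{field_path}: displacement field must be 4-D with last dim 3")
    return SpatialTransform(affine=affine, displacement=np.asarray(disp, float),
                            displacement_grid=grid, metadata=str(affine_path))


# -------------------------------------------------------------- streamlines
_STREAMLINE_EXTS = (".tck", ".txt")


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".tags.json")


def write_streamlines(path, tracks: StreamlineSet) -> None:
    path = Path(path)
    if path.suffix == ".tck":
        tractogram = nib.streamlines.Tractogram(
            [sl.astype(np.float32) for sl in tracks.streamlines],
            affine_to_rasmm=np.eye(4),
        )
        nib.streamlines.save(nib.streamlines.TckFile(tractogram), str(path))
    elif path.suffix == ".txt":
        with open(path, "w") as fh:
            fh.write("# streamlines: world RAS+ mm, one vertex per line, "
                     "blank line between streamlines\n")
            for sl in tracks.streamlines:
                for p in sl:
                    fh.write(f"{p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
                fh.write("\n")
    else:
        raise ValueError(
            f"unsupported streamline format {path.suffix!r}; "
            f"supported: {_STREAMLINE_EXTS}"
        )
    with open(_sidecar(path), "w") as fh:
        json.dump({"tags": tracks.tags}, fh, default=_json_default)


def read_streamlines(path) -> StreamlineSet:
    path = Path(path)
    if path.suffix == ".tck":
        tck = nib.streamlines.load(str(path))
        streamlines = [np.asarray(sl, float) for sl in tck.tractogram.streamlines]
    elif path.suffix == ".txt":
        streamlines = []
        current: list[list[float]] = []
        for line in open(path):
            line = line.strip()
            if line.startswith("#"):
                continue
            if not line:
                if current:
                    streamlines.append(np.asarray(current))
                    current = []
                continue
            current.append([float(v) for v in line.split()])
        if current:
            streamlines.append(np.asarray(current))
    else:
        raise ValueError(
            f"unsupported streamline format {path.suffix!r}; "
            f"supported: {_STREAMLINE_EXTS}"
        )
    tags: list[dict] = []
    sidecar = _sidecar(path)
    if sidecar.exists():
        tags = json.load(open(sidecar))["tags"]
    return StreamlineSet(streamlines, tags or [{} for _ in streamlines])


# ------------------------------------------------------------------ reports
def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json_report(path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_json_default, sort_keys=True)
        fh.write("\n")


# -------------------------------------------------------------------- DICOM
@dataclass
class DicomExportSpec:
    """What to burn into a navigation-compatible DICOM series."""

    volume: np.ndarray = field(repr=False)  # scalar source volume
    overlay: LabelVolume | None = None
    grid: VolumeGrid | None = None
    burn_in: int = 4095  # 12-bit max by default
    seed: int = 0  # drives deterministic UID/metadata generation
    slice_axis: int = 2
    patient_id: str = "PHANTOM"
    study_desc: str = "OR atlas labeling"

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume)
        if self.grid is None:
            if self.overlay is None:
                raise ValueError("need a grid (directly or via the overlay)")
            self.grid = self.overlay.grid
        if self.volume.shape != tuple(self.grid.shape):
            raise ValueError("volume shape must match the grid")
        if self.overlay is not None and not self.overlay.grid.same_geometry(self.grid):
            raise ValueError("overlay and volume must share one grid")
        if not (0 <= self.burn_in <= 4095):
            raise ValueError("burn_in must fit the 12-bit output range")
        if self.slice_axis not in (0, 1, 2):
            raise ValueError("slice_axis must be 0, 1 or 2")


def _deterministic_uid(seed: int, *parts) -> str:
    digest = hashlib.sha256(("/".join(map(str, (seed,) + parts))).encode()).digest()
    return "2.25." + str(int.from_bytes(digest[:12], "big"))


_RAS_TO_LPS = np.diag([-1.0, -1.0, 1.0])


def export_dicom_series(spec: DicomExportSpec, out_dir) -> list[Path]:
    """Write one DICOM file per slice with the overlay burned in.

    The source volume is linearly rescaled to [0, 3800] (inside the 12-bit
    range); overlay voxels are replaced by ``burn_in``.  Geometry tags
    (PixelSpacing, ImagePositionPatient, ImageOrientationPatient,
    SliceThickness) reproduce the grid affine in LPS+ patient coordinates.
    UIDs and series metadata are deterministic functions of ``spec.seed``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = spec.grid
    vol = spec.volume.astype(float)
    vmin, vmax = vol.min(), vol.max()
    scaled = np.zeros_like(vol) if vmax == vmin else (vol - vmin) / (vmax - vmin) * 3800.0
    pixels = np.round(scaled).astype(np.uint16)
    if spec.overlay is not None:
        pixels[spec.overlay.labels > 0] = spec.burn_in

    k_ax = spec.slice_axis
    i_ax, j_ax = [ax for ax in range(3) if ax != k_ax]
    cols = grid.affine[:3, :3]
    u_i = cols[:, i_ax] / np.linalg.norm(cols[:, i_ax])
    u_j = cols[:, j_ax] / np.linalg.norm(cols[:, j_ax])
    d_i = float(np.linalg.norm(cols[:, i_ax]))
    d_j = float(np.linalg.norm(cols[:, j_ax]))
    thickness = float(np.linalg.norm(cols[:, k_ax]))
    orient_lps = np.concatenate([_RAS_TO_LPS @ u_i, _RAS_TO_LPS @ u_j])

    study_uid = _deterministic_uid(spec.seed, "study")
    series_uid = _deterministic_uid(spec.seed, "series")
    n_slices = grid.shape[k_ax]
    files: list[Path] = []
    for k in range(n_slices):
        origin = np.zeros(3)
        origin[k_ax] = k
        pos_lps = _RAS_TO_LPS @ grid.voxel_to_world(origin)

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
        meta.MediaStorageSOPInstanceUID = _deterministic_uid(spec.seed, "inst", k)
        meta.TransferSyntaxUID = ExplicitVRLittleEndian

        ds = FileDataset(None, Dataset(), file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = SecondaryCaptureImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.PatientName = ds.PatientID = spec.patient_id
        ds.StudyDescription = spec.study_desc
        ds.SeriesDescription = "ORA labeled"
        ds.Modality = "OT"
        ds.SeriesNumber = 1
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [float(v) for v in pos_lps]
        ds.ImageOrientationPatient = [float(v) for v in orient_lps]
        ds.PixelSpacing = [d_j, d_i]  # [row spacing, column spacing]
        ds.SliceThickness = thickness
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 12
        ds.HighBit = 11
        ds.PixelRepresentation = 0
        # pixel (row, col) = voxel (i=col, j=row) of this slice
        sl = np.take(pixels, k, axis=k_ax)
        if (i_ax, j_ax) == tuple(sorted((i_ax, j_ax))):
            plane = sl  # axes already (i, j)
        else:  # pragma: no cover - i_ax < j_ax always holds for axis triples
            plane = sl.T
        ds.Rows, ds.Columns = plane.shape[1], plane.shape[0]
        ds.PixelData = np.ascontiguousarray(plane.T).tobytes()
        path = out_dir / f"slice_{k + 1:04d}.dcm"
        ds.save_as(str(path), enforce_file_format=True)
        files.append(path)
    return files


def dicom_voxel_to_world_lps(ds: pydicom.Dataset, rows_cols: np.ndarray) -> np.ndarray:
    """Reconstruct LPS world coordinates of pixel (row, col) pairs from tags."""
    pos = np.asarray(ds.ImagePositionPatient, float)
    orient = np.asarray(ds.ImageOrientationPatient, float)
    row_dir, col_dir = orient[:3], orient[3:]  # along columns / along rows
    dr, dc = (float(v) for v in ds.PixelSpacing)
    rc = np.atleast_2d(rows_cols)
    return pos + rc[:, [1]] * dc * row_dir + rc[:, [0]] * dr * col_dir
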