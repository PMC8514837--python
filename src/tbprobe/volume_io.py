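"""CT volume input/output and geometry normalization.

All downstream computation happens in physical millimetre coordinates.
A :class:`CTVolume` stores the scalar field in Hounsfield units together
with voxel spacing, origin and direction cosines; voxel indices are
0-based and refer to voxel *centers*.  Readers normalize flipped axes so
that every direction-cosine column has a positive dominant component and
the basis is right-handed, which keeps sign conventions out of the
probing arithmetic.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid
from scipy.ndimage import map_coordinates

__all__ = [
    "CTVolume",
    "read_volume",
    "write_nifti",
    "write_dicom_series",
    "write_results",
    "read_results",
    "RESULT_COLUMNS",
]

_ORTHO_TOL = 1e-6


@dataclass
class CTVolume:
    """A 3D radiodensity field (HU) with physical geometry metadata.

    ``data[i, j, k]`` is the HU value of the voxel whose center sits at
    ``origin + axes @ (i * spacing[0], j * spacing[1], k * spacing[2])``.
    ``axes`` columns are unit direction cosines forming a right-handed
    orthonormal basis.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("CTVolume.data must be a 3D array")
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError("spacing must be three strictly positive values")
        if self.axes.shape != (3, 3):
            raise ValueError("axes must be a 3x3 matrix of direction cosines")
        if not np.allclose(self.axes.T @ self.axes, np.eye(3), atol=_ORTHO_TOL):
            raise ValueError("axes must be orthonormal")
        if np.linalg.det(self.axes) <= 0:
            raise ValueError("axes must form a right-handed basis")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> physical-mm affine (center convention)."""
        aff = np.eye(4)
        aff[:3, :3] = self.axes * self.spacing[np.newaxis, :]
        aff[:3, 3] = self.origin
        return aff

    def index_to_physical(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return self.origin + (self.axes @ (ijk * self.spacing).T).T.reshape(ijk.shape)

    def physical_to_index(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        rel = (self.axes.T @ (points - self.origin).T).T
        return (rel / self.spacing).reshape(points.shape)

    def contains(self, points: np.ndarray) -> np.ndarray:
        """True where a physical point falls inside the voxel lattice
        (within half a voxel of the outermost voxel centers)."""
        idx = np.atleast_2d(self.physical_to_index(points))
        n = np.asarray(self.shape)
        ok = np.all((idx >= -0.5) & (idx <= n - 0.5), axis=1)
        return ok if np.asarray(points).ndim > 1 else ok[0]

    def interp(self, points: np.ndarray, method: str = "linear") -> np.ndarray:
        """Sample HU at physical points (trilinear or nearest)."""
        idx = np.atleast_2d(self.physical_to_index(points))
        order = {"linear": 1, "nearest": 0}[method]
        vals = map_coordinates(
            self.data.astype(np.float64), idx.T, order=order, mode="nearest"
        )
        return vals if np.asarray(points).ndim > 1 else float(vals[0])


def _canonicalize(data: np.ndarray, spacing: np.ndarray, origin: np.ndarray,
                  axes: np.ndarray) -> CTVolume:
    """Flip index axes whose direction cosine points along a negative
    world direction, so every column's dominant component is positive."""
    data = np.asarray(data)
    axes = axes.copy()
    origin = origin.copy()
    for a in range(3):
        dom = np.argmax(np.abs(axes[:, a]))
        if axes[dom, a] < 0:
            data = np.flip(data, axis=a)
            origin = origin + axes[:, a] * spacing[a] * (data.shape[a] - 1)
            axes[:, a] = -axes[:, a]
    return CTVolume(np.ascontiguousarray(data), spacing, origin, axes)


# -- NIfTI ----------------------------------------------------------------

def _read_nifti(path: Path) -> CTVolume:
    img = nib.load(str(path))
    data = np.asanyarray(img.get_fdata(dtype=np.float64)).astype(np.float32)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    aff = img.affine
    if aff is None or not np.all(np.isfinite(aff)):
        raise ValueError("NIfTI affine (sform/qform) is missing or non-finite")
    lin = aff[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    if np.any(spacing <= 0):
        raise ValueError("NIfTI affine has a zero-length axis (pixdim)")
    axes = lin / spacing
    return _canonicalize(data, spacing, aff[:3, 3].copy(), axes)


def write_nifti(volume: CTVolume, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine)
    nib.save(img, str(path))


# -- DICOM series ---------------------------------------------------------

def _require(ds, name: str):
    if not hasattr(ds, name):
        raise ValueError(f"DICOM slice is missing required geometry tag '{name}'")
    return getattr(ds, name)


def _read_dicom_series(path: Path) -> CTVolume:
    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        files = sorted(p for p in path.iterdir() if p.is_file())
    if not files:
        raise ValueError(f"no DICOM files found under {path}")
    slices = [pydicom.dcmread(str(f)) for f in files]

    iop = np.asarray(_require(slices[0], "ImageOrientationPatient"), dtype=float)
    pix = np.asarray(_require(slices[0], "PixelSpacing"), dtype=float)
    for s in slices[1:]:
        if not np.allclose(np.asarray(_require(s, "ImageOrientationPatient"), float), iop, atol=1e-6):
            raise ValueError("mixed-orientation DICOM series: ImageOrientationPatient differs between slices")
        if not np.allclose(np.asarray(_require(s, "PixelSpacing"), float), pix, atol=1e-9):
            raise ValueError("inconsistent in-plane PixelSpacing across DICOM series")

    row_dir = iop[:3]   # direction of increasing column index (in-plane x)
    col_dir = iop[3:]   # direction of increasing row index (in-plane y)
    normal = np.cross(row_dir, col_dir)

    pos = np.array([_require(s, "ImagePositionPatient") for s in slices], dtype=float)
    z = pos @ normal
    order = np.argsort(z)
    slices = [slices[i] for i in order]
    pos = pos[order]
    z = z[order]
    if len(slices) > 1:
        steps = np.diff(z)
        if np.any(steps <= 0):
            raise ValueError("duplicate ImagePositionPatient in DICOM series")
        if not np.allclose(steps, steps[0], atol=1e-4):
            raise ValueError("non-uniform slice spacing in DICOM series")
        dz = float(steps[0])
    else:
        dz = float(getattr(slices[0], "SliceThickness", 1.0))

    planes = []
    for s in slices:
        arr = s.pixel_array.astype(np.float64)
        slope = float(getattr(s, "RescaleSlope", 1.0))
        inter = float(getattr(s, "RescaleIntercept", 0.0))
        planes.append(arr * slope + inter)
    # pixel_array is (rows, cols) = (j, i); reorder to data[i, j, k]
    data = np.stack(planes, axis=-1).transpose(1, 0, 2).astype(np.float32)

    spacing = np.array([pix[1], pix[0], dz])  # PixelSpacing is (row, col)
    axes = np.column_stack([row_dir, col_dir, normal])
    return _canonicalize(data, spacing, pos[0].copy(), axes)


def write_dicom_series(volume: CTVolume, directory: str | os.PathLike,
                       rescale_slope: float = 1.0,
                       rescale_intercept: float = -1024.0) -> list[Path]:
    """Write a CTVolume as a directory of single-frame CT slices.

    Stored pixel values are int16 with ``HU = stored * slope + intercept``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    study_uid, series_uid = generate_uid(), generate_uid()
    nx, ny, nz = volume.shape
    written = []
    for k in range(nz):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\x00" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.StudyInstanceUID = study_uid
        ds.SeriesInstanceUID = series_uid
        ds.Modality = "CT"
        ds.InstanceNumber = k + 1
        ds.Rows, ds.Columns = ny, nx
        ds.PixelSpacing = [float(volume.spacing[1]), float(volume.spacing[0])]
        ds.SliceThickness = float(volume.spacing[2])
        ds.ImageOrientationPatient = [*volume.axes[:, 0], *volume.axes[:, 1]]
        ds.ImagePositionPatient = list(volume.index_to_physical(np.array([0.0, 0.0, k])))
        ds.RescaleSlope = rescale_slope
        ds.RescaleIntercept = rescale_intercept
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1
        raw = np.round((volume.data[:, :, k].T - rescale_intercept) / rescale_slope)
        ds.PixelData = raw.astype(np.int16).tobytes()
        out = directory / f"slice_{k:04d}.dcm"
        ds.save_as(str(out), enforce_file_format=True)
        written.append(out)
    return written


def read_volume(path: str | os.PathLike, format: str | None = None) -> CTVolume:
    """Read a CT volume from a NIfTI file or a DICOM series directory.

    ``format`` may be ``"nifti"`` or ``"dicom-series"``; when omitted it is
    inferred from the path (directory -> DICOM, .nii/.nii.gz -> NIfTI).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        if path.is_dir():
            format = "dicom-series"
        elif path.name.endswith((".nii", ".nii.gz")):
            format = "nifti"
        else:
            raise ValueError(f"cannot infer volume format from {path.name}")
    if format == "nifti":
        return _read_nifti(path)
    if format == "dicom-series":
        return _read_dicom_series(path)
    raise ValueError(f"unknown volume format {format!r}")


# -- per-probe result tables ----------------------------------------------

RESULT_COLUMNS = [
    "subject",
    "grid_x_mm",
    "grid_y_mm",
    "d_tb_mm",
    "cortical_hu",
    "cortical_bmd_mg_ha_cm3",
    "codi_mg_ha_mm2",
    "status",
]


def _ordered_columns(df: pd.DataFrame) -> list[str]:
    sisi = sorted(c for c in df.columns if c.startswith("sisi_"))
    cols = RESULT_COLUMNS[:6] + sisi + RESULT_COLUMNS[6:]
    extra = [c for c in df.columns if c not in cols]
    return [c for c in cols if c in df.columns] + extra


def write_results(table: pd.DataFrame | Sequence[dict], path: str | os.PathLike) -> None:
    """Write per-probe records as CSV, one row per (subject, grid_x, grid_y).

    Column order is stable; missing measurements (NaN) become empty fields.
    """
    df = pd.DataFrame(table)
    if df.empty:
        raise ValueError("refusing to write an empty result table")
    df = df[_ordered_columns(df)]
    df.to_csv(path, index=False, na_rep="")


def read_results(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
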