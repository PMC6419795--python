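"""Volume representation and standard-format I/O.

The universal image currency is :class:`VoxelGrid`: a 3D array of Hounsfield
units indexed ``(slice z, row y, column x)`` with isotropic in-plane spacing,
a slice increment, and a physical origin. Physical coordinates are millimetres;
``x`` increases with column index, ``y`` with row index (image rows run
downward), ``z`` with slice index.

I/O goes through SimpleITK: DICOM series (read), MetaImage ``.mha``/``.mhd``
(read/write, the default), and NIfTI ``.nii``/``.nii.gz`` (read/write).
DICOM rescale slope/intercept is applied on read so values are always HU.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import SimpleITK as sitk

from .errors import FormatError, GeometryError

__all__ = ["VoxelGrid", "ROISpec", "load_stack", "save_stack", "extract_profile"]

_METAIMAGE_EXT = {".mha", ".mhd"}
_NIFTI_EXT = {".nii", ".nii.gz"}


@dataclass
class VoxelGrid:
    """A 3D CT volume in Hounsfield units.

    Parameters
    ----------
    values
        Array of shape ``(nz, ny, nx)``, HU. Stored as floating point so the
        volume survives resampling; integer input is promoted.
    spacing_xy
        In-plane voxel edge length in mm (isotropic).
    spacing_z
        Slice increment in mm.
    origin
        Physical ``(x, y, z)`` position of voxel ``(0, 0, 0)`` in mm.
    """

    values: np.ndarray
    spacing_xy: float
    spacing_z: float
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"values must be 3D (nz, ny, nx), got shape {self.values.shape}")
        if not np.issubdtype(self.values.dtype, np.floating):
            self.values = self.values.astype(np.float32)
        if not (self.spacing_xy > 0 and self.spacing_z > 0):
            raise ValueError("spacings must be strictly positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HU values must be finite")
        self.origin = tuple(float(v) for v in self.origin)

    # -- geometry helpers -------------------------------------------------
    @property
    def nz(self) -> int:
        return self.values.shape[0]

    @property
    def ny(self) -> int:
        return self.values.shape[1]

    @property
    def nx(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def x_mm(self, col) -> np.ndarray | float:
        """Physical x of a column index (voxel centre)."""
        return self.origin[0] + np.asarray(col, dtype=float) * self.spacing_xy

    def y_mm(self, row) -> np.ndarray | float:
        return self.origin[1] + np.asarray(row, dtype=float) * self.spacing_xy

    def z_mm(self, idx) -> np.ndarray | float:
        return self.origin[2] + np.asarray(idx, dtype=float) * self.spacing_z

    @property
    def centre(self) -> tuple[float, float, float]:
        """Physical centre of the stack (mm): midpoint of the voxel-centre grid."""
        return (
            self.origin[0] + (self.nx - 1) / 2.0 * self.spacing_xy,
            self.origin[1] + (self.ny - 1) / 2.0 * self.spacing_xy,
            self.origin[2] + (self.nz - 1) / 2.0 * self.spacing_z,
        )

    def copy(self) -> "VoxelGrid":
        return VoxelGrid(self.values.copy(), self.spacing_xy, self.spacing_z, self.origin)


@dataclass(frozen=True)
class ROISpec:
    """A cylindrical region of interest in image coordinates.

    ``centre_x``/``centre_y`` and ``radius`` are mm; the slice range is a
    half-open index interval ``[slice_start, slice_end)``.
    """

    centre_x: float
    centre_y: float
    radius: float
    slice_start: int
    slice_end: int

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")
        if not 0 <= self.slice_start < self.slice_end:
            raise ValueError("require 0 <= slice_start < slice_end")


# ---------------------------------------------------------------------------
# SimpleITK bridge
# ---------------------------------------------------------------------------

def to_sitk(grid: VoxelGrid) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(grid.values, dtype=np.float32))
    img.SetSpacing((float(grid.spacing_xy), float(grid.spacing_xy), float(grid.spacing_z)))
    img.SetOrigin(tuple(float(v) for v in grid.origin))
    return img


def from_sitk(img: sitk.Image, *, spacing_tol: float = 1e-3) -> VoxelGrid:
    sx, sy, sz = img.GetSpacing()
    if abs(sx - sy) > spacing_tol * max(sx, sy):
        raise GeometryError(f"anisotropic in-plane voxels not supported: {sx} x {sy} mm")
    values = sitk.GetArrayFromImage(img).astype(np.float32)
    return VoxelGrid(values, float((sx + sy) / 2.0), float(sz), tuple(img.GetOrigin()))


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "dicom_series"
    name = path.name.lower()
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        return "nifti"
    if path.suffix.lower() in _METAIMAGE_EXT:
        return "metaimage"
    raise FormatError(f"cannot infer image format from {path}")


def _load_dicom_series(path: Path) -> VoxelGrid:
    reader = sitk.ImageSeriesReader()
    series_ids = reader.GetGDCMSeriesIDs(str(path))
    if len(series_ids) == 0:
        raise FormatError(f"no DICOM series found in {path}")
    if len(series_ids) > 1:
        raise FormatError(f"directory {path} contains {len(series_ids)} interleaved series; expected one")
    files = reader.GetGDCMSeriesFileNames(str(path), series_ids[0])
    _check_uniform_slice_spacing(files)
    reader.SetFileNames(files)
    img = reader.Execute()  # applies rescale slope/intercept -> HU
    return from_sitk(sitk.Cast(img, sitk.sitkFloat32))


def _check_uniform_slice_spacing(files: Sequence[str], tol: float = 0.01) -> None:
    """Reject series whose slice positions deviate > ``tol`` (relative) from uniform."""
    import pydicom

    zs = []
    for f in files:
        ds = pydicom.dcmread(f, stop_before_pixels=True)
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is None:
            return  # no positions to check
        zs.append(float(ipp[2]))
    if len(zs) < 3:
        return
    dz = np.diff(sorted(zs))
    mean_dz = float(np.mean(dz))
    if mean_dz == 0 or np.max(np.abs(dz - mean_dz)) > tol * abs(mean_dz):
        raise GeometryError("non-uniform slice spacing beyond 1% tolerance")


def load_stack(
    path: str | os.PathLike,
    format: Literal["dicom_series", "metaimage", "nifti", "auto"] = "auto",
) -> VoxelGrid:
    """Read a CT volume; slices come back ordered by ascending physical z.

    DICOM series directories must contain exactly one coherent series; the
    rescale slope/intercept is applied so values are HU.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"path does not exist: {path}")
    if format == "auto":
        format = _infer_format(path)
    if format == "dicom_series":
        return _load_dicom_series(path)
    if format in ("metaimage", "nifti"):
        try:
            img = sitk.ReadImage(str(path))
        except RuntimeError as exc:  # pragma: no cover - ITK error text varies
            raise FormatError(f"cannot read {path}: {exc}") from exc
        return from_sitk(sitk.Cast(img, sitk.sitkFloat32))
    raise FormatError(f"unknown format {format!r}")


def save_stack(
    grid: VoxelGrid,
    path: str | os.PathLike,
    format: Literal["metaimage", "nifti", "auto"] = "auto",
) -> None:
    """Write a volume as MetaImage or NIfTI.

    Integer-valued volumes that fit in 16 bits are written as ``int16``
    (lossless for integer HU data); anything else is written as ``float32``.
    """
    path = Path(path)
    if format == "auto":
        format = _infer_format(path)
    if format == "dicom_series":
        raise FormatError("writing DICOM series is not supported; use metaimage or nifti")
    if format not in ("metaimage", "nifti"):
        raise FormatError(f"unknown format {format!r}")

    vals = grid.values
    integral = bool(np.all(vals == np.round(vals)))
    in_range = bool(vals.size == 0 or (vals.min() >= -32768 and vals.max() <= 32767))
    if integral and in_range:
        arr = np.round(vals).astype(np.int16)
    else:
        arr = vals.astype(np.float32)
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr))
    img.SetSpacing((float(grid.spacing_xy), float(grid.spacing_xy), float(grid.spacing_z)))
    img.SetOrigin(tuple(float(v) for v in grid.origin))
    try:
        sitk.WriteImage(img, str(path), useCompression=format == "nifti")
    except RuntimeError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def extract_profile(
    grid: VoxelGrid,
    slice_index: int,
    axis: Literal["x", "y"],
    direction: Literal["forward", "reverse"] = "forward",
) -> np.ndarray:
    """Grey values along the central row (axis='x') or column (axis='y').

    For even dimensions the central line is index ``dim // 2``. ``reverse``
    returns the elementwise reversal of the forward profile.
    """
    if not 0 <= slice_index < grid.nz:
        raise IndexError(f"slice {slice_index} out of range [0, {grid.nz})")
    if axis == "x":
        profile = grid.values[slice_index, grid.ny // 2, :]
    elif axis == "y":
        profile = grid.values[slice_index, :, grid.nx // 2]
    else:
        raise ValueError("axis must be 'x' or 'y'")
    profile = np.asarray(profile, dtype=np.float64).copy()
    if direction == "reverse":
        return profile[::-1].copy()
    if direction != "forward":
        raise ValueError("direction must be 'forward' or 'reverse'")
    return profile
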