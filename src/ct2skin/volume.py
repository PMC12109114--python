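"""CT volume loading and triplanar reslicing.

A head CT series is loaded into a Hounsfield-unit voxel grid together with its
acquisition geometry (per-axis spacing and world origin, both in millimetres,
following the DICOM patient coordinate convention of the input series).  From
that grid, ordered stacks of axial, sagittal and coronal slices are produced by
pure re-indexing: all three planes are axis-aligned, so no interpolation is
ever performed and every slice pixel is an original voxel value.

Conventions
-----------
* The HU grid is stored as ``hu[z, y, x]`` (slice, row, column of the axial
  acquisition); the public ``shape`` is reported as ``(nx, ny, nz)``.
* Axial slice ``k``: rows traverse +y, columns traverse +x.
* Sagittal slice ``k`` (fixed x) and coronal slice ``k`` (fixed y) place the
  volume z-axis along image rows, *reversed*, so that the top of the head is
  at the top of the displayed image.  The permutation is recorded per slice in
  ``row_axis``/``col_axis``/``row_reversed`` and is consumed unchanged by the
  world-coordinate projection, which makes the mapping exactly invertible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pydicom

__all__ = [
    "Orientation",
    "VoxelVolume",
    "PlanarSlice",
    "load_volume",
    "load_nifti",
    "reslice",
]

Orientation = Literal["axial", "sagittal", "coronal"]

_ORIENTATIONS: tuple[str, ...] = ("axial", "sagittal", "coronal")

#: world axis indices
_X, _Y, _Z = 0, 1, 2


class VolumeError(ValueError):
    """Raised for malformed or unsupported input series."""


@dataclass(frozen=True)
class VoxelVolume:
    """A 3D Hounsfield-unit scalar grid plus acquisition geometry.

    Parameters
    ----------
    hu :
        Array of shape ``(nz, ny, nx)`` holding HU values (rescale slope and
        intercept already applied).
    spacing_mm :
        Voxel size ``(sx, sy, sz)`` in millimetres.
    origin_mm :
        World position ``(ox, oy, oz)`` of voxel ``(x=0, y=0, z=0)``.
    """

    hu: np.ndarray
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        hu = np.asarray(self.hu)
        if hu.ndim != 3 or min(hu.shape) < 1:
            raise VolumeError(f"HU grid must be 3D and nonempty, got shape {hu.shape}")
        if not np.all(np.isfinite(hu)):
            raise VolumeError("HU grid contains non-finite values")
        if any(s <= 0 for s in self.spacing_mm):
            raise VolumeError(f"spacing components must be > 0, got {self.spacing_mm}")
        object.__setattr__(self, "hu", hu)
        object.__setattr__(self, "spacing_mm", tuple(float(s) for s in self.spacing_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        """Voxel counts ``(nx, ny, nz)``."""
        nz, ny, nx = self.hu.shape
        return (nx, ny, nz)

    def axis_extent(self, axis: int) -> int:
        """Voxel count along world axis 0=x, 1=y, 2=z."""
        return self.shape[axis]

    def world_of_index(self, idx_xyz: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (N, 3) in (x, y, z) order to world mm."""
        idx = np.atleast_2d(np.asarray(idx_xyz, dtype=float))
        return np.asarray(self.origin_mm) + idx * np.asarray(self.spacing_mm)

    def index_of_world(self, xyz_mm: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`world_of_index` (fractional indices)."""
        pts = np.atleast_2d(np.asarray(xyz_mm, dtype=float))
        return (pts - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)


@dataclass(frozen=True)
class PlanarSlice:
    """A single 2D HU image extracted from a :class:`VoxelVolume`.

    ``row_axis``/``col_axis`` name the world axes (0=x, 1=y, 2=z) traversed by
    image rows and columns; ``row_reversed`` records that row 0 corresponds to
    the *largest* index along ``row_axis`` (used for sagittal/coronal views so
    the head is upright).  ``index`` is the voxel index along the slicing axis.
    """

    pixels: np.ndarray
    orientation: Orientation
    index: int
    row_axis: int
    col_axis: int
    row_reversed: bool
    spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float]
    volume_shape: tuple[int, int, int]  # (nx, ny, nz)

    @property
    def slice_axis(self) -> int:
        return ({0, 1, 2} - {self.row_axis, self.col_axis}).pop()

    def rowcol_to_world(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) pixel coordinates to world millimetres."""
        rows = np.asarray(rows, dtype=float)
        cols = np.asarray(cols, dtype=float)
        n_row = self.volume_shape[self.row_axis]
        row_idx = (n_row - 1) - rows if self.row_reversed else rows
        out = np.empty((rows.size, 3), dtype=float)
        origin = self.origin_mm
        spacing = self.spacing_mm
        out[:, self.row_axis] = origin[self.row_axis] + row_idx * spacing[self.row_axis]
        out[:, self.col_axis] = origin[self.col_axis] + cols * spacing[self.col_axis]
        ax = self.slice_axis
        out[:, ax] = origin[ax] + self.index * spacing[ax]
        return out

    def world_to_rowcol(self, xyz_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Exact inverse of :meth:`rowcol_to_world` (fractional row/col)."""
        pts = np.atleast_2d(np.asarray(xyz_mm, dtype=float))
        idx = (pts - np.asarray(self.origin_mm)) / np.asarray(self.spacing_mm)
        row_idx = idx[:, self.row_axis]
        n_row = self.volume_shape[self.row_axis]
        rows = (n_row - 1) - row_idx if self.row_reversed else row_idx
        return rows, idx[:, self.col_axis]


def reslice(volume: VoxelVolume, orientation: Orientation) -> list[PlanarSlice]:
    """Extract the ordered slice stack for one anatomical orientation.

    Axial yields ``nz`` slices of shape ``(ny, nx)``, sagittal ``nx`` slices of
    shape ``(nz, ny)``, coronal ``ny`` slices of shape ``(nz, nx)``.  The
    operation is a pure axis permutation of the stored grid (plus a flip of the
    z rows for sagittal/coronal); every voxel appears in exactly one slice.
    """
    if orientation not in _ORIENTATIONS:
        raise VolumeError(
            f"unknown orientation {orientation!r}; expected one of {_ORIENTATIONS}"
        )
    hu = volume.hu  # (nz, ny, nx)
    nx, ny, nz = volume.shape
    common = dict(
        spacing_mm=volume.spacing_mm,
        origin_mm=volume.origin_mm,
        volume_shape=volume.shape,
    )
    slices: list[PlanarSlice] = []
    if orientation == "axial":
        for k in range(nz):
            slices.append(
                PlanarSlice(
                    pixels=hu[k, :, :],
                    orientation="axial",
                    index=k,
                    row_axis=_Y,
                    col_axis=_X,
                    row_reversed=False,
                    **common,
                )
            )
    elif orientation == "sagittal":
        # rows: z reversed (head up); cols: y
        flipped = hu[::-1]  # (nz, ny, nx) with z reversed
        for k in range(nx):
            slices.append(
                PlanarSlice(
                    pixels=flipped[:, :, k],
                    orientation="sagittal",
                    index=k,
                    row_axis=_Z,
                    col_axis=_Y,
                    row_reversed=True,
                    **common,
                )
            )
    else:  # coronal
        flipped = hu[::-1]
        for k in range(ny):
            slices.append(
                PlanarSlice(
                    pixels=flipped[:, k, :],
                    orientation="coronal",
                    index=k,
                    row_axis=_Z,
                    col_axis=_X,
                    row_reversed=True,
                    **common,
                )
            )
    return slices


# ---------------------------------------------------------------------------
# DICOM series loading
# ---------------------------------------------------------------------------

_AXIAL_IOP = np.array([1.0, 0.0, 0.0, 0.0, 1.0, 0.0])


def _read_series(paths: Iterable[Path]) -> list[pydicom.Dataset]:
    datasets = []
    for p in paths:
        try:
            ds = pydicom.dcmread(str(p))
        except Exception:  # non-DICOM clutter is ignored
            continue
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    return datasets


def load_volume(dicom_dir: str | os.PathLike, gap_tol_mm: float = 1e-3) -> VoxelVolume:
    """Load a single axial CT DICOM series into a :class:`VoxelVolume`.

    Slices are ordered by their world z position (not by filename), rescale
    slope/intercept are applied to recover HU, and the z spacing is derived
    from the inter-slice distance.

    Raises
    ------
    VolumeError
        If the directory mixes series, lacks spacing tags, contains obliquely
        oriented slices, or the slice gaps are non-uniform beyond ``gap_tol_mm``.
    """
    directory = Path(dicom_dir)
    datasets = _read_series(sorted(directory.iterdir()))
    if not datasets:
        raise VolumeError(f"no DICOM image files found in {directory}")

    series_uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(series_uids) != 1:
        raise VolumeError(f"directory contains {len(series_uids)} series; expected exactly one")

    for ds in datasets:
        if "PixelSpacing" not in ds or "ImagePositionPatient" not in ds:
            raise VolumeError("slice is missing PixelSpacing or ImagePositionPatient")
        iop = np.asarray(getattr(ds, "ImageOrientationPatient", _AXIAL_IOP), dtype=float)
        if not np.allclose(iop, _AXIAL_IOP, atol=1e-6):
            raise VolumeError(
                "only standard axial orientation is supported; "
                f"got ImageOrientationPatient={iop.tolist()}"
            )

    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))

    spacings = {tuple(float(v) for v in ds.PixelSpacing) for ds in datasets}
    if len(spacings) != 1:
        raise VolumeError(f"inconsistent in-plane PixelSpacing across slices: {spacings}")
    sy, sx = spacings.pop()  # DICOM PixelSpacing is (row, col) = (dy, dx)

    z = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    if len(z) > 1:
        gaps = np.diff(z)
        if np.any(gaps <= 0):
            raise VolumeError("duplicate or non-monotone slice positions in series")
        if gaps.max() - gaps.min() > gap_tol_mm:
            raise VolumeError(
                f"non-uniform slice gaps (range {gaps.min():.6g}..{gaps.max():.6g} mm "
                f"exceeds tolerance {gap_tol_mm} mm); a slice may be missing"
            )
        sz = float(np.mean(gaps))
    else:
        sz = float(getattr(datasets[0], "SliceThickness", 1.0) or 1.0)

    first = datasets[0]
    origin = (
        float(first.ImagePositionPatient[0]),
        float(first.ImagePositionPatient[1]),
        float(first.ImagePositionPatient[2]),
    )

    planes = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    hu = np.stack(planes).astype(np.float32)

    return VoxelVolume(hu=hu, spacing_mm=(sx, sy, sz), origin_mm=origin)


def load_nifti(path: str | os.PathLike) -> VoxelVolume:
    """Load a single-file NIfTI volume through the same :class:`VoxelVolume` contract.

    Only axis-aligned affines (diagonal rotation part, positive scales) are
    accepted; oblique volumes are rejected rather than resampled, matching the
    DICOM loader's behaviour.
    """
    import nibabel as nib

    img = nib.load(str(path))
    affine = np.asarray(img.affine, dtype=float)
    rot = affine[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0.0, atol=1e-6):
        raise VolumeError("oblique NIfTI affines are not supported")
    scales = np.diag(rot)
    if np.any(scales <= 0):
        raise VolumeError("NIfTI affine must have positive axis scales")
    data = np.asanyarray(img.dataobj).astype(np.float32)  # (nx, ny, nz)
    if data.ndim != 3:
        raise VolumeError(f"expected a 3D NIfTI volume, got {data.ndim}D")
    hu = np.transpose(data, (2, 1, 0))  # -> (nz, ny, nx)
    origin = tuple(float(v) for v in affine[:3, 3])
    spacing = tuple(float(s) for s in scales)
    return VoxelVolume(hu=hu, spacing_mm=spacing, origin_mm=origin)
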