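"""Volume data model, NIfTI I/O, and resampling to a working grid.

Conventions used throughout the package
---------------------------------------
* Voxel arrays are indexed ``(x, y, z)`` with ``z`` the cranio-caudal axis.
* Voxel indexing is 0-based; all physical quantities are millimetres.
* The physical coordinate of voxel ``(i, j, k)`` is
  ``origin + (i * sx, j * sy, k * sz)``.
* Scalar volumes hold Hounsfield units (HU); label volumes hold the class
  codes ``{0: background, 1: kidney, 2: ureter, 3: bladder}``.

NIfTI (.nii / .nii.gz) is the canonical interchange format. A directory
path is treated as a DICOM series and read through SimpleITK; this is an
optional convenience behind the same contract.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Tuple, Union

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "BACKGROUND",
    "KIDNEY",
    "URETER",
    "BLADDER",
    "CLASS_NAMES",
    "ImageVolume",
    "LabelVolume",
    "read_volume",
    "read_labels",
    "write_volume",
    "resample",
]

BACKGROUND, KIDNEY, URETER, BLADDER = 0, 1, 2, 3
CLASS_NAMES = {BACKGROUND: "background", KIDNEY: "kidney", URETER: "ureter", BLADDER: "bladder"}

Triple = Tuple[float, float, float]


def _check_grid(voxels: np.ndarray, spacing) -> None:
    if voxels.ndim != 3:
        raise ValueError(f"expected a rank-3 volume, got rank {voxels.ndim}")
    if min(voxels.shape) < 1:
        raise ValueError(f"every dimension must be >= 1, got shape {voxels.shape}")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three strictly positive numbers, got {spacing}")


@dataclass
class ImageVolume:
    """A 3-D scalar CT volume in Hounsfield units on a regular grid."""

    voxels: np.ndarray
    spacing: Triple = (1.0, 1.0, 1.0)
    origin: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float32)
        _check_grid(self.voxels, self.spacing)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.voxels.shape

    @property
    def extent_mm(self) -> Triple:
        """Physical extent spanned by the grid (``dim * spacing`` per axis)."""
        return tuple(d * s for d, s in zip(self.shape, self.spacing))

    def index_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to physical mm coordinates."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def physical_to_index(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_centers(self) -> np.ndarray:
        """Physical coordinates of every voxel center, shape ``(*grid, 3)``."""
        grids = np.meshgrid(
            *[np.arange(n) * s + o for n, s, o in zip(self.shape, self.spacing, self.origin)],
            indexing="ij",
        )
        return np.stack(grids, axis=-1)

    def same_grid(self, other: "ImageVolume | LabelVolume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


@dataclass
class LabelVolume:
    """A 3-D label volume over the classes background/kidney/ureter/bladder.

    Shares the grid conventions of :class:`ImageVolume`; when paired with a
    companion image it must live on the identical lattice.
    """

    labels: np.ndarray
    spacing: Triple = (1.0, 1.0, 1.0)
    origin: Triple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        arr = np.asarray(self.labels)
        _check_grid(arr, self.spacing)
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("label volume must contain integers")
            arr = np.round(arr).astype(np.uint8)
        if arr.min() < 0 or arr.max() > 3:
            bad = sorted(set(np.unique(arr)) - {0, 1, 2, 3})
            raise ValueError(f"label values outside {{0,1,2,3}}: {bad}")
        self.labels = arr.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    # grid helpers shared with ImageVolume
    shape = ImageVolume.shape
    extent_mm = ImageVolume.extent_mm
    index_to_physical = ImageVolume.index_to_physical
    physical_to_index = ImageVolume.physical_to_index
    same_grid = ImageVolume.same_grid

    def voxel_centers(self) -> np.ndarray:
        grids = np.meshgrid(
            *[np.arange(n) * s + o for n, s, o in zip(self.labels.shape, self.spacing, self.origin)],
            indexing="ij",
        )
        return np.stack(grids, axis=-1)

    @property
    def voxels(self) -> np.ndarray:  # uniform access for I/O helpers
        return self.labels

    def foreground(self) -> np.ndarray:
        """Binary urinary-tract mask (any nonzero class)."""
        return self.labels > 0


Volume = Union[ImageVolume, LabelVolume]


def _affine_from_grid(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    aff[:3, 3] = origin
    return aff


def read_volume(path: Union[str, Path]) -> ImageVolume:
    """Read a 3-D scalar volume from a NIfTI file (or a DICOM series directory).

    Spacing and origin are taken from the header. Raises
    :class:`FileNotFoundError` for a missing path and :class:`ValueError`
    for a non-3-D image (the message names the offending rank).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    if path.is_dir():
        return _read_dicom_series(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected a rank-3 image, file has rank {data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return ImageVolume(data.astype(np.float32), spacing=spacing, origin=origin)


def read_labels(path: Union[str, Path]) -> LabelVolume:
    """Read a label volume (same contract as :func:`read_volume`)."""
    vol = read_volume(path)
    return LabelVolume(np.round(vol.voxels).astype(np.uint8), vol.spacing, vol.origin)


def _read_dicom_series(directory: Path) -> ImageVolume:
    import SimpleITK as sitk

    reader = sitk.ImageSeriesReader()
    files = reader.GetGDCMSeriesFileNames(str(directory))
    if not files:
        raise ValueError(f"no DICOM series found in {directory}")
    reader.SetFileNames(files)
    img = reader.Execute()
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    data = np.ascontiguousarray(arr.transpose(2, 1, 0)).astype(np.float32)
    return ImageVolume(data, spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin()))


def write_volume(volume: Volume, path: Union[str, Path]) -> None:
    """Write a volume as NIfTI. Labels are stored as unsigned 8-bit, HU as float32."""
    path = Path(path)
    parent = path.parent
    if not parent.exists():
        raise IOError(f"directory does not exist: {parent}")
    if not os.access(parent, os.W_OK):
        raise IOError(f"directory not writable: {parent}")
    if isinstance(volume, LabelVolume):
        data = volume.labels.astype(np.uint8)
    else:
        data = volume.voxels.astype(np.float32)
    img = nib.Nifti1Image(data, _affine_from_grid(volume.spacing, volume.origin))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def resample(volume: Volume, target_spacing: Triple) -> Volume:
    """Resample a volume onto a new spacing, preserving the physical extent.

    Output dimension per axis is ``ceil(dim * spacing / target_spacing)``, so
    the field of view is never truncated (it may grow by less than one output
    voxel). Scalar volumes are linearly interpolated; label volumes use
    nearest-neighbour, which cannot invent classes.
    """
    target_spacing = tuple(float(s) for s in target_spacing)
    if len(target_spacing) != 3 or any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be strictly positive, got {target_spacing}")
    if np.allclose(target_spacing, volume.spacing):
        return replace(volume)

    in_shape = np.array(volume.voxels.shape)
    in_sp = np.array(volume.spacing)
    out_sp = np.array(target_spacing)
    out_shape = np.ceil(in_shape * in_sp / out_sp - 1e-9).astype(int)
    out_shape = np.maximum(out_shape, 1)

    # output voxel (i,j,k) center sits at origin + i*out_sp -> input index i*out_sp/in_sp
    coords = np.meshgrid(
        *[np.arange(n) * out_sp[a] / in_sp[a] for a, n in enumerate(out_shape)],
        indexing="ij",
    )
    is_label = isinstance(volume, LabelVolume)
    order = 0 if is_label else 1
    out = ndimage.map_coordinates(
        volume.voxels.astype(np.float32 if not is_label else np.uint8),
        np.stack(coords),
        order=order,
        mode="nearest",
    )
    if is_label:
        return LabelVolume(out.astype(np.uint8), target_spacing, volume.origin)
    return ImageVolume(out.astype(np.float32), target_spacing, volume.origin)
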