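"""NIfTI volume I/O and voxel-grid contracts.

All computation in this package happens in voxel space on a single shared
grid; the affine is carried along for round-trip fidelity but is never used
to resample.  NIfTI-1 (``.nii`` / ``.nii.gz``) is the only on-disk format.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import nibabel as nib
import numpy as np

from .errors import CoregistrationError, DimensionalityError, InputError

__all__ = [
    "Volume",
    "BinaryMask",
    "read_volume",
    "read_mask",
    "write_volume",
    "assert_coregistered",
]


@dataclass
class Volume:
    """A 3D scalar image with voxel spacing in millimetres.

    Parameters
    ----------
    data:
        3D array of intensities; dtype is preserved on write.
    spacing:
        Millimetres per voxel along each axis; all entries must be > 0.
    affine:
        Optional 4x4 voxel-to-world matrix, preserved on round-trip but
        never used for computation.
    """

    data: np.ndarray
    spacing: tuple = (1.0, 1.0, 1.0)
    affine: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise DimensionalityError(
                f"expected a 3D volume, got shape {self.data.shape}"
            )
        if any(n < 1 for n in self.data.shape):
            raise DimensionalityError(
                f"every axis must have length >= 1, got shape {self.data.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3:
            raise InputError(f"spacing must have 3 entries, got {self.spacing}")
        if any(s <= 0 for s in self.spacing):
            raise InputError(f"spacing entries must be > 0, got {self.spacing}")
        if self.affine is not None:
            self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in cubic millimetres."""
        return float(np.prod(self.spacing))

    def with_data(self, data: np.ndarray) -> "Volume":
        """New Volume on the same grid carrying ``data``."""
        return Volume(np.asarray(data), self.spacing, self.affine)


class BinaryMask(Volume):
    """A Volume whose values are restricted to {0, 1}; stored as uint8."""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.dtype == bool:
            self.data = self.data.astype(np.uint8)
        super().__post_init__()
        values = np.unique(self.data)
        if not np.isin(values, (0, 1)).all():
            raise InputError(
                f"binary mask may only contain 0/1, found values {values[:10]}"
            )
        self.data = self.data.astype(np.uint8)

    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


def _default_affine(spacing) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def read_volume(path: Union[str, Path]) -> Volume:
    """Read a NIfTI-1 file into a :class:`Volume`.

    Raises
    ------
    InputError
        If the file does not exist.
    DimensionalityError
        If the image is not 3D (e.g. a 4D time series).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise DimensionalityError(
            f"{path} is not a 3D image (shape {data.shape})"
        )
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(data, spacing, np.asarray(img.affine))


def read_mask(path: Union[str, Path]) -> BinaryMask:
    """Read a NIfTI-1 file as a binary mask (any nonzero voxel -> 1)."""
    vol = read_volume(path)
    return BinaryMask((vol.data != 0).astype(np.uint8), vol.spacing, vol.affine)


def write_volume(vol: Volume, path: Union[str, Path]) -> None:
    """Write a Volume (or BinaryMask) to a NIfTI-1 file.

    The data dtype and the spacing are preserved so that
    ``read_volume(write_volume(v))`` is the identity.
    """
    path = Path(path)
    if not path.parent.exists():
        raise InputError(f"parent directory does not exist: {path.parent}")
    affine = vol.affine if vol.affine is not None else _default_affine(vol.spacing)
    data = vol.data
    if isinstance(vol, BinaryMask):
        data = data.astype(np.uint8)
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))


def _grid(vol: Volume):
    return vol.shape, vol.spacing


def assert_coregistered(vols: Sequence[Volume], atol_mm: float = 1e-3) -> None:
    """Check that all volumes live on one grid (shape, spacing within atol).

    Order-invariant: every entry is compared with the first.
    """
    if len(vols) == 0:
        raise InputError("assert_coregistered needs at least one volume")
    ref_shape, ref_spacing = _grid(vols[0])
    for v in vols[1:]:
        shape, spacing = _grid(v)
        if shape != ref_shape or not np.allclose(
            spacing, ref_spacing, rtol=0, atol=atol_mm
        ):
            raise CoregistrationError(
                f"grids differ: shape {ref_shape} spacing {ref_spacing} "
                f"vs shape {shape} spacing {spacing}"
            )
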