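"""3D scalar volumes bound to a voxel grid, with NIfTI-1 round-trip IO."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class Volume:
    """A 3D scalar grid with an affine and isotropic-or-not voxel spacing.

    Voxel indices are 0-based; world coordinates come from ``affine``.
    """

    data: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be a 4x4 matrix")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel spacing along each axis in mm."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    def like(self, data: np.ndarray) -> "Volume":
        """New Volume on this grid with different data."""
        return Volume(np.asarray(data), self.affine.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Volume):
            return NotImplemented
        return np.array_equal(self.data, other.data) and np.allclose(self.affine, other.affine)


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI-1 file into a Volume.

    Raises ValueError for non-3D images (a trailing singleton dimension is
    squeezed, matching common scanner exports).
    """
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return Volume(data, img.affine)


def write_volume(vol: Volume, path: str | Path, dtype=None) -> None:
    """Write a Volume as NIfTI-1. Masks should pass ``dtype=np.uint8``."""
    data = vol.data if dtype is None else vol.data.astype(dtype)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms(tuple(vol.voxel_size))
    nib.save(img, str(path))
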