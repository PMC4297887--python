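"""3D voxel lattices with physical voxel sizes.

A :class:`VoxelGrid3D` is the carrier for everything volumetric in the
pipeline: binary lesion masks (native scanner space and template space) and
PD/T2 intensity volumes.  Distances are always computed in millimetres via
the per-axis voxel sizes, never in raw index units, because clinical lesion
masks routinely live on anisotropic lattices (e.g. 0.9375 x 0.9375 x 3 mm
axial acquisitions).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VoxelGrid3D", "load_nifti", "save_nifti"]


@dataclass
class VoxelGrid3D:
    """A 3D scalar lattice with per-axis physical voxel sizes.

    Parameters
    ----------
    values
        3D array of finite scalars.  Binary masks use {0, 1}.
    voxel_size_mm
        Physical edge lengths of one voxel along each axis, in mm.
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.values.ndim}")
        if min(self.values.shape) < 1:
            raise ValueError("all dimensions must be >= 1")
        vs = tuple(float(v) for v in self.voxel_size_mm)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel sizes must be three positive reals, got {self.voxel_size_mm}")
        self.voxel_size_mm = vs
        if not np.all(np.isfinite(self.values)):
            raise ValueError("grid values must be finite")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def is_binary(self) -> bool:
        return bool(np.isin(self.values, (0, 1)).all())

    def center_index(self) -> tuple[int, int, int]:
        """Index of the central voxel: floor(n/2) on each axis."""
        return tuple(n // 2 for n in self.dims)  # type: ignore[return-value]

    def center_mm(self) -> np.ndarray:
        """Physical coordinate (mm) of the central voxel's centre."""
        return np.asarray(self.center_index(), dtype=float) * np.asarray(self.voxel_size_mm)

    def same_lattice(self, other: "VoxelGrid3D") -> bool:
        return self.dims == other.dims and np.allclose(self.voxel_size_mm, other.voxel_size_mm)

    def copy(self) -> "VoxelGrid3D":
        return VoxelGrid3D(self.values.copy(), self.voxel_size_mm)


def save_nifti(grid: VoxelGrid3D, path: str | os.PathLike) -> None:
    """Write a grid as NIfTI with a diagonal affine built from the voxel sizes."""
    affine = np.diag(list(grid.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(grid.values, dtype=np.float32), affine)
    img.header.set_zooms(grid.voxel_size_mm)
    nib.save(img, os.fspath(path))


def load_nifti(path: str | os.PathLike) -> VoxelGrid3D:
    """Read a NIfTI volume back into a :class:`VoxelGrid3D`.

    Voxel sizes are taken from the header zooms; orientation information
    beyond the zooms is ignored (the pipeline works in the file's own axes).
    """
    img = nib.load(os.fspath(path))
    data = np.asarray(img.get_fdata())
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VoxelGrid3D(data, zooms)
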