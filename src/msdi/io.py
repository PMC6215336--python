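"""NIfTI input/output via nibabel.

Volumes are stored with a diagonal affine built from the voxel size; the
world orientation is ignored beyond voxel dimensions — the B0 direction
is configuration, not header, information.  Arrays are 0-based.
"""

from __future__ import annotations

import os
from typing import Optional, Tuple

import nibabel as nib
import numpy as np

from .core import FieldVolume, VoxelGrid


def save_volume(values: np.ndarray, grid: VoxelGrid, path: str) -> None:
    affine = np.diag(list(grid.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), affine)
    img.header.set_zooms(grid.voxel_size_mm)
    nib.save(img, path)


def load_volume(
    path: str, b0_dir: Tuple[float, float, float] = (0.0, 0.0, 1.0)
) -> Tuple[np.ndarray, VoxelGrid]:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    img = nib.load(path)
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    grid = VoxelGrid(shape=data.shape, voxel_size_mm=tuple(float(z) for z in zooms), b0_dir=b0_dir)
    return data, grid


def load_field(
    path: str,
    te_ms: Optional[float] = None,
    b0_T: Optional[float] = None,
    units: str = "rad",
    wrapped: bool = False,
    b0_dir: Tuple[float, float, float] = (0.0, 0.0, 1.0),
) -> FieldVolume:
    values, grid = load_volume(path, b0_dir=b0_dir)
    return FieldVolume(
        values=values, grid=grid, units=units, te_ms=te_ms, b0_T=b0_T, wrapped=wrapped
    )
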