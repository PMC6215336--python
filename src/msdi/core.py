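"""Core geometry and volume containers shared by all stages.

The package works on regular Cartesian voxel grids.  A :class:`VoxelGrid`
carries the array shape, anisotropic voxel size in millimetres and the unit
direction of the main magnetic field B0.  Scalar volumes are plain float64
``numpy`` arrays; the only container with non-trivial bookkeeping is
:class:`FieldVolume`, which tracks phase units (``rad`` vs ``normalised``)
and the acquisition constants (TE, B0) needed to convert susceptibility in
ppm into phase in radians.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

#: Reduced gyromagnetic ratio of the proton, MHz/T.
GAMMA_BAR_MHZ_PER_T = 42.576

#: Reference TE*B0 product (ms*T) to which all field maps are normalised
#: before inversion, so a single lambda range transfers across acquisitions.
REFERENCE_TE_B0_MS_T = 60.0


def phase_per_ppm(te_ms: float, b0_T: float) -> float:
    """Phase accrued per ppm of susceptibility-induced field shift.

    ``phi = 2*pi * gamma_bar * B0 * TE * 1e-6 * chi[ppm]`` (radians).
    """
    return 2.0 * np.pi * GAMMA_BAR_MHZ_PER_T * 1e6 * b0_T * (te_ms * 1e-3) * 1e-6


#: rad per ppm at the reference normalisation TE*B0 = 60 ms*T.
PHASE_PER_PPM_NORM = phase_per_ppm(REFERENCE_TE_B0_MS_T, 1.0)


class GridMismatchError(ValueError):
    """Raised when volumes defined on different grids are combined."""


@dataclass(frozen=True)
class VoxelGrid:
    """Regular 3D voxel lattice with physical spacing and B0 direction.

    Parameters
    ----------
    shape:
        Array shape (nx, ny, nz); every entry must be positive, and >= 8
        for use in the inversion stages.
    voxel_size_mm:
        Voxel edge lengths in millimetres, one per axis.
    b0_dir:
        Direction of the main field.  Stored normalised to unit length;
        defaults to the third (z) axis.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    b0_dir: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        vox = tuple(float(v) for v in self.voxel_size_mm)
        if len(shape) != 3 or len(vox) != 3:
            raise ValueError("VoxelGrid is strictly three-dimensional")
        if any(n < 2 for n in shape):
            raise ValueError(f"degenerate grid shape {shape}: every dimension must be >= 2")
        if any(v <= 0 for v in vox):
            raise ValueError(f"voxel sizes must be positive, got {vox}")
        b0 = np.asarray(self.b0_dir, dtype=float)
        norm = float(np.linalg.norm(b0))
        if norm < 1e-12:
            raise ValueError("b0_dir must be a non-zero vector")
        b0 = b0 / norm
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size_mm", vox)
        object.__setattr__(self, "b0_dir", tuple(float(c) for c in b0))

    # -- geometry helpers -------------------------------------------------
    @property
    def nvox(self) -> int:
        return int(np.prod(self.shape))

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        return tuple(n * v for n, v in zip(self.shape, self.voxel_size_mm))

    def freq_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis spatial-frequency lattices in cycles/mm (FFT layout)."""
        axes = [
            np.fft.fftfreq(n, d=v) for n, v in zip(self.shape, self.voxel_size_mm)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))

    def offset_grids_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Signed voxel-centre offsets from the origin voxel, mm, FFT layout.

        The origin sits at array index (0, 0, 0) with wrap-around negative
        offsets, matching the layout expected by circular convolution.
        """
        axes = [
            np.fft.fftfreq(n, d=1.0 / n) * v
            for n, v in zip(self.shape, self.voxel_size_mm)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinates relative to the volume centre, mm."""
        axes = [
            (np.arange(n) - n // 2) * v
            for n, v in zip(self.shape, self.voxel_size_mm)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))

    def check_same(self, other: "VoxelGrid") -> None:
        if self.shape != other.shape or not np.allclose(
            self.voxel_size_mm, other.voxel_size_mm
        ):
            raise GridMismatchError(f"grid mismatch: {self} vs {other}")


@dataclass
class FieldVolume:
    """A scalar phase/field volume with unit tracking.

    ``units`` is ``'rad'`` for raw phase in radians or ``'normalised'``
    after TE*B0 normalisation (see :func:`msdi.preprocess.normalize_field`).
    ``wrapped`` marks phase still wrapped into [-pi, pi).
    """

    values: np.ndarray
    grid: VoxelGrid
    units: str = "rad"
    te_ms: Optional[float] = None
    b0_T: Optional[float] = None
    wrapped: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != tuple(self.grid.shape):
            raise GridMismatchError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.units not in ("rad", "normalised"):
            raise ValueError(f"unknown field units {self.units!r}")

    def with_values(self, values: np.ndarray, **changes) -> "FieldVolume":
        """Copy of this volume with new data (and optional metadata edits)."""
        return replace(self, values=np.asarray(values, dtype=np.float64), **changes)


def as_roi(mask: np.ndarray, grid: Optional[VoxelGrid] = None) -> np.ndarray:
    """Validate and coerce a region-of-interest mask to boolean."""
    roi = np.asarray(mask).astype(bool)
    if grid is not None and roi.shape != tuple(grid.shape):
        raise GridMismatchError("ROI shape does not match grid")
    if not roi.any():
        raise ValueError("ROI mask is empty")
    return roi
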