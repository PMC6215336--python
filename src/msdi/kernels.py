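"""Frequency-domain dipole and spherical-mean-value (SMV) kernels.

The forward model of susceptibility-induced field perturbations is a
convolution with the unit dipole response, expressed analytically in the
frequency domain (Salomir/Marques form)::

    D(k) = 1/3 - (k . b0)^2 / |k|^2 ,      D(0) = 0 .

``D(0) = 0`` makes all solutions unreferenced (zero DC offset).  The SMV
kernel ``S_l`` is a rasterised sphere of radius ``r_l`` normalised to unit
sum; its high-pass complement ``S~_l = F(delta - S_l)`` suppresses fields
that are harmonic over the sphere (i.e. background fields), which is the
pre-conditioning step of each pyramid scale.

All convolutions are circular (FFT-based); phantom sources therefore keep a
margin of at least the largest SMV radius from the volume edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
import scipy.fft as _fft

from .core import VoxelGrid, GridMismatchError


def _fftn(x: np.ndarray) -> np.ndarray:
    return _fft.fftn(x)


def _ifftn(x: np.ndarray) -> np.ndarray:
    return _fft.ifftn(x)


@dataclass(frozen=True)
class SMVKernel:
    """Spherical-mean-value kernel of a single pyramid scale."""

    radius_mm: float
    spatial: np.ndarray  #: full-grid kernel, origin at index (0,0,0), unit sum
    freq: np.ndarray  #: F(S_l), real
    complement: np.ndarray  #: S~_l = 1 - F(S_l); zero at DC


@dataclass(frozen=True)
class KernelSet:
    """Dipole kernel, per-scale SMV kernels and the chi->phase scaling."""

    grid: VoxelGrid
    dipole: np.ndarray
    smv: Dict[int, SMVKernel] = field(default_factory=dict)
    chi_to_phase: float = 1.0  #: rad per ppm applied in the forward model

    @property
    def radii_mm(self) -> list[float]:
        return [self.smv[i].radius_mm for i in sorted(self.smv)]


def make_dipole_kernel(grid: VoxelGrid) -> np.ndarray:
    """Analytic frequency-domain dipole kernel on the grid's FFT lattice.

    Returns a real array with ``D(0) = 0`` (unreferenced convention).
    """
    kx, ky, kz = grid.freq_grids()
    bx, by, bz = grid.b0_dir
    k2 = kx * kx + ky * ky + kz * kz
    kb = kx * bx + ky * by + kz * bz
    with np.errstate(divide="ignore", invalid="ignore"):
        D = 1.0 / 3.0 - (kb * kb) / k2
    D[k2 == 0] = 0.0
    return np.ascontiguousarray(D)


def make_smv_kernel(grid: VoxelGrid, radius_mm: float) -> SMVKernel:
    """Rasterise the SMV sphere of ``radius_mm`` and its frequency complement.

    A voxel belongs to the kernel when its centre lies within the radius
    (no partial-volume anti-aliasing); anisotropic voxel sizes are honoured.
    """
    radius_mm = float(radius_mm)
    if radius_mm < max(grid.voxel_size_mm):
        raise ValueError(
            f"SMV radius {radius_mm} mm is below the largest voxel dimension "
            f"{max(grid.voxel_size_mm)} mm: kernel would degenerate to a delta"
        )
    if 2.0 * radius_mm >= min(grid.fov_mm):
        raise ValueError(
            f"SMV radius {radius_mm} mm does not fit in the field of view {grid.fov_mm}"
        )
    ox, oy, oz = grid.offset_grids_mm()
    r2 = ox * ox + oy * oy + oz * oz
    inside = r2 <= radius_mm * radius_mm + 1e-12
    spatial = inside.astype(np.float64)
    spatial /= spatial.sum()
    freq = _fftn(spatial).real  # kernel is symmetric -> real spectrum
    complement = 1.0 - freq
    complement.flat[0] = 0.0  # unit-sum kernel: exact high-pass zero at DC
    return SMVKernel(radius_mm=radius_mm, spatial=spatial, freq=freq, complement=complement)


def make_kernel_set(
    grid: VoxelGrid,
    radii_mm: Sequence[float],
    chi_to_phase: float = 1.0,
) -> KernelSet:
    """Bundle the dipole kernel and SMV kernels for a scale schedule."""
    smv = {
        l: make_smv_kernel(grid, r) for l, r in enumerate(radii_mm, start=1)
    }
    return KernelSet(
        grid=grid,
        dipole=make_dipole_kernel(grid),
        smv=smv,
        chi_to_phase=float(chi_to_phase),
    )


def _check_grid(values: np.ndarray, kernels: KernelSet) -> None:
    if values.shape != tuple(kernels.grid.shape):
        raise GridMismatchError(
            f"volume shape {values.shape} != kernel grid {kernels.grid.shape}"
        )


def forward_field(
    chi: np.ndarray,
    kernels: KernelSet,
    highpass_scale: Optional[int] = None,
    scale_to_phase: bool = False,
) -> np.ndarray:
    """Field induced by a susceptibility distribution.

    Computes ``F^H (D F chi)``, or ``F^H (S~_l D F chi)`` when
    ``highpass_scale`` selects a pyramid scale.  With ``scale_to_phase`` the
    result is additionally multiplied by the chi->phase factor of the kernel
    set (rad per ppm); otherwise the output shares the units of ``chi``.
    The operator is linear in ``chi``.
    """
    chi = np.asarray(chi, dtype=np.float64)
    _check_grid(chi, kernels)
    K = kernels.dipole
    if highpass_scale is not None:
        K = K * kernels.smv[highpass_scale].complement
    out = _ifftn(_fftn(chi) * K).real
    if scale_to_phase:
        out = out * kernels.chi_to_phase
    return out


def forward_adjoint(
    y: np.ndarray,
    kernels: KernelSet,
    highpass_scale: Optional[int] = None,
    scale_to_phase: bool = False,
) -> np.ndarray:
    """Adjoint of :func:`forward_field` (conjugate kernel multiplication).

    The dipole and SMV spectra are real and even, so the operator is
    self-adjoint; the conjugation is kept explicit for the inner-product
    test required by the conjugate-gradient solver.
    """
    y = np.asarray(y, dtype=np.float64)
    _check_grid(y, kernels)
    K = kernels.dipole
    if highpass_scale is not None:
        K = K * kernels.smv[highpass_scale].complement
    out = _ifftn(_fftn(y) * np.conj(K)).real
    if scale_to_phase:
        out = out * kernels.chi_to_phase
    return out


def smv_smooth(
    values: np.ndarray,
    roi: np.ndarray,
    kernel: SMVKernel,
    renormalise: bool = True,
) -> np.ndarray:
    """Spherical mean of ``values`` over the ROI.

    With ``renormalise`` (the default) the kernel mass falling outside the
    ROI is discarded and the remaining in-ROI mass rescaled to one, so the
    mean stays unbiased up to the ROI boundary and the mask is not eroded
    between scales.  Output is zero outside the ROI.
    """
    roi_f = roi.astype(np.float64)
    num = _ifftn(_fftn(values * roi_f) * kernel.freq).real
    if not renormalise:
        return num * roi_f
    den = _ifftn(_fftn(roi_f) * kernel.freq).real
    out = np.zeros_like(num)
    ok = roi & (den > 1e-9)
    out[ok] = num[ok] / den[ok]
    return out


def smv_highpass(
    values: np.ndarray,
    roi: np.ndarray,
    kernel: SMVKernel,
    renormalise: bool = True,
) -> np.ndarray:
    """High-pass complement of the spherical mean, restricted to the ROI."""
    out = (values - smv_smooth(values, roi, kernel, renormalise=renormalise))
    out[~roi.astype(bool)] = 0.0
    return out
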