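"""Phase pre-processing: unwrapping, background removal, normalisation.

The inversion consumes a local (background-filtered) field map in
normalised units together with magnitude-derived noise weights.  This
module provides the algorithmic core of that chain:

* Laplacian phase unwrapping (sin/cos Laplacian + Neumann Poisson solve),
* variable-kernel SMV background removal (vSMV) with a large initial
  radius shrinking towards the ROI boundary,
* TE*B0 = 60 ms*T field normalisation,
* composite inverse-magnitude noise weights per pyramid scale,
* the second-difference phase-quality map feeding the reliability masks.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Optional, Tuple

import numpy as np
import scipy.fft as _fft

from .core import REFERENCE_TE_B0_MS_T, FieldVolume, VoxelGrid, as_roi
from .kernels import SMVKernel, make_smv_kernel, smv_smooth


# ---------------------------------------------------------------------------
# Laplacian unwrapping
# ---------------------------------------------------------------------------

def _neumann_laplacian(x: np.ndarray, voxel_size_mm) -> np.ndarray:
    """Discrete 7-point Laplacian with edge-replicated (Neumann) boundaries."""
    out = np.zeros_like(x)
    for ax, h in enumerate(voxel_size_mm):
        p = np.pad(
            x,
            [(1, 1) if a == ax else (0, 0) for a in range(x.ndim)],
            mode="edge",
        )
        sl_lo = [slice(None)] * x.ndim
        sl_hi = [slice(None)] * x.ndim
        sl_mid = [slice(None)] * x.ndim
        sl_lo[ax] = slice(0, -2)
        sl_hi[ax] = slice(2, None)
        sl_mid[ax] = slice(1, -1)
        out += (p[tuple(sl_lo)] + p[tuple(sl_hi)] - 2.0 * p[tuple(sl_mid)]) / h**2
    return out


def _poisson_solve_neumann(rhs: np.ndarray, voxel_size_mm) -> np.ndarray:
    """Solve ``lap(u) = rhs`` under Neumann boundaries via DCT-II; zero mean."""
    coeff = _fft.dctn(rhs, type=2, norm="ortho")
    eig = np.zeros(rhs.shape)
    for ax, (n, h) in enumerate(zip(rhs.shape, voxel_size_mm)):
        k = np.arange(n).reshape([-1 if a == ax else 1 for a in range(rhs.ndim)])
        eig = eig + (2.0 * np.cos(np.pi * k / n) - 2.0) / h**2
    eig.flat[0] = 1.0  # DC handled separately (set to zero below)
    coeff = coeff / eig
    coeff.flat[0] = 0.0
    return _fft.idctn(coeff, type=2, norm="ortho")


def laplacian_unwrap(wrapped: FieldVolume, snap_to_cycles: bool = True) -> FieldVolume:
    """Unwrap phase by inverting the Laplacian estimated from sin/cos.

    ``lap(phi) ~= cos(w) lap(sin w) - sin(w) lap(cos w)`` holds for any
    wrapped representative ``w`` of the phase, so solving the (Neumann)
    Poisson problem recovers the unwrapped phase up to terms in the
    operator's null space.  With ``snap_to_cycles`` (the default) the
    spectral estimate is then used only to pick the integer 2*pi cycle of
    each voxel, so the output is exactly congruent to the measured phase
    and the smooth approximation error of the Poisson solve is discarded.
    The global offset is unrecoverable and fixed to zero mean, consistent
    with unreferenced susceptibility maps.
    """
    w = wrapped.values
    vox = wrapped.grid.voxel_size_mm
    sin_w, cos_w = np.sin(w), np.cos(w)
    rhs = cos_w * _neumann_laplacian(sin_w, vox) - sin_w * _neumann_laplacian(cos_w, vox)
    phi = _poisson_solve_neumann(rhs, vox)
    if snap_to_cycles:
        two_pi = 2.0 * np.pi
        phi = w + two_pi * np.round((phi - w) / two_pi)
        phi = phi - phi.mean()
    return wrapped.with_values(phi, wrapped=False)


# ---------------------------------------------------------------------------
# vSMV background removal
# ---------------------------------------------------------------------------

def vsmv_background_removal(
    phi: FieldVolume,
    roi: np.ndarray,
    r0_mm: float = 40.0,
    step_mm: Optional[float] = None,
    rmin_mm: Optional[float] = None,
) -> Tuple[FieldVolume, np.ndarray]:
    """Variable-kernel spherical-mean background filtering.

    Each ROI voxel has the spherical mean of the *largest* kernel radius
    that still fits entirely inside the ROI subtracted, sweeping radii
    from ``r0_mm`` down to ``rmin_mm`` in steps of ``step_mm`` (both
    default to one voxel).  Harmonic background fields equal their
    spherical mean and are thereby suppressed; the output ROI loses only
    a one-kernel (``rmin``) boundary shell.
    """
    grid = phi.grid
    roi = as_roi(roi, grid)
    vox_max = max(grid.voxel_size_mm)
    if step_mm is None:
        step_mm = vox_max
    if rmin_mm is None:
        rmin_mm = vox_max
    if not (r0_mm >= rmin_mm >= vox_max):
        raise ValueError("need r0_mm >= rmin_mm >= one voxel")

    radii = list(np.arange(r0_mm, rmin_mm - 1e-9, -step_mm))
    if not radii or radii[-1] > rmin_mm + 1e-9:
        radii.append(rmin_mm)
    # Kernels larger than the FOV can never fit inside the ROI.
    radii = [r for r in radii if 2.0 * r < min(grid.fov_mm)]
    if not radii:
        raise ValueError("no vSMV kernel fits the field of view")

    roi_f = roi.astype(np.float64)
    roi_spec = _fft.fftn(roi_f)
    phi_spec = _fft.fftn(phi.values * roi_f)

    out = np.zeros(grid.shape)
    assigned = np.zeros(grid.shape, dtype=bool)
    roi_out = np.zeros(grid.shape, dtype=bool)
    for r in radii:
        kern = make_smv_kernel(grid, r)
        coverage = _fft.ifftn(roi_spec * kern.freq).real
        nvox_kernel = int(round(1.0 / kern.spatial.max()))
        fits = roi & (coverage >= 1.0 - 0.5 / nvox_kernel)
        if not fits.any():
            continue
        roi_out |= fits
        fresh = fits & ~assigned
        if fresh.any():
            mean_r = _fft.ifftn(phi_spec * kern.freq).real
            out[fresh] = phi.values[fresh] - mean_r[fresh]
            assigned |= fresh
    if not roi_out.any():
        raise ValueError("ROI too small: no voxel admits the minimum vSMV kernel")
    out[~roi_out] = 0.0
    return phi.with_values(out), roi_out


# ---------------------------------------------------------------------------
# Field normalisation
# ---------------------------------------------------------------------------

def normalize_field(phi: FieldVolume) -> FieldVolume:
    """Scale the field by ``60 / (TE[ms] * B0[T])`` and mark it normalised.

    Harmonises effective echo times across acquisitions so a single
    regularisation-parameter range transfers between protocols.  Applying
    the normalisation twice is an error.
    """
    if phi.units == "normalised":
        raise ValueError("field is already normalised")
    if not phi.te_ms or not phi.b0_T:
        raise ValueError("te_ms and b0_T must be set (and non-zero) to normalise")
    scale = REFERENCE_TE_B0_MS_T / (phi.te_ms * phi.b0_T)
    return phi.with_values(phi.values * scale, units="normalised")


def denormalize_field(phi: FieldVolume) -> FieldVolume:
    """Inverse of :func:`normalize_field` (unit-tracked)."""
    if phi.units != "normalised":
        raise ValueError("field is not normalised")
    scale = (phi.te_ms * phi.b0_T) / REFERENCE_TE_B0_MS_T
    return phi.with_values(phi.values * scale, units="rad")


# ---------------------------------------------------------------------------
# Noise weights
# ---------------------------------------------------------------------------

def noise_weight(
    magnitude: np.ndarray,
    roi: np.ndarray,
    smv_kernel: SMVKernel,
) -> np.ndarray:
    """Composite inverse-noise weight ``[A^-2 + A_l^-2]^(-1/2)`` per scale.

    Phase noise scales inversely with signal magnitude; the high-pass
    filtered phase of scale ``l`` combines the raw phase and its spherical
    mean, so both the magnitude ``A`` and its SMV-smoothed counterpart
    ``A_l = S_l * A`` enter the composite weight.  Each term is normalised
    to unit mean over the ROI; the result is zero outside the ROI, and
    non-positive (dead) voxels get weight zero with a warning.
    """
    mag = np.asarray(magnitude, dtype=np.float64)
    roi = as_roi(mag_shape_check(mag, roi))
    dead = roi & (mag <= 0)
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} non-positive magnitude voxels inside ROI; weight set to 0",
            stacklevel=2,
        )
    a_hat = np.zeros_like(mag)
    live = roi & (mag > 0)
    a_hat[live] = mag[live] / mag[live].mean()
    a_l = smv_smooth(mag, roi, smv_kernel)
    a_l_hat = np.zeros_like(a_l)
    live_l = live & (a_l > 0)
    a_l_hat[live_l] = a_l[live_l] / a_l[roi & (a_l > 0)].mean()
    w = np.zeros_like(mag)
    ok = live & live_l
    w[ok] = 1.0 / np.sqrt(a_hat[ok] ** -2 + a_l_hat[ok] ** -2)
    return w


def mag_shape_check(mag: np.ndarray, roi: np.ndarray) -> np.ndarray:
    if np.asarray(roi).shape != mag.shape:
        raise ValueError("magnitude and ROI shapes differ")
    return roi


# ---------------------------------------------------------------------------
# Second-difference phase-quality map
# ---------------------------------------------------------------------------

#: The 13 unique axis directions of the 3x3x3 neighbourhood (antipodal
#: pairs collapsed; first non-zero component positive).
SECOND_DIFF_DIRECTIONS: tuple[tuple[int, int, int], ...] = tuple(
    d
    for d in itertools.product((-1, 0, 1), repeat=3)
    if d != (0, 0, 0) and (d > (0, 0, 0))
)


def _wrap_to_pi(x: np.ndarray) -> np.ndarray:
    return np.mod(x + np.pi, 2.0 * np.pi) - np.pi


def second_difference_map(phi: FieldVolume) -> np.ndarray:
    """Root-sum-of-squares of second differences over 13 directions.

    For each direction ``d`` of the 3x3x3 neighbourhood the second
    difference ``phi(x+d) - 2 phi(x) + phi(x-d)`` is accumulated; boundary
    voxels use only the directions for which both neighbours exist.  When
    the input is flagged wrapped, differences are taken modulo 2*pi.
    Large values mark unreliable, rapidly varying phase neighbourhoods.
    """
    x = phi.values
    out = np.zeros_like(x)
    def _sl(a: int, off: int, n: int) -> slice:
        stop = n - a + off
        return slice(a + off, None if stop == n else stop)

    for d in SECOND_DIFF_DIRECTIONS:
        centre = tuple(_sl(abs(di), 0, n) for di, n in zip(d, x.shape))
        plus = tuple(_sl(abs(di), di, n) for di, n in zip(d, x.shape))
        minus = tuple(_sl(abs(di), -di, n) for di, n in zip(d, x.shape))
        diff = x[plus] - 2.0 * x[centre] + x[minus]
        if phi.wrapped:
            diff = _wrap_to_pi(diff)
        out[centre] += diff**2
    return np.sqrt(out)
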