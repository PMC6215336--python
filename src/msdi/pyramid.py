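"""Multi-scale dipole inversion: the Laplacian-pyramid scale loop.

Starting from a normalised local-field map ``phi``, each scale ``l``:

1. re-initialises the residual field ``phi_l = phi - D * X_{l-1}``
   (telescoping: equivalently ``phi_{l-1} - D * X'_{l-1}``),
2. high-pass filters it with the scale's SMV kernel,
   ``phi'_l = phi_l - S_l * phi_l`` (ROI-renormalised, no mask erosion),
3. rebuilds the composite noise weight, reliability mask and (scale 1
   only) the morphological edge prior,
4. solves the constrained deconvolution for the increment ``X'_l`` and
   accumulates ``X_l = X_{l-1} + X'_l``.

The full-resolution map is the final cumulative sum; any prefix sum is a
high-pass susceptibility map (HPSM) that only contains short-range dipole
fields and is therefore insensitive to smooth background contributions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field, replace
from typing import List, Optional, Sequence

import numpy as np

from .core import FieldVolume, PHASE_PER_PPM_NORM, VoxelGrid, as_roi
from .inversion import ScaleSpec, edge_mask, reliability_mask, solve_scale
from .kernels import KernelSet, forward_field, make_kernel_set, smv_smooth
from .preprocess import noise_weight, second_difference_map

#: Reference scale schedule: power-of-two SMV radii in millimetres.
DEFAULT_RADII_MM = (2.0, 4.0, 8.0, 16.0)


@dataclass
class ScaleResult:
    """Per-scale output of :func:`run_msdi`."""

    scale_index: int
    spec: ScaleSpec
    chi_delta: np.ndarray  #: X'_l (ppm)
    chi_cum: np.ndarray  #: X_l = sum of increments up to this scale (ppm)
    weights_final: np.ndarray
    qmask: np.ndarray
    cost_history: list
    converged: bool
    phi_scale: np.ndarray  #: phi_l fed to this scale (normalised rad)
    phi_highpass: np.ndarray  #: phi'_l after SMV filtering


@dataclass
class MSDIConfig:
    """Ordered list of scale specifications (radii strictly increasing).

    The default schedule uses four scales at 2/4/8/16 mm (snapped to the
    voxel resolution), a single shared regularisation parameter
    ``lambda = 10^2.7`` and the morphological edge prior on the first
    scale only.  Per-scale overrides (e.g. increasing lambda as the
    maximum radius shrinks, for high-fidelity HPSM) are supported by
    editing individual :class:`~msdi.inversion.ScaleSpec` entries.
    """

    scales: List[ScaleSpec] = dc_field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.scales:
            raise ValueError("MSDIConfig needs at least one scale")
        radii = [s.r_mm for s in self.scales]
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError(f"scale radii must be strictly increasing, got {radii}")

    @property
    def radii_mm(self) -> List[float]:
        return [s.r_mm for s in self.scales]

    @classmethod
    def default(
        cls,
        voxel_size_mm: Sequence[float] = (1.0, 1.0, 1.0),
        lam: float = 10**2.7,
        radii_mm: Sequence[float] = DEFAULT_RADII_MM,
        max_scale: Optional[int] = None,
        **spec_overrides,
    ) -> "MSDIConfig":
        """Reference configuration; ``max_scale`` truncates for HPSM use."""
        realised = scale_schedule(voxel_size_mm, radii_mm)
        if max_scale is not None:
            realised = realised[:max_scale]
        scales = [
            ScaleSpec(r_mm=r, lam=lam, use_edge_prior=(i == 0), **spec_overrides)
            for i, r in enumerate(realised)
        ]
        return cls(scales=scales)


def scale_schedule(
    voxel_size_mm: Sequence[float], radii_mm: Sequence[float]
) -> List[float]:
    """Snap requested SMV radii to multiples of the coarsest voxel size.

    Each radius maps to the nearest positive multiple of the largest
    voxel dimension (ties round up); duplicates collapse with a warning.
    """
    radii = [float(r) for r in radii_mm]
    if not radii or any(r <= 0 for r in radii):
        raise ValueError("radii must be positive")
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be ascending")
    v = max(float(h) for h in voxel_size_mm)
    snapped = [max(1, int(np.floor(r / v + 0.5))) * v for r in radii]
    out: List[float] = []
    for r in snapped:
        if out and abs(r - out[-1]) < 1e-9:
            warnings.warn(f"duplicate realised SMV radius {r} mm collapsed", stacklevel=2)
            continue
        out.append(r)
    if not out:
        raise ValueError("empty scale schedule")
    return out


def run_msdi(
    phi: FieldVolume,
    magnitude: np.ndarray,
    roi: np.ndarray,
    config: MSDIConfig,
    second_diff: Optional[np.ndarray] = None,
) -> List[ScaleResult]:
    """Run the full multi-scale inversion and return all scale results.

    ``phi`` must be in normalised units (see
    :func:`msdi.preprocess.normalize_field`), background-filtered or raw
    per the caller's choice.  ``second_diff`` optionally supplies a
    precomputed phase second-difference map (e.g. from the wrapped
    measured phase); by default it is derived from ``phi`` itself.
    """
    if phi.units != "normalised":
        raise ValueError("run_msdi expects a normalised field (see normalize_field)")
    grid = phi.grid
    roi = as_roi(roi, grid)
    magnitude = np.asarray(magnitude, dtype=np.float64)
    radii = config.radii_mm
    kernels = make_kernel_set(grid, radii, chi_to_phase=PHASE_PER_PPM_NORM)
    if second_diff is None:
        second_diff = second_difference_map(phi)

    results: List[ScaleResult] = []
    chi_cum = np.zeros(grid.shape)
    for l, spec in enumerate(config.scales, start=1):
        phi_l = phi.values - forward_field(chi_cum, kernels, scale_to_phase=True)
        phi_hp = phi_l - smv_smooth(phi_l, roi, kernels.smv[l])
        phi_hp[~roi] = 0.0
        weights = noise_weight(magnitude, roi, kernels.smv[l])
        qmask = reliability_mask(
            second_diff, roi, l, q_percent=spec.q_percent, radii_mm=radii
        )
        emask = (
            edge_mask(magnitude, roi, spec.edge_fraction, grid.voxel_size_mm)
            if spec.use_edge_prior
            else None
        )
        try:
            sol = solve_scale(
                phi_hp, weights, qmask, emask, kernels, spec, scale_index=l, roi=roi
            )
        except Exception as err:
            raise RuntimeError(f"MSDI failed at scale {l} (r = {spec.r_mm} mm)") from err
        chi_cum = chi_cum + sol.chi
        results.append(
            ScaleResult(
                scale_index=l,
                spec=spec,
                chi_delta=sol.chi,
                chi_cum=chi_cum.copy(),
                weights_final=sol.weights_final,
                qmask=qmask,
                cost_history=sol.cost_history,
                converged=sol.converged,
                phi_scale=phi_l,
                phi_highpass=phi_hp,
            )
        )
    return results


def hpsm(results: Sequence[ScaleResult], max_scale: int = 1) -> np.ndarray:
    """High-pass susceptibility map: cumulative sum of the first scales."""
    if not 1 <= max_scale <= len(results):
        raise ValueError("max_scale out of range")
    return results[max_scale - 1].chi_cum
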