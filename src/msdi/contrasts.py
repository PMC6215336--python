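"""Susceptibility-derived contrasts: VenoMSDI, MVSSM, HPSM-SWI, projections.

Sign convention: maps are unreferenced (zero volume mean) and
paramagnetic-positive, so venous blood and iron-rich tissue appear as
positive susceptibilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d


def veno_mask(hpsm_highreg: np.ndarray) -> np.ndarray:
    """Binary vessel mask from a highly regularised short-range map.

    Intended input: HPSM with r_max = 2 mm and strong regularisation
    (reference lambda = 10^1.6), where positive values are almost
    exclusively venous blood.  The mask is simply susceptibility > 0.
    """
    return (np.asarray(hpsm_highreg) > 0).astype(np.uint8)


def mvssm(chi_full: np.ndarray, vessel_mask: np.ndarray) -> np.ndarray:
    """Macroscopic-vessel-suppressed map: chi * (1 - mask).

    Vessel voxels are reset to exactly zero; all other values are
    preserved bit-exactly.
    """
    chi_full = np.asarray(chi_full)
    vessel_mask = np.asarray(vessel_mask)
    if chi_full.shape != vessel_mask.shape:
        raise ValueError("chi and vessel mask shapes differ")
    out = chi_full.copy()
    out[vessel_mask.astype(bool)] = 0.0
    return out


@dataclass
class SWIWeights:
    """SWI weighting volume Gamma in [0, 1] with its generating ramp."""

    values: np.ndarray
    critical_value_ppm: float
    power: int = 4


def hpsm_swi_weights(chi1: np.ndarray, c_ppm: float = 0.2, power: int = 4) -> SWIWeights:
    """Linear susceptibility ramp for magnitude weighting.

    Gamma = 1 for chi < 0, (c - chi)/c on [0, c], 0 above the critical
    value c (default 0.2 ppm), so strongly paramagnetic (venous) voxels
    are maximally attenuated.
    """
    if c_ppm <= 0:
        raise ValueError("critical value must be positive")
    chi1 = np.asarray(chi1, dtype=np.float64)
    gamma = np.clip((c_ppm - chi1) / c_ppm, 0.0, 1.0)
    return SWIWeights(values=gamma, critical_value_ppm=float(c_ppm), power=int(power))


def apply_swi(magnitude: np.ndarray, weights: SWIWeights) -> np.ndarray:
    """Weight the (mean-normalised) magnitude by Gamma**power (default 4)."""
    magnitude = np.asarray(magnitude, dtype=np.float64)
    if magnitude.shape != weights.values.shape:
        raise ValueError("magnitude and weights shapes differ")
    return magnitude * weights.values**weights.power


def intensity_projection(
    volume: np.ndarray,
    axis: int,
    extent_mm: float,
    mode: str,
    voxel_size_mm: Sequence[float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Sliding-window minimum/maximum intensity projection (mIP/MIP).

    The physical extent converts to the nearest odd slice count so the
    window is centred; boundaries replicate the edge slice.  Reference
    extents: 7.5 mm for mIP-SWI and 15 mm for MIP-HPSM.
    """
    if mode not in ("min", "max"):
        raise ValueError("mode must be 'min' or 'max'")
    h = float(voxel_size_mm[axis])
    slices = extent_mm / h
    if slices < 1.0 - 1e-9:
        raise ValueError("projection extent is below one slice")
    n = max(1, 2 * int(np.floor((slices - 1.0) / 2.0 + 0.5)) + 1)
    filt = minimum_filter1d if mode == "min" else maximum_filter1d
    return filt(np.asarray(volume, dtype=np.float64), size=n, axis=axis, mode="nearest")
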