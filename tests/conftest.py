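"""Shared fixtures: grids, phantoms and the (expensive) reference pipeline run.

Session-scoped fixtures cache the standard-phantom simulation, its
preprocessing and the full multi-scale inversion so the recovery,
venography, robustness and acceptance tests share one computation.

The reference inversion runs on the unwrapped, normalised field without
prior background filtering: the pyramid's own SMV preconditioning
suppresses the external sources, and on this compact phantom geometry a
variable-kernel background filter would also erase much of the
long-range field of interior sources (see docs/methods.md).  vSMV has
its own unit and regression tests.
"""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from msdi import (
    MSDIConfig,
    VoxelGrid,
    laplacian_unwrap,
    make_kernel_set,
    make_phantom,
    normalize_field,
    run_msdi,
    simulate_acquisition,
    standard_phantom_spec,
    vsmv_background_removal,
)
from msdi.preprocess import second_difference_map


@pytest.fixture(scope="session")
def grid64() -> VoxelGrid:
    return VoxelGrid((64, 64, 64), (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def grid32() -> VoxelGrid:
    return VoxelGrid((32, 32, 32), (1.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def kernels64(grid64):
    return make_kernel_set(grid64, (2.0, 4.0, 8.0, 16.0))


@pytest.fixture(scope="session")
def standard_sim():
    """Standard phantom (seed 1234, SNR 50) and its simulated acquisition."""
    spec = standard_phantom_spec(seed=1234, snr=50.0)
    ph = make_phantom(spec)
    sim = simulate_acquisition(ph.chi, ph.magnitude, ph.roi, spec)
    return ph, sim


@pytest.fixture(scope="session")
def standard_preprocessed(standard_sim):
    """Unwrapped + normalised field (and the vSMV variant) of the standard run."""
    ph, sim = standard_sim
    unwrapped = laplacian_unwrap(sim["wrapped_phase"])
    phi = normalize_field(unwrapped)
    second_diff = second_difference_map(sim["wrapped_phase"])
    filtered, roi_vsmv = vsmv_background_removal(unwrapped, ph.roi, r0_mm=40.0)
    return {
        "phantom": ph,
        "sim": sim,
        "phi": phi,
        "roi": ph.roi,
        "phi_vsmv": normalize_field(filtered),
        "roi_vsmv": roi_vsmv,
        "second_diff": second_diff,
    }


def _run(pre, phi_key, roi_key, **cfg_kwargs):
    cfg = MSDIConfig.default(pre[phi_key].grid.voxel_size_mm, **cfg_kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_msdi(
            pre[phi_key],
            pre["sim"]["noisy_magnitude"],
            pre[roi_key],
            cfg,
            second_diff=pre["second_diff"],
        )


@pytest.fixture(scope="session")
def standard_msdi(standard_preprocessed):
    """Full four-scale inversion of the standard phantom (default config)."""
    return _run(standard_preprocessed, "phi", "roi")


@pytest.fixture(scope="session")
def vsmv_msdi(standard_preprocessed):
    """Same inversion on the vSMV background-filtered field."""
    return _run(standard_preprocessed, "phi_vsmv", "roi_vsmv")


@pytest.fixture(scope="session")
def veno_hpsm(standard_preprocessed):
    """Highly regularised single-scale map (r_max 2 mm, lambda 10^1.6)."""
    results = _run(standard_preprocessed, "phi", "roi", lam=10**1.6, max_scale=1)
    return results[-1].chi_cum
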