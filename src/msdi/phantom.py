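"""Synthetic susceptibility phantoms and simulated acquisitions.

Scenes are piecewise-constant susceptibility distributions (spheres,
ellipsoids, cylinders) inside a spherical region of interest, optionally
with point-dipole background sources placed strictly outside the ROI to
emulate air/tissue and other external field contributions.  The simulator
produces the quantities an MRI scanner would deliver: a wrapped phase
volume and a noisy magnitude volume, with i.i.d. complex Gaussian noise at
a prescribed SNR.

The analytic exterior field of a uniform sphere,

    dB/B0 = (dchi/3) (a/r)^3 (3 cos^2 theta - 1),   zero inside,

serves as the independent oracle for the k-space dipole model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import FieldVolume, VoxelGrid, phase_per_ppm
from .kernels import KernelSet, forward_field, make_dipole_kernel


@dataclass(frozen=True)
class ObjectSpec:
    """One piecewise-constant susceptibility object.

    ``shape`` is ``sphere`` (size = (radius,)), ``ellipsoid``
    (size = (a, b, c) semi-axes) or ``cylinder`` (size = (radius,
    half_length), with ``axis`` the long axis index).  ``centre_mm`` is
    relative to the volume centre.  ``magnitude`` scales the tissue signal
    inside the object.
    """

    shape: str
    centre_mm: Tuple[float, float, float]
    size_mm: Tuple[float, ...]
    chi_ppm: float
    magnitude: float = 1.0
    axis: int = 2


@dataclass(frozen=True)
class BackgroundSource:
    """Point dipole outside the ROI: moment in ppm*mm^3 (chi * volume)."""

    position_mm: Tuple[float, float, float]
    moment: float


@dataclass
class PhantomSpec:
    grid: VoxelGrid
    objects: List[ObjectSpec] = dc_field(default_factory=list)
    background_sources: List[BackgroundSource] = dc_field(default_factory=list)
    roi_radius_mm: float = 28.0
    snr: float = 50.0
    te_ms: float = 20.0
    b0_T: float = 3.0
    seed: int = 1234
    edge_margin_mm: float = 16.0  #: min object distance to volume edges (= r_max)


@dataclass
class Phantom:
    chi: np.ndarray
    magnitude: np.ndarray
    roi: np.ndarray
    labels: np.ndarray
    grid: VoxelGrid
    spec: PhantomSpec


def _object_mask(obj: ObjectSpec, grid: VoxelGrid) -> np.ndarray:
    x, y, z = grid.coords_mm()
    dx, dy, dz = (c - o for c, o in zip((x, y, z), obj.centre_mm))
    if obj.shape == "sphere":
        (r,) = obj.size_mm
        return dx * dx + dy * dy + dz * dz <= r * r
    if obj.shape == "ellipsoid":
        a, b, c = obj.size_mm
        return (dx / a) ** 2 + (dy / b) ** 2 + (dz / c) ** 2 <= 1.0
    if obj.shape == "cylinder":
        r, half = obj.size_mm
        d = [dx, dy, dz]
        along = d.pop(obj.axis)
        return (d[0] ** 2 + d[1] ** 2 <= r * r) & (np.abs(along) <= half)
    raise ValueError(f"unknown object shape {obj.shape!r}")


def _object_extent_mm(obj: ObjectSpec) -> np.ndarray:
    """Per-axis half-extents of the object's bounding box, mm."""
    if obj.shape == "sphere":
        (r,) = obj.size_mm
        return np.array([r, r, r], dtype=float)
    if obj.shape == "ellipsoid":
        return np.asarray(obj.size_mm, dtype=float)
    if obj.shape == "cylinder":
        r, half = obj.size_mm
        ext = np.array([r, r, r], dtype=float)
        ext[obj.axis] = half
        return ext
    raise ValueError(f"unknown object shape {obj.shape!r}")


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Rasterise the scene: chi, tissue magnitude, ROI and label volumes.

    Overlapping objects follow last-object-wins precedence, in both chi
    and the label map.  The tissue magnitude carries a smooth seeded bias
    field to exercise the noise-weighting machinery.  Deterministic given
    the spec seed.
    """
    grid = spec.grid
    x, y, z = grid.coords_mm()
    roi = x * x + y * y + z * z <= spec.roi_radius_mm**2

    half_fov = np.asarray(grid.fov_mm) / 2.0
    for obj in spec.objects:
        ext = _object_extent_mm(obj)
        centre = np.asarray(obj.centre_mm)
        corner = np.abs(centre) + ext
        if np.linalg.norm(corner) > spec.roi_radius_mm:
            raise ValueError(f"object {obj} extends outside the ROI")
        if np.any(corner > half_fov - spec.edge_margin_mm + 1e-9):
            raise ValueError(
                f"object {obj} violates the {spec.edge_margin_mm} mm edge margin "
                "required by circular convolution"
            )
    for src in spec.background_sources:
        if np.linalg.norm(src.position_mm) <= spec.roi_radius_mm:
            raise ValueError(f"background source {src} lies inside the ROI")

    chi = np.zeros(grid.shape)
    labels = np.zeros(grid.shape, dtype=np.int32)
    magnitude = np.where(roi, 1.0, 0.05)
    for idx, obj in enumerate(spec.objects, start=1):
        m = _object_mask(obj, grid)
        chi[m] = obj.chi_ppm
        labels[m] = idx
        magnitude[m] = 0.05 + (obj.magnitude - 0.05) * roi[m]

    # Smooth multiplicative bias: band-limited seeded noise, ~+/-10%.
    rng = np.random.default_rng(spec.seed)
    coarse = rng.standard_normal((4, 4, 4))
    from scipy.ndimage import zoom

    bias = zoom(coarse, [s / 4 for s in grid.shape], order=3)[
        : grid.shape[0], : grid.shape[1], : grid.shape[2]
    ]
    bias = 1.0 + 0.1 * bias / max(np.abs(bias).max(), 1e-12)
    magnitude = magnitude * bias
    return Phantom(
        chi=chi, magnitude=magnitude, roi=roi, labels=labels, grid=grid, spec=spec
    )


def analytic_sphere_field(
    chi_ppm: float,
    radius_mm: float,
    grid: VoxelGrid,
    centre_mm: Sequence[float] = (0.0, 0.0, 0.0),
) -> np.ndarray:
    """Analytic field shift (ppm of B0) of a uniform susceptibility sphere.

    Exterior: ``(chi/3) (a/r)^3 (3 cos^2 theta - 1)`` with theta measured
    from the B0 direction; exactly zero inside the sphere (Lorentz-corrected
    measured field).
    """
    x, y, z = grid.coords_mm()
    dx, dy, dz = x - centre_mm[0], y - centre_mm[1], z - centre_mm[2]
    r2 = dx * dx + dy * dy + dz * dz
    bx, by, bz = grid.b0_dir
    rb = dx * bx + dy * by + dz * bz
    with np.errstate(divide="ignore", invalid="ignore"):
        cos2 = rb * rb / r2
        fieldv = (chi_ppm / 3.0) * (radius_mm**2 / r2) ** 1.5 * (3.0 * cos2 - 1.0)
    fieldv[r2 <= radius_mm * radius_mm] = 0.0
    return fieldv


def background_field(
    sources: Sequence[BackgroundSource], grid: VoxelGrid
) -> np.ndarray:
    """Superposed point-dipole fields (ppm of B0) of external sources."""
    out = np.zeros(grid.shape)
    x, y, z = grid.coords_mm()
    bx, by, bz = grid.b0_dir
    for src in sources:
        dx, dy, dz = x - src.position_mm[0], y - src.position_mm[1], z - src.position_mm[2]
        r2 = dx * dx + dy * dy + dz * dz
        rb = dx * bx + dy * by + dz * bz
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = src.moment * (3.0 * rb * rb / r2 - 1.0) / (4.0 * np.pi * r2**1.5)
        contrib[r2 < 1e-9] = 0.0
        out += contrib
    return out


def simulate_acquisition(
    chi: np.ndarray,
    magnitude: np.ndarray,
    roi: np.ndarray,
    spec: PhantomSpec,
    kernels: Optional[KernelSet] = None,
) -> Dict[str, np.ndarray | FieldVolume]:
    """Forward-simulate the complex GRE signal and return wrapped phase.

    field[ppm] = dipole_conv(chi) + sum of background-source fields;
    signal = magnitude * exp(i * chi_to_phase * field) + complex Gaussian
    noise with per-component sigma = mean(magnitude in ROI) / SNR.
    """
    grid = spec.grid
    if kernels is None:
        kernels = KernelSet(grid=grid, dipole=make_dipole_kernel(grid))
    field_ppm = forward_field(chi, kernels)
    if spec.background_sources:
        field_ppm = field_ppm + background_field(spec.background_sources, grid)
    scale = phase_per_ppm(spec.te_ms, spec.b0_T)
    phase = scale * field_ppm
    signal = magnitude * np.exp(1j * phase)
    if np.isfinite(spec.snr):
        rng = np.random.default_rng(spec.seed)
        sigma = float(magnitude[roi].mean()) / spec.snr
        noise = sigma * (
            rng.standard_normal(grid.shape) + 1j * rng.standard_normal(grid.shape)
        )
        signal = signal + noise
    wrapped = FieldVolume(
        values=np.angle(signal),
        grid=grid,
        units="rad",
        te_ms=spec.te_ms,
        b0_T=spec.b0_T,
        wrapped=True,
    )
    return {
        "wrapped_phase": wrapped,
        "noisy_magnitude": np.abs(signal),
        "field_ppm": field_ppm,
        "true_phase": phase,
    }


def standard_phantom_spec(seed: int = 1234, snr: float = 50.0) -> PhantomSpec:
    """The versioned 'standard phantom' used throughout the test suite.

    64^3 grid at 1 mm isotropic, spherical ROI of radius 28 mm, three
    paramagnetic nuclei-like spheres (0.05/0.10/0.20 ppm), two 1.5-mm
    venous-blood-like cylinders (0.45 ppm), one diamagnetic slab
    (-0.05 ppm) and two external dipole sources.  TE*B0 = 60 ms*T so the
    normalisation step is unity.
    """
    import importlib.resources as res

    import yaml

    text = res.files("msdi").joinpath("data/standard_phantom.yaml").read_text()
    return phantom_spec_from_dict(yaml.safe_load(text), seed=seed, snr=snr)


def phantom_spec_from_dict(
    d: dict, seed: Optional[int] = None, snr: Optional[float] = None
) -> PhantomSpec:
    """Build a :class:`PhantomSpec` from a plain (YAML-friendly) mapping."""
    grid = VoxelGrid(
        shape=tuple(d["grid"]["shape"]),
        voxel_size_mm=tuple(d["grid"]["voxel_size_mm"]),
        b0_dir=tuple(d["grid"].get("b0_dir", (0, 0, 1))),
    )
    objects = [
        ObjectSpec(
            shape=o["shape"],
            centre_mm=tuple(o["centre_mm"]),
            size_mm=tuple(o["size_mm"]),
            chi_ppm=float(o["chi_ppm"]),
            magnitude=float(o.get("magnitude", 1.0)),
            axis=int(o.get("axis", 2)),
        )
        for o in d.get("objects", [])
    ]
    sources = [
        BackgroundSource(position_mm=tuple(s["position_mm"]), moment=float(s["moment"]))
        for s in d.get("background_sources", [])
    ]
    return PhantomSpec(
        grid=grid,
        objects=objects,
        background_sources=sources,
        roi_radius_mm=float(d.get("roi_radius_mm", 28.0)),
        snr=float(snr if snr is not None else d.get("snr", 50.0)),
        te_ms=float(d.get("te_ms", 20.0)),
        b0_T=float(d.get("b0_T", 3.0)),
        seed=int(seed if seed is not None else d.get("seed", 1234)),
        edge_margin_mm=float(d.get("edge_margin_mm", 16.0)),
    )
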