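"""Single-scale nonlinear morphology-constrained dipole deconvolution.

Each pyramid scale solves the constrained minimisation

    X'_l = argmin_X  lambda * || Q_l W_l (exp(i A X) - exp(i phi'_l)) ||_2^2
                     + || M_grad grad X ||_1

where ``A`` is the high-pass dipole forward operator of the scale
(including the chi->phase scaling), ``W_l`` the magnitude-derived noise
weight with MERIT residual down-weighting, ``Q_l`` the scale-specific
phase-reliability mask and ``M_grad`` the binary morphological (edge)
masks that exempt strong magnitude gradients from the sparsity penalty.

The solver is a quasi-Newton fixed-point iteration: the complex
exponential is linearised to first order, the l1 term is reweighted with
``1/sqrt(|grad X|^2 + e)``, and the resulting normal equations are solved
by conjugate gradients to a loose relative tolerance.  The outer loop
stops when the relative update norm falls below ``outer_tol``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .core import VoxelGrid, as_roi
from .kernels import KernelSet, forward_adjoint, forward_field


@dataclass
class ScaleSpec:
    """Hyper-parameters of one pyramid scale.

    Defaults follow the reference recipe: MERIT threshold ``f = 6``,
    reliability percentile seed ``q = 10`` %, l1 smoothing ``e = 1e-6``,
    CG tolerance 0.1 and outer (normalised residual step) tolerance 0.1.
    """

    r_mm: float
    lam: float = 10**2.7
    use_edge_prior: bool = False
    merit_f: float = 6.0
    q_percent: float = 10.0
    epsilon: float = 1e-6
    cg_tol: float = 0.1
    outer_tol: float = 0.1
    max_outer: int = 10
    max_cg: int = 100
    edge_fraction: float = 0.30

    def __post_init__(self) -> None:
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if not (0.0 <= self.q_percent <= 100.0):
            raise ValueError("q_percent must lie in [0, 100]")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


@dataclass
class SolveResult:
    """Output of :func:`solve_scale`."""

    chi: np.ndarray  #: per-scale susceptibility increment, ppm, zero mean
    weights_final: np.ndarray
    cost_history: List[Tuple[float, float]]  #: (fidelity, regulariser) per outer iter
    converged: bool
    n_outer: int


class SolverDivergence(RuntimeError):
    """Raised when the objective turns non-finite."""


# ---------------------------------------------------------------------------
# Gradient / divergence pair
# ---------------------------------------------------------------------------

def grad_forward(x: np.ndarray, voxel_size_mm: Sequence[float]) -> np.ndarray:
    """Forward finite differences per axis; zero at the far edge.

    Returns an array of shape (3, *x.shape).
    """
    out = np.zeros((3,) + x.shape)
    for ax, h in enumerate(voxel_size_mm):
        d = np.diff(x, axis=ax) / h
        sl = [slice(None)] * x.ndim
        sl[ax] = slice(0, x.shape[ax] - 1)
        out[ax][tuple(sl)] = d
    return out


def grad_adjoint(g: np.ndarray, voxel_size_mm: Sequence[float]) -> np.ndarray:
    """Exact adjoint of :func:`grad_forward` (a negative divergence).

    Per axis: ``(G^T y)[i] = (y[i-1] - y[i]) / h`` with ``y[-1] = 0``,
    except the last voxel which receives ``y[n-2] / h`` (the final
    gradient row is identically zero, so ``y[n-1]`` never contributes).
    """
    out = np.zeros(g.shape[1:])
    for ax, h in enumerate(voxel_size_mm):
        y = g[ax]
        n = y.shape[ax]

        def _sl(s: slice) -> tuple:
            full = [slice(None)] * y.ndim
            full[ax] = s
            return tuple(full)

        acc = np.zeros_like(y)
        acc[_sl(slice(1, None))] = y[_sl(slice(0, n - 1))]
        acc[_sl(slice(0, n - 1))] -= y[_sl(slice(0, n - 1))]
        out += acc / h
    return out


# ---------------------------------------------------------------------------
# Masks and reweighting
# ---------------------------------------------------------------------------

def edge_mask(
    magnitude: np.ndarray,
    roi: np.ndarray,
    mask_fraction: float = 0.30,
    voxel_size_mm: Sequence[float] = (1.0, 1.0, 1.0),
) -> np.ndarray:
    """Binary morphological masks: 0 at the strongest magnitude gradients.

    Per finite-difference direction, ROI voxels whose absolute gradient
    exceeds the (1 - fraction) quantile within the ROI are flagged 0
    (regulariser disabled there); all other voxels, including those
    outside the ROI, are 1.  A constant magnitude has no edges and yields
    an all-ones mask.
    """
    roi = as_roi(roi)
    g = grad_forward(np.asarray(magnitude, dtype=np.float64), voxel_size_mm)
    mask = np.ones_like(g)
    for ax in range(3):
        mags = np.abs(g[ax])
        thresh = np.quantile(mags[roi], 1.0 - mask_fraction)
        mask[ax][roi & (mags > thresh)] = 0.0
    return mask


def reliability_mask(
    second_diff: np.ndarray,
    roi: np.ndarray,
    scale_index: int,
    q_percent: float = 10.0,
    radii_mm: Sequence[float] = (2.0, 4.0, 8.0, 16.0),
) -> np.ndarray:
    """Scale-specific phase-reliability mask Q_l.

    The first scale is fully trusted (all ones).  For ``l >= 2`` the ROI
    voxels whose second-difference value strictly exceeds the
    ``100 - q * r_l / r_2`` percentile (computed within the ROI) are
    zeroed; the excluded fraction thus grows with the SMV radius
    (10/20/40 % for the default schedule).
    """
    if scale_index < 1:
        raise ValueError("scale_index is 1-based")
    radii = list(radii_mm)
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly ascending")
    roi = as_roi(roi)
    mask = np.ones(second_diff.shape)
    if scale_index == 1:
        return mask
    if len(radii) < 2:
        raise ValueError("reliability masking for l >= 2 needs at least two radii")
    percent = q_percent * radii[scale_index - 1] / radii[1]
    if percent > 100.0:
        raise ValueError(f"effective masking percentile {percent} % exceeds 100 %")
    thresh = np.percentile(second_diff[roi], 100.0 - percent)
    mask[roi & (second_diff > thresh)] = 0.0
    return mask


def merit_reweight(
    base_weight: np.ndarray, residual: np.ndarray, f: float = 6.0
) -> np.ndarray:
    """Model-error reduction through iterative tuning (MERIT).

    Voxels whose normalised consistency residual exceeds ``f`` have their
    weight divided by the squared residual; all others keep the pristine
    base weight.  Always applied to the unmodified base weight, so the
    down-weighting never compounds across iterations.
    """
    w = np.array(base_weight, dtype=np.float64, copy=True)
    bad = residual > f
    w[bad] = base_weight[bad] / residual[bad] ** 2
    return w


def normalised_residual(
    weight: np.ndarray,
    qmask: np.ndarray,
    model_phase: np.ndarray,
    data_phase: np.ndarray,
    roi: np.ndarray,
) -> np.ndarray:
    """|Q W (e^{i model} - e^{i data})| scaled to unit mean over the ROI."""
    r = np.abs(qmask * weight * (np.exp(1j * model_phase) - np.exp(1j * data_phase)))
    mean = r[roi].mean()
    if mean <= 0:
        return np.zeros_like(r)
    return r / mean


# ---------------------------------------------------------------------------
# The quasi-Newton / CG solver
# ---------------------------------------------------------------------------

def solve_scale(
    phi_hp: np.ndarray,
    weights: np.ndarray,
    qmask: np.ndarray,
    emask: Optional[np.ndarray],
    kernels: KernelSet,
    spec: ScaleSpec,
    scale_index: int,
    roi: Optional[np.ndarray] = None,
) -> SolveResult:
    """Minimise the scale-l objective for the high-pass filtered phase.

    ``phi_hp`` must already be high-pass SMV-filtered for this scale and
    expressed in normalised phase units; ``emask`` is the (3, nx, ny, nz)
    edge-mask stack or ``None`` to disable the morphological prior.  The
    returned susceptibility increment is in ppm with zero volume mean
    (unreferenced convention).
    """
    grid = kernels.grid
    vox = grid.voxel_size_mm
    phi_hp = np.asarray(phi_hp, dtype=np.float64)
    roi = as_roi(roi if roi is not None else np.ones(grid.shape, bool), grid)
    if emask is None:
        emask = np.ones((3,) + tuple(grid.shape))
    a0 = np.asarray(weights, dtype=np.float64)  # pristine base weight
    W = a0.copy()
    lam = float(spec.lam)
    e_iphi = np.exp(1j * phi_hp)

    # The solution variable is susceptibility expressed in normalised phase
    # (radian) units, y = chi_to_phase * chi, matching the solver family the
    # reference lambda values were calibrated for; chi in ppm is recovered
    # on return.  The forward map on y is then the dimensionless kernel.
    def A(v: np.ndarray) -> np.ndarray:
        return forward_field(v, kernels, highpass_scale=scale_index)

    def At(v: np.ndarray) -> np.ndarray:
        return forward_adjoint(v, kernels, highpass_scale=scale_index)

    x = np.zeros(grid.shape)
    Ax = np.zeros(grid.shape)
    cost_history: List[Tuple[float, float]] = []
    best: Tuple[float, np.ndarray] | None = None
    converged = False
    n_outer = 0

    for it in range(spec.max_outer):
        n_outer = it + 1
        if it > 0:
            rhat = normalised_residual(W, qmask, Ax, phi_hp, roi)
            W = merit_reweight(a0, rhat, spec.merit_f)
        qw2 = (qmask * W) ** 2

        gx = emask * grad_forward(x, vox)
        vr = 1.0 / np.sqrt(np.sum(gx * gx, axis=0) + spec.epsilon)
        P = emask * vr[None]  # per-direction IRLS weight (emask binary)

        def H(dx: np.ndarray) -> np.ndarray:
            reg = grad_adjoint(P * emask * grad_forward(dx, vox), vox)
            fid = 2.0 * lam * At(qw2 * A(dx))
            return reg + fid

        rhs = 2.0 * lam * At(qw2 * np.sin(phi_hp - Ax)) - grad_adjoint(P * gx, vox)

        dx = _conjugate_gradient(H, rhs, tol=spec.cg_tol, max_iter=spec.max_cg)
        x = x + dx
        Ax = A(x)

        resid = (qmask * W) * (np.exp(1j * Ax) - e_iphi)
        fidelity = lam * float(np.sum(np.abs(resid) ** 2))
        reg_cost = float(np.sum(np.abs(emask * grad_forward(x, vox))))
        if not np.isfinite(fidelity) or not np.isfinite(reg_cost):
            raise SolverDivergence(
                f"non-finite cost at scale {scale_index}, outer iteration {n_outer}"
            )
        cost_history.append((fidelity, reg_cost))
        total = fidelity + reg_cost
        if best is None or total < best[0]:
            best = (total, x.copy())

        update = float(np.linalg.norm(dx)) / max(float(np.linalg.norm(x)), 1e-30)
        if update < spec.outer_tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"scale {scale_index}: no convergence within {spec.max_outer} outer "
            "iterations; returning best iterate",
            stacklevel=2,
        )
        x = best[1] if best is not None else x
    x = x - x.mean()  # unreferenced: zero DC over the full volume
    return SolveResult(
        chi=x / kernels.chi_to_phase,
        weights_final=W,
        cost_history=cost_history,
        converged=converged,
        n_outer=n_outer,
    )


def _conjugate_gradient(H, b: np.ndarray, tol: float, max_iter: int) -> np.ndarray:
    """Plain CG on the SPD normal equations, relative-residual stopping."""
    x = np.zeros_like(b)
    r = b.copy()
    p = r.copy()
    rs = float(np.vdot(r, r).real)
    b_norm = np.sqrt(rs)
    if b_norm == 0:
        return x
    for _ in range(max_iter):
        Hp = H(p)
        denom = float(np.vdot(p, Hp).real)
        if denom <= 0:
            break
        alpha = rs / denom
        x += alpha * p
        r -= alpha * Hp
        rs_new = float(np.vdot(r, r).real)
        if np.sqrt(rs_new) <= tol * b_norm:
            break
        p = r + (rs_new / rs) * p
        rs = rs_new
    return x
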