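"""Reconstruction-quality metrics and L-curve model selection.

RMSE, HFEN and 1-SSIM quantify dissimilarity to a reference map; the ROI
error summarises regional mean offsets.  Note the structural
dissimilarity index is known to reward over-regularised, texture-free
maps and should be interpreted with caution.

The L-curve plots log data-fidelity against log regulariser cost over a
lambda sweep; the maximum-curvature "corner" balances the two and serves
as the regularisation-parameter estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import UnivariateSpline
from scipy.ndimage import gaussian_laplace
from skimage.metrics import structural_similarity

from .core import as_roi

#: HFEN Laplacian-of-Gaussian parameters: sigma 1.5 voxels, 15^3 taps.
HFEN_SIGMA = 1.5
HFEN_TRUNCATE = 7.0 / HFEN_SIGMA

#: SSIM window and stabilisation constants.
SSIM_SIGMA = 1.5
SSIM_K1 = 0.01
SSIM_K2 = 0.03


def rmse_percent(x: np.ndarray, ref: np.ndarray, roi: np.ndarray) -> float:
    """100 * ||x - ref|| / ||ref|| over the ROI."""
    roi = as_roi(roi)
    dx = np.asarray(x, dtype=np.float64)[roi] - np.asarray(ref, dtype=np.float64)[roi]
    denom = np.linalg.norm(np.asarray(ref, dtype=np.float64)[roi])
    if denom == 0:
        raise ValueError("reference is identically zero over the ROI")
    return float(100.0 * np.linalg.norm(dx) / denom)


def log_kernel() -> np.ndarray:
    """The 15^3 Laplacian-of-Gaussian kernel (sigma 1.5), re-centred to
    zero tap sum so constants are annihilated exactly."""
    imp = np.zeros((15, 15, 15))
    imp[7, 7, 7] = 1.0
    kern = gaussian_laplace(imp, HFEN_SIGMA, truncate=HFEN_TRUNCATE, mode="constant")
    kern -= kern.sum() / kern.size
    return kern


def _log_filter(x: np.ndarray) -> np.ndarray:
    # edge replication keeps constants exactly annihilated at the boundary
    from scipy.ndimage import convolve

    return convolve(x, log_kernel(), mode="nearest")


def hfen_percent(x: np.ndarray, ref: np.ndarray, roi: np.ndarray) -> float:
    """RMSE% after Laplacian-of-Gaussian filtering of both volumes.

    The LoG annihilates the DC component, so the metric only sees
    high-spatial-frequency disagreement.
    """
    fx = _log_filter(np.asarray(x, dtype=np.float64))
    fr = _log_filter(np.asarray(ref, dtype=np.float64))
    return rmse_percent(fx, fr, roi)


def one_minus_ssim(x: np.ndarray, ref: np.ndarray, roi: np.ndarray) -> float:
    """Structural dissimilarity: 1 - mean SSIM over the ROI.

    Gaussian window (sigma 1.5), K1 = 0.01, K2 = 0.03, dynamic range
    taken as the reference's range over the ROI.
    """
    roi = as_roi(roi)
    x = np.asarray(x, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    drange = float(ref[roi].max() - ref[roi].min())
    if drange == 0:
        return 0.0 if np.allclose(x[roi], ref[roi]) else 2.0
    _, ssim_map = structural_similarity(
        ref,
        x,
        gaussian_weights=True,
        sigma=SSIM_SIGMA,
        use_sample_covariance=False,
        K1=SSIM_K1,
        K2=SSIM_K2,
        data_range=drange,
        full=True,
    )
    return float(1.0 - ssim_map[roi].mean())


def roi_error(x: np.ndarray, ref: np.ndarray, labels: np.ndarray) -> float:
    """Mean absolute difference of per-label means (labels > 0)."""
    labels = np.asarray(labels)
    ids = np.unique(labels[labels > 0])
    if ids.size == 0:
        raise ValueError("label volume contains no positive labels")
    x = np.asarray(x, dtype=np.float64)
    ref = np.asarray(ref, dtype=np.float64)
    errs = [
        abs(float(x[labels == i].mean()) - float(ref[labels == i].mean())) for i in ids
    ]
    return float(np.mean(errs))


@dataclass
class LCurve:
    """L-curve sweep with per-point curvature and the selected corner."""

    lambdas: np.ndarray
    log_fidelity: np.ndarray
    log_regulariser: np.ndarray
    curvature: np.ndarray
    optimal_lambda: float
    no_corner: bool = False


def lcurve_select(
    lambdas: Sequence[float],
    fidelity_costs: Sequence[float],
    reg_costs: Sequence[float],
    smoothing: float = 1e-4,
) -> LCurve:
    """Select lambda at the point of maximum L-curve curvature.

    The (log fidelity, log regulariser) curve, parameterised by
    log10(lambda), is fit with lightly smoothing cubic splines and its
    signed curvature evaluated at the sweep points; the optimum is the
    grid member maximising curvature.  A collinear sweep (zero curvature
    everywhere) sets the ``no_corner`` flag and returns the middle
    lambda.  The selection is invariant to rescaling either cost axis by
    a positive constant (which only shifts the log curves).
    """
    lam = np.asarray(lambdas, dtype=np.float64)
    fid = np.asarray(fidelity_costs, dtype=np.float64)
    reg = np.asarray(reg_costs, dtype=np.float64)
    if lam.size < 5:
        raise ValueError("L-curve analysis needs at least 5 lambda points")
    if np.any(np.diff(lam) <= 0):
        raise ValueError("lambdas must be strictly increasing")
    if np.any(fid <= 0) or np.any(reg <= 0):
        raise ValueError("costs must be positive to take logarithms")
    t = np.log10(lam)
    x = np.log(fid)
    y = np.log(reg)
    span = max(np.ptp(x), np.ptp(y), 1e-12)
    s = smoothing * lam.size * span**2
    sx = UnivariateSpline(t, x, k=3, s=s)
    sy = UnivariateSpline(t, y, k=3, s=s)
    x1, x2 = sx.derivative(1)(t), sx.derivative(2)(t)
    y1, y2 = sy.derivative(1)(t), sy.derivative(2)(t)
    speed2 = x1 * x1 + y1 * y1
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (x1 * y2 - y1 * x2) / np.power(speed2, 1.5)
    kappa[~np.isfinite(kappa)] = 0.0
    # Curvature scale-free test for collinearity: compare against the
    # curve's overall bending (chord deviation) rather than raw kappa.
    no_corner = bool(np.max(np.abs(kappa)) < 1e-8)
    idx = int(lam.size // 2) if no_corner else int(np.argmax(kappa))
    return LCurve(
        lambdas=lam,
        log_fidelity=x,
        log_regulariser=y,
        curvature=kappa,
        optimal_lambda=float(lam[idx]),
        no_corner=no_corner,
    )
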