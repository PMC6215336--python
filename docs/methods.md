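# Methods

## The model

Gradient-echo phase measures the magnetic field perturbation induced by
tissue susceptibility.  In the frequency domain the field is the
susceptibility distribution multiplied by the unit dipole response

    D(k) = 1/3 - (k . b0)^2 / |k|^2 ,      D(0) = 0 ,

which vanishes on a double cone at the magic angle, making the inverse
problem (field → susceptibility, "dipole inversion") ill-posed.  The
package implements a multi-scale dipole inversion: a Laplacian-pyramid
decomposition of the field by spherical-mean-value (SMV) filtering with
increasing kernel radius, each level inverted separately and the
susceptibility increments summed.

For scale `l` with SMV kernel `S_l` (a rasterised sphere of radius `r_l`
normalised to unit sum, high-pass complement `S~_l = 1 - F(S_l)`):

1. residual field: `phi_l = phi - F^H D F X_{l-1}` (with `X_0 = 0`);
2. preconditioning: `phi'_l = phi_l - S_l * phi_l` (spherical means are
   computed with in-ROI renormalised kernel mass, so the mask is never
   eroded between scales);
3. constrained inversion:

       X'_l = argmin_X  lambda ||Q_l W_l (e^{i A_l X} - e^{i phi'_l})||_2^2
                        + ||M_grad grad X||_1

   with `A_l = F^H S~_l D F`, solved by a quasi-Newton fixed-point
   iteration (first-order linearisation of the complex exponential,
   iteratively reweighted l1 with smoothing `e`, conjugate-gradient
   inner solves);
4. accumulation: `X_l = X_{l-1} + X'_l`.

Because each level only fits the part of the field that survives its own
high-pass filter, smooth background fields (harmonic inside the ROI)
cannot contaminate the short-radius levels: truncating the pyramid after
the first level(s) yields a high-pass susceptibility map (HPSM) that is
insensitive to background sources by construction.

### Error control

* **Noise weights.**  `W_l` is initialised from the signal magnitude:
  `A'_l = [A^-2 + A_l^-2]^(-1/2)` with `A` the magnitude and
  `A_l = S_l * A`, each normalised to unit mean over the ROI.  Phase
  noise scales inversely with magnitude, and the high-pass filtered
  phase combines the raw phase with its spherical mean, hence the
  composite form.
* **MERIT.**  At each outer iteration, voxels whose normalised
  consistency residual exceeds `f = 6` have their weight divided by the
  squared residual.  The residual is `|Q W (e^{iAX} - e^{i phi'})|`
  normalised to unit mean over the ROI; the reweighting always starts
  from the pristine base weight (no compounding) and is applied from the
  second outer iteration onward — the residual at the zero
  initialisation reflects the data, not model error.
* **Reliability masks.**  For scales `l >= 2`, the voxels in the top
  `q * r_l / r_2` percentile of the measured-phase second differences
  (root-sum-of-squares over the 13 unique directions of the 3x3x3
  neighbourhood) are excluded from the data term.  With `q = 10` % and
  radii 2/4/8/16 mm the exclusions are 10/20/40 % at scales 2-4: the
  coarser the scale, the lower the tolerance for unreliable phase,
  because inconsistencies propagate further through large kernels.
* **Morphological prior.**  The top 30 % magnitude-gradient locations
  (per finite-difference direction, within the ROI) are exempted from
  the gradient-sparsity penalty — but only at the first scale, where
  vascular features coincide with rapid magnitude variation.

### Solver conventions

The solution variable is susceptibility expressed in normalised phase
units (`chi * 2 pi gamma_bar B0 TE`, with TE*B0 at the 60 ms*T
reference), the convention of the solver family for which the reference
regularisation parameters were calibrated; ppm values are recovered on
return.  This matters: the quoted lambda range (10^1.6 highly
regularised, 10^2.7 reference, 10^3.3 high fidelity) presumes the l1
penalty acts on the radian-unit solution, and the l1 smoothing parameter
`e = 1e-6` is likewise a radian-unit constant.  Defaults: CG relative
tolerance 0.1, outer relative-update tolerance 0.1, at most 10 outer
iterations (the cited solver family's typical cap; only tolerances are
prescribed), initialisation `X = 0` at every scale (the telescoping
re-initialisation makes warm starts unnecessary and keeps scales
independent).  Solutions are unreferenced: the volume mean is removed
(`D(0) = 0` leaves the DC mode unconstrained anyway).  The gradient
operator is forward finite differences with a zero row at the far edge;
its exact adjoint (negative divergence) is used throughout, and the l1
reweighting `1/sqrt(|grad X|^2 + e)` is refreshed every outer iteration.

## Pre-processing

* **Laplacian unwrapping.**  The discrete Laplacian of the true phase is
  estimated from sin/cos of the wrapped phase and inverted with a
  Neumann (DCT-II) Poisson solve.  A periodic (FFT) solve was rejected:
  a wrapped linear ramp — the canonical unwrapping test case — lies in
  the null space of the periodic Laplacian and cannot be recovered under
  periodic boundaries.  By default the spectral estimate is then used
  only to select each voxel's integer 2*pi cycle
  (`snap_to_cycles=True`), because the Poisson solution itself lacks the
  harmonic component of the field (set by unknown boundary fluxes) and
  smoothly distorts the output; snapping discards that error entirely
  wherever it is below pi.  The global offset is fixed to zero mean.
* **vSMV background removal.**  Variable-kernel SMV filtering: each ROI
  voxel has the spherical mean of the largest kernel (from r0 = 40 mm
  down to 1 voxel, in 1-voxel steps) that fits inside the ROI
  subtracted.  Only the outermost 1-voxel shell of the ROI is lost.  No
  inverse (deconvolution) filtering is applied — the pyramid's own
  `S~_l`-preconditioned inversion is the deconvolution step.
* **Normalisation.**  Fields are scaled by `60 / (TE[ms] * B0[T])`
  before inversion so one lambda range transfers across acquisitions;
  the operation is unit-tracked and refuses to run twice.

## Model selection

The L-curve plots log data-fidelity against log regulariser cost over a
log-spaced lambda sweep (default 10^1.0 to 10^3.4 in 10^0.2 steps).
Both axes are fit with lightly smoothing cubic splines parameterised by
log10(lambda) and the corner is the sweep point of maximum curvature;
collinear sweeps raise a no-corner flag.  The selection is invariant to
rescaling either cost axis.  Performance metrics: RMSE as a percentage
of the reference norm; HFEN (RMSE after filtering both volumes with a
15^3-tap, sigma 1.5 Laplacian-of-Gaussian kernel re-centred to zero tap
sum, edge-replicated boundaries); 1-SSIM (Gaussian window sigma 1.5,
K1 = 0.01, K2 = 0.03, dynamic range from the reference over the ROI) —
known to reward over-regularised, texture-free maps, interpret with
caution; and the ROI error (mean absolute difference of per-label
means).

## The synthetic phantom

The standard scene is a 64^3 volume at 1 mm isotropic with a spherical
ROI of radius 28 mm: three "nuclei" spheres at 0.05/0.10/0.20 ppm
(deep-grey-matter-like iron levels), two 1.5-mm-radius cylinders at
0.45 ppm (venous blood at typical oxygenation), a diamagnetic slab at
-0.05 ppm (myelinated white matter), and two external point-dipole
sources (moment 300 ppm*mm^3) outside the ROI standing in for air/tissue
interface fields.  TE*B0 = 60 ms*T so normalisation is unity, and
SNR 50 complex Gaussian noise (per-component sigma = mean ROI magnitude
/ SNR) is typical of a 3 T gradient-echo acquisition.  All objects keep
a 16 mm (= largest SMV radius) margin to the volume edges because all
convolutions are circular.  The tissue magnitude carries a seeded
band-limited ~10 % bias field.

What the phantom does *not* emulate: realistic brain morphology,
flow/motion effects, multi-echo signal evolution (R2* decay), coil
sensitivities, or dipole-incompatible fields beyond additive noise.
Passing tests therefore demonstrate the correctness and the designed
robustness properties of the algorithm, not in vivo performance.

### Geometry caveat for background filtering

On this compact geometry (28 mm ROI) the vSMV filter is more destructive
than in vivo: interior kernels are capped at ~28 mm rather than 40 mm,
so much of the long-range field of interior sources is subtracted along
with the background, which biases the ROI-mean susceptibility of
off-centre objects low (about -18 % for the weakest sphere even with
noiseless data).  The reference recovery tests therefore invert the
unwrapped field directly — the pyramid's own SMV preconditioning
suppresses the external sources — while vSMV is exercised by its own
suppression tests and by a regression test confirming it still lowers
whole-ROI reconstruction error in the presence of external sources.

## Problem sizes

Tests run the full pipeline once on the 64^3 standard phantom
(four scales), single-scale 64^3 runs for the venography and
background-robustness checks, and a lambda sweep on a reduced 32^3
phantom for the L-curve shape property; the dense linear-algebra oracle
for the solver uses a 16^3 grid where the normal equations fit in
memory.  These sizes were chosen to keep the whole suite in the
few-minute range while leaving every operator on a grid large enough for
its asymptotics (kernel radii well below the field of view) to hold.

## Known limitations

* Oblique acquisitions are supported only through `b0_dir`; no
  resampling of angulated fields of view.
* Single-echo ingestion only; multi-echo combination is upstream scope.
* The phase-reliability percentile is computed on the post-erosion ROI
  when vSMV is applied first.
* Laplacian unwrapping cannot resolve per-voxel phase steps above pi
  (e.g. vessels at very long echo times); such voxels alias before the
  algorithm sees them.
* RF-bias correction of the magnitude for SWI weighting is accepted as
  pre-corrected input; only mean normalisation is applied internally.
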