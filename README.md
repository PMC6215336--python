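# msdi — multi-scale dipole inversion for quantitative susceptibility mapping

Quantitative susceptibility mapping (QSM) recovers tissue magnetic
susceptibility (in ppm) from the phase of gradient-echo MRI — the main
non-invasive window on brain iron, myelin and venous oxygenation.  The
field-to-source inversion is ill-posed (the dipole kernel
`D(k) = 1/3 - k_z^2/|k|^2` vanishes on the magic-angle cone) and
notoriously sensitive to background fields and phase errors, which
propagate as streaking and shadowing artefacts.

This package implements a multi-scale dipole inversion: the local field
is decomposed into a Laplacian pyramid by spherical-mean-value (SMV)
filtering with power-of-two kernel radii (2, 4, 8, 16 mm), and each
level `l` solves the nonlinear, morphology-constrained sub-problem

    X'_l = argmin_X  lambda ||Q_l W_l (e^{i F^H S~_l D F X} - e^{i phi'_l})||_2^2
                     + ||M_grad grad X||_1

with the susceptibility map the sum of the per-scale increments
`X_L = sum_l X'_l`.  `W_l` are magnitude-derived noise weights with
iterative residual down-weighting (MERIT, `f = 6`), `Q_l` are
scale-specific phase-reliability masks that exclude the top
`q r_l / r_2` percentile of phase second differences (10/20/40 % at
scales 2–4 for `q = 10`), and the morphological prior `M_grad` exempts
the top-30 % magnitude gradients from the sparsity penalty on the first
scale only.  Because each scale only sees high-pass-filtered fields,
short-radius solutions are structurally protected from background
contamination; truncating the pyramid gives high-pass susceptibility
maps (HPSM), from which the package also derives vessel masks
(VenoMSDI), macro-vessel-suppressed maps (MVSSM), susceptibility-weighted
magnitude contrast (HPSM-SWI) and mIP/MIP projections.  Evaluation
utilities provide RMSE/HFEN/1-SSIM/ROI-error metrics and L-curve
(maximum-curvature) regularisation-parameter selection.

Inputs are NIfTI volumes (wrapped phase in radians, magnitude, binary
ROI) or fully synthetic numerical phantoms produced by the built-in
generator; no external data are required.

## Worked example

```python
import numpy as np
from msdi import (standard_phantom_spec, make_phantom, simulate_acquisition,
                  laplacian_unwrap, normalize_field, MSDIConfig, run_msdi,
                  rmse_percent)
from msdi.preprocess import second_difference_map

spec = standard_phantom_spec(seed=1234, snr=50.0)   # 64^3, TE*B0 = 60 ms*T
ph = make_phantom(spec)
sim = simulate_acquisition(ph.chi, ph.magnitude, ph.roi, spec)

phi = normalize_field(laplacian_unwrap(sim["wrapped_phase"]))
cfg = MSDIConfig.default(spec.grid.voxel_size_mm)   # lambda = 10^2.7, 4 scales
results = run_msdi(phi, sim["noisy_magnitude"], ph.roi, cfg,
                   second_diff=second_difference_map(sim["wrapped_phase"]))

chi = results[-1].chi_cum
for label, true in [(1, 0.05), (2, 0.10), (3, 0.20)]:
    est = chi[ph.labels == label].mean()
    print(f"sphere {label}: {est:.4f} ppm (truth {true})")
print(f"RMSE = {rmse_percent(chi, ph.chi, ph.roi):.0f}%")
```

prints

```
sphere 1: 0.0435 ppm (truth 0.05)
sphere 2: 0.0988 ppm (truth 0.1)
sphere 3: 0.1981 ppm (truth 0.2)
RMSE = 23%
```

i.e. the four-scale inversion recovers the ROI-mean susceptibility of
the three test spheres to within 13 %, 2 % and 1 % of truth at SNR 50,
with a whole-ROI RMSE comparable to the values typical of
single-orientation QSM (where even top-ranked reconstructions sit well
above 60 % against in vivo ground truths — the metric is dominated by
voxel-scale noise, while regional means are far more accurate).

The same pipeline is available from the shell:

```sh
msdi phantom --seed 1234 --out ph/
msdi preprocess --phase ph/phase.nii.gz --mask ph/roi.nii.gz \
    --te-ms 20 --b0-t 3 --out pre/
msdi run --phase pre/field_normalised.nii.gz --mag ph/magnitude_noisy.nii.gz \
    --mask pre/roi_filtered.nii.gz --out inv/
msdi evaluate --x inv/chi_cum_4.nii.gz --ref ph/chi_truth.nii.gz \
    --roi pre/roi_filtered.nii.gz --out metrics.csv
```

plus `msdi contrast veno|mvssm|swi|project`, `msdi lcurve`, and
`msdi pipeline` for a configured end-to-end run with a checksummed
reproducibility manifest.

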