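# Standard phantom: 64^3 at 1 mm isotropic, spherical ROI r = 28 mm.
# Three nuclei-like spheres, two venous-blood-like cylinders, one
# diamagnetic slab, two external dipole sources. TE*B0 = 60 ms*T.
grid:
  shape: [64, 64, 64]
  voxel_size_mm: [1.0, 1.0, 1.0]
  b0_dir: [0.0, 0.0, 1.0]
roi_radius_mm: 28.0
snr: 50.0
te_ms: 20.0
b0_T: 3.0
seed: 1234
edge_margin_mm: 16.0
objects:
  - {shape: sphere, centre_mm: [-10.0, -8.0, 0.0], size_mm: [6.0], chi_ppm: 0.05, magnitude: 0.95}
  - {shape: sphere, centre_mm: [10.0, -5.0, 4.0], size_mm: [5.0], chi_ppm: 0.10, magnitude: 0.90}
  - {shape: sphere, centre_mm: [0.0, 10.0, -6.0], size_mm: [5.0], chi_ppm: 0.20, magnitude: 0.85}
  - {shape: cylinder, centre_mm: [-6.0, 8.0, 0.0], size_mm: [1.5, 16.0], chi_ppm: 0.45, magnitude: 0.60, axis: 2}
  - {shape: cylinder, centre_mm: [0.0, -14.0, 8.0], size_mm: [1.5, 14.0], chi_ppm: 0.45, magnitude: 0.60, axis: 0}
  - {shape: ellipsoid, centre_mm: [0.0, 0.0, 12.0], size_mm: [12.0, 9.0, 3.0], chi_ppm: -0.05, magnitude: 1.0}
background_sources:
  - {position_mm: [24.0, 24.0, 0.0], moment: 300.0}
  - {position_mm: [-26.0, 0.0, 18.0], moment: 300.0}
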