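# ocubeam

A desk-scale proton pencil-beam dose pipeline for adapting a general-purpose,
actively scanned proton beamline (the CNAO synchrotron line) to ocular
(uveal-melanoma) treatments. It re-creates, with closed-form physics instead
of full Monte Carlo particle transport, the complete simulation chain of such
a commissioning study:

- **Range–energy law** `R = α·E^p` fitted in log–log space to measured ranges
  in water, with leave-one-out cross-validation.
- **Analytical Bragg curves** (Bortfeld model: power-law range, Gaussian range
  straggling `σ ≈ 0.012·R^0.935` cm accumulated over the *total*
  water-equivalent path, linear fluence reduction), including degraded beams
  behind a PMMA range shifter.
- **Fermi–Eyges moment transport** of the transverse beam through the line:
  vacuum exit window, the two monitor-chamber foil stacks, distributed air
  scattering, and the (sub-divided) range shifter, each adding Highland
  scattering kicks. The source divergence is calibrated per energy from two
  measured planes, so intermediate planes are genuine predictions.
- **SOBP planning**: energy layers at 2 mm pull-back steps; plateau-filling
  weights solved distal-to-proximal (iterated to self-consistency) so the
  summed dose equals the plateau height at every Bragg-peak bin.
- **Scanned-field delivery** with a 3 mm spot lattice, an elliptical brass
  collimator modelled as a masked-and-blurred aperture, and an analytic or
  seeded Monte Carlo fluence-sampling dose engine (identical marginals).
- **Anatomical eye phantom** parameterized by the outer sclera radius, with a
  posterior spherical-cap tumor, gaze rotation, voxelization to a labelled
  density/WER grid, and per-structure cumulative DVHs.
- **Synthetic DICOM CT** head series (10 slices, 512×512 at 0.97×0.97 mm²,
  2 mm thickness) with an 86×86 eye crop and an HU→density/WER ramp, so the
  image-based pathway runs without any patient data.

## Worked example

```python
import ocubeam
from ocubeam import studies

# 1. Cross-validated range prediction (fit three measured energies,
#    predict the fourth)
print(round(studies.loo_range_prediction(100.51), 2))   # 73.58 (measured: 74.00 mm)

# 2. Residual range behind the 43 mm PMMA shifter at 99.03 MeV
print(round(studies.residual_range_prediction(99.03), 2))  # 33.52 (measured: 33.50 mm)

# 3. The ten-layer spread-out Bragg peak in water
m = studies.sobp_water_box_study()
print(round(m.width, 2), round(m.distal_falloff_80_20, 2),
      round(m.entrance_plateau_ratio, 1))               # 19.07 1.04 72.0

# 4. Transverse FWHM predicted at the post-monitor plane for 81.56 MeV
print(round(studies.fwhm_prediction(81.56, -654.6), 2))  # 7.8 (measured: 8.35 ± 0.84 mm)

# 5. Scanned 40x40 mm field at the moved isocenter: Y penumbra
print(round(studies.field_penumbra(collimator=False), 2))  # 6.9  (measured: 7.25 mm)
print(round(studies.field_penumbra(collimator=True), 2))   # 2.67 (measured: 4.00 mm)
```

The numbers in comments are what the calls print here, next to the published
measurements they emulate. The SOBP width comes out ~1 mm wider than the
published 18.10 mm — the proximal shoulder of the analytical Bragg curves
sits slightly higher than the Monte Carlo curves behind the published table;
see `docs/methods.md` for the analysis.

A command-line layer wraps the same functions:

```
ocubeam validate-range                 # measured vs fitted vs leave-one-out ranges
ocubeam fwhm-scan --energy 81.56      # FWHM at the five measured planes
ocubeam rs-study                       # FWHM vs shifter thickness, both isocenters
ocubeam sobp --out run/sobp            # SOBP in the 25 mm water box
ocubeam irradiate-water --out run/tl   # scanned field on the thin-layer scorer
ocubeam irradiate-eye --seed 7 --events 500000 --mode mc --out run/eye
ocubeam make-ct --seed 1 --out ct      # synthetic DICOM head series
ocubeam irradiate-dicom --seed 1 --events 100000 --mode mc --out run/dicom
ocubeam dvh run/eye                    # recompute DVHs from an exported run
```

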