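# Methods

This note documents the physics models, the calibration choices, the
numerical conventions, and the known limitations of the pipeline. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`.

## Range–energy model and Bragg curves

Proton range in water is modelled as `R = α·E^p`, fitted by least squares in
log–log space to the measured (energy, range) calibration pairs of the CNAO
line (81.56–148.8 MeV). The fit reproduces each calibration point within
0.5% and predicts a held-out energy within 0.6% (leave-one-out). "Range"
throughout means the depth of the distal 80% dose point, the common clinical
convention; the source measurements do not state their convention, and the
~0.35 mm spread between their measured and simulated columns is compatible
with either.

Depth dose uses the Bortfeld analytical Bragg model: the unstraggled
power-law curve with linear fluence reduction (β = 0.012 cm⁻¹, γ = 0.6),
convolved with Gaussian range straggling. Near the peak the curve is
evaluated with parabolic-cylinder functions; more than 8σ upstream the
asymptotic closed form is used (the two agree to machine precision at the
switch). The tail-fluence fraction ε is set to 0.2, Bortfeld's upper
recommended value, appropriate for the sub-100 MeV degraded beams modelled
here; it mainly controls the entrance-to-plateau dose ratio.

Straggling combines in quadrature: σ_mono = 0.012·R^0.935 (cm) evaluated at
the **total** water-equivalent range of the undegraded beam (degrader WET
plus residual range — straggling accumulates over the whole path), the range
spread `p·R·σE/E` from the synchrotron's 0.05% energy spread, and any
explicit extra term. A degraded beam's curve is the deep portion of the
undegraded curve shifted upstream by the degrader WET, with the shift
calibrated so the distal 80% depth equals the residual range from the range
law. This reproduces both the elevated entrance dose and the distal falloff
of shifter-degraded beams.

## Water equivalence

Beamline and tissue materials carry a water-equivalent ratio (WER). For
tissues it is approximated by `ρ·(Z/A)/(Z/A)_water` (the mean-excitation
correction is ignored; for near-water media the error is at the percent
level). The PMMA shifter instead uses a WER **calibrated from the published
measurements themselves**: the fitted 100.51 MeV range (73.70 mm) minus the
measured residual range behind the 43 mm shifter (35.50 mm) gives
WET ≈ 38.2 mm, i.e. WER ≈ 0.888. This is far from the physical stopping-power
ratio of PMMA (~1.16) and presumably reflects a geometry or reference-plane
convention in the source measurements; internal consistency with the
published residual-range table is what the rest of the pipeline needs, so
0.888 is the default and the composition-derived value is selectable
(`beamline_materials(pmma_wer="physical")`).

A related bookkeeping constant: the published residual ranges (17.5–35.5 mm)
exceed what fits between the water-box entrance and the reported SOBP
position by ~13 mm, so the residual-range scale carries an implicit upstream
reference plane. Target-conforming runs therefore compute a **ranging
offset** (`align_depth_offset`) that places the SOBP's distal 95% level at
the deepest water-equivalent depth of the target — the standard clinical
distal-edge alignment. For the eye study this offset comes out at ~13 mm,
consistent with the implicit offset in the published water-box numbers.

## Transverse transport

The beam's transverse second moments (⟨y²⟩, ⟨yθ⟩, ⟨θ²⟩) are propagated from
the vacuum exit window: drifts update the moments exactly, and every
material adds a Highland/Lynch–Dahl angular kick
`θ₀ = (13.6 MeV/pv)·√(x/X₀)·[1 + 0.038·ln(x/X₀)]` evaluated at the local
energy (slabs thicker than ~1 mm are sub-divided, with the logarithmic term
taken once over the full slab). Air is treated as a distributed scatterer
whose logarithmic correction sees the whole window-to-isocenter column. The
monitor chambers are reduced to their foil material budget (Mylar/Kapton/
Al/Cu anodes and cathodes plus the N₂ gas columns); electrode segmentation
is not modelled, and the un-printed positions inside the nozzle are spread
uniformly — the isocenter width is insensitive to this at the sub-percent
level. The total foil budget is ≈0.9 mm water.

Because the source emittance is not published, each energy's source is
calibrated from two measured planes: the width at the exit window is taken
as-is and an **effective divergence** is solved so the transported FWHM at
the standard isocenter matches the measurement. The three intermediate
measured planes then test the model; predictions land within the ~10% film
uncertainty. For intermediate layer energies the two calibration inputs are
interpolated linearly in energy.

A seeded ray-sampling simulation of the identical drift/kick sequence
confirms the moment algebra to better than 2% on FWHM.

## Scanned delivery and the dose engine

A field is a lattice of Gaussian spots (3 mm pitch, 14×14 over 40×40 mm²).
For each energy layer the transverse fluence is built on the target lattice;
with the brass collimator present the fluence is evaluated at the collimator
plane, masked by the elliptical aperture (perfect absorber/transmitter —
brass edge scatter neglected), and blurred over the remaining 50 mm drift
with the post-shifter angular spread as an independent Gaussian. The
neglected position–angle correlation makes the open-aperture limit a few
percent narrower than the direct transport; the collimated penumbra is
insensitive to it.

Depth dose is looked up at the water-equivalent depth accumulated along
straight columns (divergence within the phantom is ≤30 mrad and is not
applied to ray directions); the depth-dependent lateral growth (residual
divergence plus in-phantom multiple Coulomb scattering, computed as a
Fermi–Eyges integral in water) is applied as an extra per-slice Gaussian
blur of the fluence. For a single spot this reproduces the central-axis
fluence decline a small-field scorer sees.

The **Monte Carlo mode** samples proton histories — layer (∝ weight), spot,
Gaussian position at the masking plane, aperture survival, drift scattering —
and scores each history's conditional expected dose along its column (a
track-repeating/fluence-sampling estimator). Its per-voxel expectation is
identical to the analytic mode by construction, with multinomial counting
noise from the sampled fluence; agreement is verified voxelwise against the
analytic engine at 8×50 000 histories. Identical seeds give bit-identical
dose grids.

## SOBP weights

Energy layers sit at 2 mm residual-range steps. The weight of each layer is
the classic plateau-filling solution: working distal to proximal, layer j's
weight raises the summed dose at its Bragg-peak bin to the plateau height H.
At 2 mm spacing each layer's distal falloff (~1 mm 80–20%) overlaps the next
deeper peak bin, so a single pass overshoots the deep bins by ~4%; the same
condition is therefore iterated (Gauss–Seidel) until the sum equals H at
every peak bin, which brings the inter-peak plateau ripple below 2%. The
resulting relative weights track the published ten-layer table layer by
layer (within ~9% at worst, e.g. 0.368 vs 0.357 for the second layer).

The measured SOBP metrics are: plateau = mean of samples above 90% of the
maximum; width = span between the outermost 95%-of-plateau crossings;
distal falloff = distal 80%→20%-of-plateau distance; entrance ratio =
entrance dose / plateau; flatness = (max−min)/(max+min) over the central 80%
of the width. With these conventions the model gives width 19.07 mm versus
the published 18.10 mm: the analytical curves' sub-peak shoulder stays above
95% for ~1 mm further proximal of the shallowest peak than the Monte Carlo
curves behind the published table. Falloff (1.04 vs 1.3±0.02 mm) and
entrance ratio (72% vs 80%) bracket the published values within their stated
tolerances.

## Transverse uniformity metric

The published uniformity is quoted for the region where dose exceeds 80% of
the central value, with the values "distributed in a Gaussian shape". A
plain 2σ/mean over that region is dominated by the deterministic shoulder
between 80% and 100% at the field edge — for the measured penumbra (σ≈4.3 mm)
it evaluates to ~10–11% regardless of statistics, which cannot reproduce the
published 7%/4%. The default estimator therefore fits a Gaussian to the
histogram of in-region values (robust to the shoulder tail) and reports
2σ/μ in percent; the plain-moment and max–min variants remain available.
Profiles are read out film-style: the mean over a 10 mm central strip of the
thin-layer scorer, 0.5 mm pixels for sampled runs.

## Eye phantom

All dimensions scale with the outer sclera radius (default 12.25 mm). The
printed facts are honoured exactly: a 48 mm water cube as the brain (face
just behind the globe-center plane, eye protruding), a dome-shaped tumor of
9 mm axial extent whose base plane sits at the isocenter, gaze rotation
about the globe center with the whole model translated so the tumor centroid
returns to the beam axis. Everything else is a documented default from
standard ophthalmic anatomy (1.0 mm sclera, 0.5 mm retina, 40° corneal cap,
9×9×4.5 mm lens 5.8 mm anterior of center, ciliary ring, 10 mm optic-nerve
stub tilted 15° nasally, tumor base radius 7 mm = collimator aperture minus
the 3 mm margin), overridable per instance. Voxel labels are assigned at
voxel centers with an innermost-wins priority (tumor > lens > nerve >
ciliary > cornea > retina > sclera > aqueous > vitreous > brain).

At 40° gaze the rigid dome's beam-axis extent is ~11.4 mm, which is why the
six deepest energy layers (≈12 mm SOBP) are the published plan for it.

## The ocular DVH study and its limits

With the published plan pinned (six deepest layers, 20×22 mm aperture, 40°
gaze, 9 mm × 14 mm dome), the tumor's lateral corners sit shallow because
the globe surface curves away from the beam: the tumor spans ~15 mm of
water-equivalent depth against an ~11 mm SOBP. The minimum tumor dose is
then ~0.70 of the maximum — on the SOBP's proximal shoulder — and scanning
the ranging offset for the max-min dose moves it only to ~0.73. At that
iso-level essentially every in-aperture vitreous voxel qualifies, so the
vitreous volume fraction at the tumor-covering level evaluates to ~56%,
against ~40% in the source study. The source study's DVH threshold was an
absolute deposited energy whose per-structure semantics are not recoverable;
this pipeline uses the relative iso-level convention throughout.
Optic-nerve sparing is likewise not reproduced: after the 40° rotation the
nerve stub and the brain water behind it lie inside the aperture at plateau
depth.

## Synthetic CT

The DICOM pathway ships a synthetic head series (documented HU anchors, a
superficial right eye with bony orbit and lens, seeded Gaussian noise) with
the exact clinical slice geometry, plus a two-segment HU→density ramp
anchored at air and water (WER = density for soft tissue, ×0.95 above the
soft-tissue segment). These are synthetic stand-ins for a patient scan: they
exercise the identical code path (DICOM read, crop, calibration, dose,
DVH), but no quantitative dose number on this pathway is compared with the
source study.

## Problem sizes

Default study sizes, chosen so the full suite and the acceptance script run
in minutes on one core: analytic profiles on 0.25 mm pixels; sampled
uniformity runs at 1.8×10⁶ primaries on 0.5 mm pixels (the source study's
statistics); the ocular DVH at 5×10⁵ primaries on a 100³ grid of 0.3 mm
voxels (the source study used up to 5×10⁶ on 200³ of 0.2 mm; the kernel
estimator keeps per-voxel noise at the few-percent level at the smaller
size). Session time for a ~12 Gy fraction at 1 Gy/spill with 1 s spills and
5 s pauses evaluates to 67 s.

## Known limitations

- No nuclear secondaries, neutron dose, or RBE modelling beyond a constant.
- Collimator edge scatter and the position–angle correlation across the
  50 mm drift are neglected.
- In-phantom rays are straight; heterogeneity-induced MCS differences
  (tissue vs water) are ignored.
- The eye-phantom proportions beyond the printed facts are plausible
  defaults, not patient anatomy; DVH numbers for small structures carry the
  corresponding geometric uncertainty.
- Passing the synthetic-CT tests shows the image pathway works, not that the
  HU calibration matches any scanner.
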