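"""Published CNAO commissioning measurements used as model inputs.

These are the measured quantities of the CNAO proton line that calibrate and
validate the transport model: transverse FWHM at five planes for four nominal
energies (radiochromic films, ~10% uncertainty), ranges in water (PTW
Peakfinder), and the energy-layer table of the ocular spread-out Bragg peak
behind the 43 mm PMMA range shifter.
"""

from __future__ import annotations

#: Detector planes along the beam axis (mm; standard isocenter = 0, upstream
#: negative): vacuum exit window, downstream of monitor Box 2, intermediate,
#: isocenter, beyond isocenter.
FWHM_PLANES_MM = (-1093.6, -654.6, -350.0, 0.0, 500.0)

#: Measured transverse FWHM (mm) per nominal energy (MeV) at those planes.
FWHM_MEASURED_MM = {
    81.56: (5.48, 8.35, 12.52, 16.39, 24.52),
    100.51: (5.60, 7.24, 10.46, 13.63, 20.64),
    119.05: (5.50, 6.60, 9.13, 11.25, 17.70),
    148.80: (4.05, 5.65, 7.44, 9.80, 14.15),
}

#: Measured proton ranges in water (mm) per nominal energy (MeV).
RANGES_MEASURED_MM = {
    81.56: 50.00,
    100.51: 74.00,
    119.05: 101.00,
    148.80: 151.00,
}

#: Ocular SOBP energy layers behind the 43 mm PMMA range shifter:
#: (nominal energy MeV, residual range in water mm, published weight %).
#: The first six rows were used for the eye irradiation.
SOBP_LAYERS = (
    (100.51, 35.50, 90.00),
    (99.03, 33.50, 32.10),
    (97.54, 31.50, 25.60),
    (96.04, 29.50, 21.00),
    (94.51, 27.50, 18.24),
    (92.97, 25.50, 15.66),
    (91.41, 23.50, 14.00),
    (89.82, 21.50, 13.00),
    (88.22, 19.50, 11.00),
    (86.59, 17.50, 10.00),
)

#: Relative energy spread of the synchrotron beam.
SIGMA_E_REL = 5e-4

#: Nominal shifter thickness for the ocular setup (mm PMMA).
RS_THICKNESS_MM = 43.0


def range_calibration_points(exclude_energy: float | None = None):
    """(energy, range) pairs for the range-energy fit, optionally leaving
    one energy out for cross-validation."""
    return [
        (e, r)
        for e, r in RANGES_MEASURED_MM.items()
        if exclude_energy is None or abs(e - exclude_energy) > 1e-9
    ]
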