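"""End-to-end replication runs of the published commissioning studies.

Each function reproduces one published observable from scratch: range
cross-validation, shifter WET arithmetic, the 10-layer SOBP in the water
box, transverse FWHM prediction, scanned-field penumbra and uniformity, and
the ocular DVH study.  They are used by the acceptance script and the
acceptance test suite, and are handy as worked examples.
"""

from __future__ import annotations

import numpy as np

from . import cnao
from .beamline import (
    CollimatorSpec,
    build_ocular_layout,
    build_standard_layout,
    calibrated_source,
    default_range_model,
    fwhm_at,
)
from .delivery import (
    ScanPattern,
    align_depth_offset,
    build_sobp_plan,
    select_energy_layers,
    simulate_dose,
)
from .eye import build_eye, thin_layer_grid, voxelize
from .metrics import (
    Profile,
    SOBPMetrics,
    coverage_level,
    dvh,
    penumbra_80_20,
    sobp_metrics,
    transverse_uniformity,
)
from .physics import fit_range_energy, range_in_water


def loo_range_prediction(energy: float = 100.51) -> float:
    """Range at one calibration energy predicted from a fit to the others."""
    model = fit_range_energy(cnao.range_calibration_points(exclude_energy=energy))
    return float(range_in_water(model, energy))


def residual_range_prediction(energy: float = 99.03) -> float:
    """Residual range behind the 43 mm shifter, from the fitted law and the
    WET calibrated on the deepest published layer."""
    model = default_range_model()
    wet = float(model.range_mm(cnao.SOBP_LAYERS[0][0])) - cnao.SOBP_LAYERS[0][1]
    return float(model.range_mm(energy)) - wet


def sobp_water_box_study() -> SOBPMetrics:
    """The 10-layer SOBP on the analytic engine: summed degraded Bragg
    curves at the published residual ranges with plateau-filling weights."""
    model = default_range_model()
    wet = float(model.range_mm(100.51)) - cnao.SOBP_LAYERS[0][1]
    layers = select_energy_layers(
        cnao.SOBP_LAYERS[0][1], 18.0, 2.0, degrader_wet_mm=wet, range_model=model
    )
    plan = build_sobp_plan(layers, wet, model)
    prof = Profile(plan.depth_grid, plan.depth_dose(), axis="depth")
    return sobp_metrics(prof)


def fwhm_prediction(energy: float = 81.56, plane_mm: float = -654.6) -> float:
    """Transverse FWHM at an intermediate plane from the two-plane-calibrated
    source."""
    model = default_range_model()
    src = calibrated_source(energy, model)
    lay = build_standard_layout(energy)
    return fwhm_at(lay, src, plane_mm, model)


def _scan_field_dose(
    collimator: bool,
    mode: str = "analytic",
    n_primaries: int = 0,
    seed: int | None = None,
    pixel_mm: float = 0.25,
):
    model = default_range_model()
    wet_layout = build_ocular_layout(
        100.51,
        cnao.RS_THICKNESS_MM,
        collimator=CollimatorSpec() if collimator else None,
        range_model=model,
    )
    wet = wet_layout.shifter_wet()
    layers = select_energy_layers(
        cnao.SOBP_LAYERS[0][1], 0.0, degrader_wet_mm=wet, range_model=model
    )
    plan = build_sobp_plan(layers, wet, model)
    target = thin_layer_grid(
        field_mm=(70.0, 70.0), pixel_mm=pixel_mm, center=(-530.0, 0.0, 0.0)
    )
    return simulate_dose(
        wet_layout, plan, ScanPattern(), target, mode=mode,
        n_primaries=n_primaries, seed=seed, range_model=model,
    )


def field_penumbra(collimator: bool) -> float:
    """80-20% Y penumbra of the 40x40 mm scanned field on the thin layer."""
    d = _scan_field_dose(collimator)
    prof = d.strip_profile("y", strip_mm=10.0)
    return penumbra_80_20(prof, "right")


def field_uniformity(
    collimator: bool, seed: int, n_primaries: int = 1_800_000
) -> float:
    """Plateau uniformity of the sampled scanned field (study-level
    statistics: 1.8e6 primaries, 0.5 mm pixels, 10 mm strip readout)."""
    d = _scan_field_dose(
        collimator, mode="mc", n_primaries=n_primaries, seed=seed, pixel_mm=0.5
    )
    prof = d.strip_profile("y", strip_mm=10.0)
    return transverse_uniformity(prof)


def eye_dvh_study(
    seed: int,
    n_primaries: int = 500_000,
    voxel_mm: float = 0.3,
    shape=(100, 100, 100),
) -> dict:
    """Full ocular irradiation of the voxelized eye phantom.

    40 deg gaze, 43 mm shifter, elliptical brass collimator, the six deepest
    energy layers, 40x40 mm scan; returns the tumor-coverage iso-level and
    the per-structure volume fractions at that level.
    """
    model = default_range_model()
    layout = build_ocular_layout(
        100.51, cnao.RS_THICKNESS_MM, collimator=CollimatorSpec(),
        range_model=model,
    )
    wet = layout.shifter_wet()
    layers = select_energy_layers(
        cnao.SOBP_LAYERS[0][1], 10.0, 2.0, degrader_wet_mm=wet,
        range_model=model, n_layers=6,
    )
    plan = build_sobp_plan(layers, wet, model)
    grid = voxelize(build_eye(12.25, gaze_angle=40.0), voxel_mm, shape=shape)
    offset = align_depth_offset(plan, grid, "tumor", 0.95)
    dose = simulate_dose(
        layout, plan, ScanPattern(), grid, mode="mc",
        n_primaries=n_primaries, seed=seed, range_model=model,
        depth_offset_mm=offset,
    )
    curves = {c.structure: c for c in dvh(dose)}
    level = coverage_level(curves["tumor"], 100.0)
    return {
        "iso_level_rel": level / float(dose.dose.max()),
        "depth_offset_mm": offset,
        "fractions_pct": {
            name: c.fraction_at(level) for name, c in curves.items()
        },
    }
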