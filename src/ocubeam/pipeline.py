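"""Configuration, run orchestration and deterministic manifests.

Every CLI verb is a thin veneer over these functions; a run directory gets
the metrics JSON, profile/DVH tables, exported dose grids and a manifest
(config echo, seed, package version) sufficient to reproduce the outputs
bit-for-bit in Monte Carlo mode.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, cnao
from .beamline import (
    CollimatorSpec,
    build_ocular_layout,
    build_standard_layout,
    calibrated_source,
    default_range_model,
    fwhm_at,
    fwhm_vs_rs_thickness,
)
from .delivery import (
    ScanPattern,
    align_depth_offset,
    build_sobp_plan,
    select_energy_layers,
    simulate_dose,
)
from .eye import build_eye, export_metaimage, thin_layer_grid, voxelize, water_box_grid
from .metrics import (
    Profile,
    dvh,
    export_dvh_csv,
    penumbra_80_20,
    sobp_metrics,
    transverse_uniformity,
)
from .physics import range_in_water


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """One pipeline run: beam, layout, plan, scan, phantom, scoring."""

    energy: float = 100.51
    sigmaE_rel: float = cnao.SIGMA_E_REL
    layout: str = "ocular"  # standard | ocular
    rs_thickness: float = cnao.RS_THICKNESS_MM
    collimator: bool = False
    distal_range: float = 35.5
    sobp_width: float = 18.0
    layer_spacing: float = 2.0
    n_layers: int | None = None
    scan_step: float = 3.0
    scan_field: tuple[float, float] = (40.0, 40.0)
    single_spot: bool = False
    phantom: str = "water_box"  # water_box | thin_layer | eye | dicom
    eye_radius: float = 12.25
    gaze_angle: float = 40.0
    voxel_size: float = 0.3
    grid_shape: tuple[int, int, int] = (100, 100, 100)
    mode: str = "analytic"  # analytic | mc
    events: int = 0
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise ConfigError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self):
        if self.mode == "mc" and self.seed is None:
            raise ConfigError("mc mode requires an explicit seed")
        if self.mode == "mc" and self.events <= 0:
            raise ConfigError("mc mode requires events > 0")
        if self.layout not in ("standard", "ocular"):
            raise ConfigError(f"unknown layout {self.layout!r}")
        if self.phantom not in ("water_box", "thin_layer", "eye", "dicom"):
            raise ConfigError(f"unknown phantom {self.phantom!r}")


def _manifest(config: RunConfig, outputs: dict, out_dir: Path) -> dict:
    cfg = asdict(config)
    blob = json.dumps(cfg, sort_keys=True).encode()
    man = {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "python": platform.python_version(),
        "outputs": sorted(outputs),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(man, fh, indent=2, sort_keys=True)
    return man


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute build -> plan -> simulate -> score and write all artifacts."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    model = default_range_model()
    metrics: dict = {}
    outputs: dict = {}

    try:
        wet = 0.0
        if config.layout == "ocular":
            coll = CollimatorSpec() if config.collimator else None
            layout = build_ocular_layout(
                config.energy, config.rs_thickness, collimator=coll,
                range_model=model,
            )
            wet = layout.shifter_wet()
        else:
            layout = build_standard_layout(config.energy)

        layers = select_energy_layers(
            config.distal_range,
            config.sobp_width,
            config.layer_spacing,
            degrader_wet_mm=wet,
            range_model=model,
            n_layers=config.n_layers,
        )
        plan = build_sobp_plan(layers, wet, model, sigmaE_rel=config.sigmaE_rel)
        metrics["layers"] = [
            {
                "energy_mev": l.nominal_energy,
                "residual_range_mm": l.residual_range,
                "weight": l.weight,
            }
            for l in plan.layers
        ]

        scan = (
            ScanPattern.single_spot()
            if config.single_spot
            else ScanPattern(step=config.scan_step, field=tuple(config.scan_field))
        )

        offset = 0.0
        if config.phantom == "water_box":
            target = water_box_grid(center=(layout.active_isocenter, 0.0, 0.0))
            offset = 12.5  # box entrance at the residual-range reference plane
        elif config.phantom == "thin_layer":
            target = thin_layer_grid(center=(layout.active_isocenter, 0.0, 0.0))
        elif config.phantom == "eye":
            eye = build_eye(config.eye_radius, config.gaze_angle)
            target = voxelize(
                eye, config.voxel_size, shape=tuple(config.grid_shape)
            )
            offset = align_depth_offset(plan, target)
        else:  # dicom
            from .synthetic_ct import (
                SyntheticHeadSpec, crop_roi, ct_to_grid, default_crop,
                generate_head_ct, read_series,
            )

            spec = SyntheticHeadSpec(seed=config.seed or 0)
            ct_dir = out / "ct"
            generate_head_ct(spec, ct_dir)
            vol, spacing = read_series(ct_dir)
            roi = crop_roi(vol, default_crop(spec))
            target = ct_to_grid(roi, spacing)
            offset = config.distal_range - 12.0  # point-beam ranging offset

        dose = simulate_dose(
            layout,
            plan,
            scan,
            target,
            mode=config.mode,
            n_primaries=config.events,
            seed=config.seed,
            range_model=model,
            depth_offset_mm=offset,
        )
        outputs["dose.mhd"] = True
        export_metaimage(target, dose.dose, str(out / "dose"))
        if config.phantom in ("eye", "dicom"):
            export_metaimage(target, target.labels.astype(np.float32),
                             str(out / "labels"))
            outputs["labels.mhd"] = True

        if config.phantom in ("water_box",):
            prof = dose.profile("depth")
            np.savetxt(
                out / "depth_dose.csv",
                np.column_stack([prof.coordinate, prof.value]),
                delimiter=",",
                header="depth_mm,dose",
                comments="",
            )
            outputs["depth_dose.csv"] = True
            m = sobp_metrics(prof)
            metrics["sobp"] = {
                "width_mm": m.width,
                "distal_falloff_80_20_mm": m.distal_falloff_80_20,
                "entrance_plateau_pct": m.entrance_plateau_ratio,
                "flatness_pct": m.flatness,
            }
        if config.phantom == "thin_layer":
            for ax in ("y", "z"):
                prof = dose.strip_profile(ax, strip_mm=10.0)
                np.savetxt(
                    out / f"profile_{ax}.csv",
                    np.column_stack([prof.coordinate, prof.value]),
                    delimiter=",",
                    header=f"{ax}_mm,dose",
                    comments="",
                )
                outputs[f"profile_{ax}.csv"] = True
                metrics[f"penumbra_80_20_{ax}_mm"] = penumbra_80_20(prof, "right")
                metrics[f"uniformity_{ax}_pct"] = transverse_uniformity(prof)
        if config.phantom in ("eye", "dicom"):
            curves = dvh(dose)
            export_dvh_csv(curves, str(out / "dvh"))
            for c in curves:
                outputs[f"dvh_{c.structure}.csv"] = True
            metrics["dvh_structures"] = [c.structure for c in curves]
            metrics["depth_offset_mm"] = offset
    except Exception as err:  # re-raise with stage context
        raise RuntimeError(f"pipeline failed for config in {out}: {err}") from err

    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    outputs["metrics.json"] = True
    man = _manifest(config, outputs, out)
    return {"metrics": metrics, "manifest": man}


# -- commissioning-style reports --------------------------------------------

def range_report() -> list[dict]:
    """Measured vs fitted range at every calibration energy plus the
    leave-one-out prediction at each (Table-shaped validation)."""
    rows = []
    model = default_range_model()
    for e, r in cnao.RANGES_MEASURED_MM.items():
        from .physics import fit_range_energy

        loo = fit_range_energy(cnao.range_calibration_points(exclude_energy=e))
        rows.append(
            {
                "energy_mev": e,
                "measured_range_mm": r,
                "fitted_range_mm": float(range_in_water(model, e)),
                "loo_predicted_mm": float(range_in_water(loo, e)),
            }
        )
    return rows


def fwhm_report(energy: float) -> list[dict]:
    """Predicted vs measured FWHM at the five documented planes."""
    layout = build_standard_layout(energy)
    src = calibrated_source(energy)
    meas = cnao.FWHM_MEASURED_MM[round(energy, 2)]
    return [
        {
            "plane_mm": p,
            "measured_fwhm_mm": meas[i],
            "predicted_fwhm_mm": fwhm_at(layout, src, p),
        }
        for i, p in enumerate(cnao.FWHM_PLANES_MM)
    ]


def rs_study(energy: float = 100.51, thicknesses=None) -> dict:
    thicknesses = list(thicknesses or np.arange(35.0, 70.1, 5.0))
    return {
        "optimized_isocenter": fwhm_vs_rs_thickness(energy, thicknesses, False),
        "standard_isocenter": fwhm_vs_rs_thickness(energy, thicknesses, True),
    }
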