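"""SOBP design, scanned-spot delivery and dose computation.

Dose model: for each energy layer the transverse fluence of the scanned spot
pattern is built on the target's (Y, Z) lattice — masked at the collimator
plane and blurred over the remaining drift with the post-degrader angular
spread when a collimator is present — and multiplied, column by column, by
the layer's analytical depth dose looked up at the water-equivalent depth
accumulated along rays parallel to the beam axis.  The depth-dependent
lateral growth inside the phantom (residual divergence plus in-phantom
multiple Coulomb scattering) is applied as an extra per-slice Gaussian blur.

The Monte Carlo mode samples proton histories — energy layer, spot, Gaussian
spot position at the masking plane, collimator transmission, drift scattering
— and scores each history's conditional expected dose along its ray (a
track-repeating kernel estimator); its per-voxel expectation is identical to
the analytic mode, with counting noise from the sampled fluence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from . import cnao
from .beamline import (
    BeamlineLayout,
    BeamSource,
    calibrate_source,
    default_range_model,
    transport_moments,
)
from .eye import LabeledGrid
from .physics import (
    PristineCurve,
    RangeEnergyModel,
    lateral_mcs_sigma_water,
    pristine_depth_dose,
)


class PlanError(ValueError):
    pass


@dataclass(frozen=True)
class EnergyLayer:
    nominal_energy: float  # MeV
    residual_range: float  # mm water, behind the degrader
    weight: float = 0.0  # fraction of the plateau height H

    def __post_init__(self):
        if self.residual_range <= 0:
            raise PlanError("residual range must be positive")


@dataclass(frozen=True)
class SOBPPlan:
    """Energy layers with plateau-filling weights and their depth curves."""

    layers: tuple[EnergyLayer, ...]
    H: float
    depth_grid: np.ndarray
    curves: tuple[PristineCurve, ...]
    fluence_factors: tuple[np.ndarray, ...] | None = None
    layer_spacing: float = 2.0

    @property
    def weights(self) -> np.ndarray:
        return np.array([l.weight for l in self.layers])

    @property
    def distal_range(self) -> float:
        return max(l.residual_range for l in self.layers)

    def depth_dose(self, depth_mm=None) -> np.ndarray:
        """Summed SOBP on the plan's depth grid (or interpolated)."""
        total = np.zeros_like(self.depth_grid)
        for i, (layer, curve) in enumerate(zip(self.layers, self.curves)):
            h = curve(self.depth_grid)
            if self.fluence_factors is not None:
                h = h * self.fluence_factors[i]
            total += layer.weight * h
        if depth_mm is None:
            return total
        return np.interp(depth_mm, self.depth_grid, total, left=total[0], right=0.0)


@dataclass(frozen=True)
class ScanPattern:
    """Discrete transverse spot lattice: (y, z) positions in mm."""

    step: float = 3.0
    field: tuple[float, float] = (40.0, 40.0)
    positions: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        if not self.positions:
            object.__setattr__(self, "positions", tuple(
                (float(y), float(z))
                for y in _lattice(self.field[0], self.step)
                for z in _lattice(self.field[1], self.step)
            ))

    @classmethod
    def single_spot(cls) -> "ScanPattern":
        return cls(step=1.0, field=(0.0, 0.0), positions=((0.0, 0.0),))


def _lattice(extent: float, step: float) -> np.ndarray:
    # spot positions at `step` pitch, symmetric, spanning at most `extent`
    n = max(int(math.floor(extent / step + 1e-9)) + 1, 1)
    return (np.arange(n) - (n - 1) / 2.0) * step


@dataclass(frozen=True)
class PrescriptionConfig:
    dose_per_fraction: float = 12.0  # Gy (RBE-weighted dose / RBE)
    rbe: float = 1.1
    gy_per_spill: float = 1.0
    spill_s: float = 1.0
    pause_s: float = 5.0

    def __post_init__(self):
        for f in ("rbe", "gy_per_spill", "spill_s", "pause_s"):
            if getattr(self, f) <= 0:
                raise PlanError(f"{f} must be positive")
        if self.dose_per_fraction < 0:
            raise PlanError("dose must be non-negative")


def session_time(prescription: PrescriptionConfig) -> float:
    """Seconds per treatment session at the synchrotron spill structure."""
    if prescription.dose_per_fraction == 0:
        return 0.0
    spills = math.ceil(prescription.dose_per_fraction / prescription.gy_per_spill)
    return spills * prescription.spill_s + (spills - 1) * prescription.pause_s


# ---------------------------------------------------------------------------
# Layer selection and SOBP weights
# ---------------------------------------------------------------------------

def select_energy_layers(
    distal_range_mm: float,
    sobp_width_mm: float,
    spacing_mm: float = 2.0,
    degrader_wet_mm: float = 0.0,
    range_model: RangeEnergyModel | None = None,
    n_layers: int | None = None,
) -> list[EnergyLayer]:
    """Energy layers at ``spacing`` pull-back steps covering the SOBP width.

    Residual ranges run from the distal range down in ``spacing`` steps,
    inclusive of the layer at ``distal_range - width``; nominal energies are
    obtained by inverting the range-energy law through the degrader WET.
    ``n_layers`` overrides the width-derived count (e.g. the six deepest
    layers of the published table).
    """
    if spacing_mm <= 0:
        raise PlanError("spacing must be positive")
    if sobp_width_mm < 0:
        raise PlanError("width must be non-negative")
    model = range_model or default_range_model()
    if n_layers is None:
        n_layers = int(math.floor(sobp_width_mm / spacing_mm + 1e-9)) + 1
    if n_layers < 1:
        raise PlanError("width/spacing imply fewer than one layer")
    out = []
    for k in range(n_layers):
        resid = distal_range_mm - k * spacing_mm
        if resid <= 0:
            raise PlanError("requested width reaches zero residual range")
        energy = float(model.energy_mev(resid + degrader_wet_mm))
        out.append(EnergyLayer(energy, resid))
    return out


def compute_sobp_weights(
    curves,
    H: float = 1.0,
    depth_grid: np.ndarray | None = None,
    fluence_factors=None,
    layers=None,
    iterate: bool = True,
) -> SOBPPlan:
    """Plateau-filling weights, distal to proximal.

    Working from the deepest layer inward, the weight of layer j brings the
    summed dose at that layer's Bragg-peak bin b_j up to the plateau height:
    w_j = (H - sum_{k<j} w_k h_k(b_j)) / h_j(b_j).

    At 2 mm pull-back spacing the distal falloff of each layer overlaps the
    next deeper peak bin, so a single distal-to-proximal pass overshoots the
    deep bins by a few percent; with ``iterate`` (default) the same filling
    condition is swept repeatedly until the summed dose equals H at every
    peak bin (Gauss-Seidel on the plateau condition).
    """
    curves = list(curves)
    ranges = [c.range_water for c in curves]
    if sorted(ranges, reverse=True) != ranges:
        raise PlanError("curves must be ordered deepest first")
    if len(set(np.round(ranges, 6))) != len(ranges):
        raise PlanError("two layers share the same range: degenerate plan")
    if depth_grid is None:
        depth_grid = np.arange(0.0, max(ranges) + 6.0, 0.02)
    ff = None
    if fluence_factors is not None:
        ff = tuple(np.interp(depth_grid, f[0], f[1]) for f in fluence_factors)

    n = len(curves)
    sampled = []
    for i, c in enumerate(curves):
        h = c(depth_grid)
        if ff is not None:
            h = h * ff[i]
        sampled.append(h)
    w = np.zeros(n)
    bins = [int(np.argmax(s)) for s in sampled]
    hkj = np.array([[sampled[k][bins[j]] for j in range(n)] for k in range(n)])
    for j in range(n):
        acc = float(w[:j] @ hkj[:j, j])
        w[j] = (H - acc) / hkj[j, j]
        if w[j] <= 0:
            raise PlanError("negative layer weight: plateau infeasible")
    if iterate:
        for _ in range(200):
            delta = 0.0
            for j in range(n):
                acc = float(w @ hkj[:, j]) - w[j] * hkj[j, j]
                new = (H - acc) / hkj[j, j]
                if new <= 0:
                    raise PlanError("negative layer weight: plateau infeasible")
                delta = max(delta, abs(new - w[j]))
                w[j] = new
            if delta < 1e-12 * H:
                break
    if layers is None:
        layers = [EnergyLayer(c.energy, c.range_water) for c in curves]
    layers = tuple(
        EnergyLayer(l.nominal_energy, l.residual_range, float(wi))
        for l, wi in zip(layers, w)
    )
    return SOBPPlan(
        layers=layers,
        H=H,
        depth_grid=depth_grid,
        curves=tuple(curves),
        fluence_factors=ff,
    )


def build_sobp_plan(
    layers,
    degrader_wet_mm: float,
    range_model: RangeEnergyModel | None = None,
    H: float = 1.0,
    sigmaE_rel: float = cnao.SIGMA_E_REL,
    depth_grid: np.ndarray | None = None,
    fluence_factors=None,
) -> SOBPPlan:
    """Analytic pristine curves for each layer plus plateau-filling weights."""
    model = range_model or default_range_model()
    curves = [
        pristine_depth_dose(
            l.nominal_energy, model, sigmaE_rel=sigmaE_rel,
            degrader_wet_mm=degrader_wet_mm,
        )
        for l in layers
    ]
    return compute_sobp_weights(
        curves, H=H, depth_grid=depth_grid,
        fluence_factors=fluence_factors, layers=tuple(layers),
    )


def central_axis_fluence_factor(
    layout: BeamlineLayout,
    source: BeamSource,
    entrance_plane_mm: float,
    depth_grid: np.ndarray,
    residual_range_mm: float,
    range_model: RangeEnergyModel | None = None,
):
    """Relative central-axis fluence vs depth for a single spot.

    The spot Gaussian keeps widening inside the phantom (residual divergence
    of the transported beam plus in-phantom MCS); the on-axis fluence of a
    2-D Gaussian scales as 1/sigma^2.  Returned as (depth grid, factor
    normalized to 1 at the entrance plane).
    """
    model = range_model or default_range_model()
    mom = transport_moments(layout, source, entrance_plane_mm, model)
    sig2_drift = (
        mom.a2
        + 2.0 * depth_grid * mom.a1
        + depth_grid**2 * mom.a0
    )
    sig_mcs = lateral_mcs_sigma_water(depth_grid, residual_range_mm, model)
    sig2 = sig2_drift + sig_mcs**2
    return depth_grid, sig2[0] / sig2


# ---------------------------------------------------------------------------
# Dose simulation
# ---------------------------------------------------------------------------

@dataclass
class DoseGrid:
    """Scored dose on a labelled voxel grid (relative units)."""

    grid: LabeledGrid
    dose: np.ndarray
    n_primaries: int = 0
    seed: int | None = None
    mode: str = "analytic"

    def normalized(self) -> np.ndarray:
        m = self.dose.max()
        return self.dose / m if m > 0 else self.dose

    def profile(self, axis: str, through=None):
        """1-D profile through the grid center along 'depth'|'y'|'z'."""
        from .metrics import Profile

        d = self.dose
        ix, iy, iz = (np.array(self.dose.shape) // 2)
        if through is not None:
            ix, iy, iz = through
        if axis == "depth":
            return Profile(self.grid.axis_coords(0), d[:, iy, iz], axis="depth")
        if axis == "y":
            return Profile(self.grid.axis_coords(1), d[ix, :, iz], axis="Y")
        if axis == "z":
            return Profile(self.grid.axis_coords(2), d[ix, iy, :], axis="Z")
        raise ValueError(axis)

    def strip_profile(self, axis: str = "y", strip_mm: float = 10.0):
        """Transverse profile averaged over a central strip of the other
        transverse axis (film-like readout)."""
        from .metrics import Profile

        d = self.dose.sum(axis=0) if self.dose.shape[0] > 1 else self.dose[0]
        ys = self.grid.axis_coords(1)
        zs = self.grid.axis_coords(2)
        if axis == "y":
            sel = np.abs(zs - zs.mean()) <= strip_mm / 2.0
            return Profile(ys, d[:, sel].mean(axis=1), axis="Y")
        sel = np.abs(ys - ys.mean()) <= strip_mm / 2.0
        return Profile(zs, d[sel, :].mean(axis=0), axis="Z")


def _spot_sigma_at(layout, source, plane, model):
    mom = transport_moments(layout, source, plane, model)
    return float(np.sqrt(mom.a2)), mom


def _layer_source(energy_mev, range_model):
    """Source for an arbitrary layer energy, interpolating the two-plane
    calibration data across the measured energies."""
    energies = np.array(sorted(cnao.FWHM_MEASURED_MM))
    w0 = np.array([cnao.FWHM_MEASURED_MM[e][0] for e in energies])
    wiso = np.array([cnao.FWHM_MEASURED_MM[e][3] for e in energies])
    f0 = float(np.interp(energy_mev, energies, w0))
    fi = float(np.interp(energy_mev, energies, wiso))
    return calibrate_source(energy_mev, f0, fi, range_model)


def _fluence_map(
    layout, source, scan, ys, zs, model, rng=None, n_samples=0
):
    """Spot-summed transverse fluence on the (ys, zs) lattice at the active
    isocenter plane; analytic if rng is None, sampled otherwise.

    Returns (fluence, sigma_iso, moments_at_iso)."""
    iso = layout.active_isocenter
    has_coll = layout.collimator is not None
    plane = layout.collimator_position if has_coll else iso
    sig_plane, mom_plane = _spot_sigma_at(layout, source, plane, model)
    _, mom_iso = _spot_sigma_at(layout, source, iso, model)
    drift = iso - plane
    sig_blur = float(np.sqrt(mom_plane.a0)) * drift

    dy = ys[1] - ys[0] if len(ys) > 1 else 1.0
    dz = zs[1] - zs[0] if len(zs) > 1 else 1.0
    spots = np.asarray(scan.positions, float)

    if rng is None:
        yy = ys[:, None, None] - spots[None, None, :, 0]
        zz = zs[None, :, None] - spots[None, None, :, 1]
        F = np.exp(-(yy**2) / (2 * sig_plane**2)) * np.exp(
            -(zz**2) / (2 * sig_plane**2)
        )
        F = F.sum(axis=2) / (2 * np.pi * sig_plane**2)
    else:
        idx = rng.integers(0, len(spots), size=n_samples)
        y = spots[idx, 0] + rng.normal(0.0, sig_plane, n_samples)
        z = spots[idx, 1] + rng.normal(0.0, sig_plane, n_samples)
        if has_coll:
            c = layout.collimator
            keep = (y / c.aperture_semi_y) ** 2 + (z / c.aperture_semi_z) ** 2 <= 1.0
            y, z = y[keep], z[keep]
        if drift > 0:
            sig_th = float(np.sqrt(mom_plane.a0))
            y = y + rng.normal(0.0, sig_th * drift, len(y))
            z = z + rng.normal(0.0, sig_th * drift, len(z))
        edges_y = np.concatenate([ys - dy / 2, [ys[-1] + dy / 2]])
        edges_z = np.concatenate([zs - dz / 2, [zs[-1] + dz / 2]])
        H, _, _ = np.histogram2d(y, z, bins=(edges_y, edges_z))
        F = H * len(spots) / (n_samples * dy * dz)
        return F, float(np.sqrt(mom_iso.a2)), mom_iso

    if has_coll:
        c = layout.collimator
        yy, zz = np.meshgrid(ys, zs, indexing="ij")
        F = F * ((yy / c.aperture_semi_y) ** 2 + (zz / c.aperture_semi_z) ** 2 <= 1.0)
        if sig_blur > 0:
            F = gaussian_filter(F, sigma=(sig_blur / dy, sig_blur / dz), mode="constant")
    return F, float(np.sqrt(mom_iso.a2)), mom_iso


def simulate_dose(
    layout: BeamlineLayout,
    plan: SOBPPlan,
    scan: ScanPattern,
    target: LabeledGrid,
    mode: str = "analytic",
    n_primaries: int = 0,
    seed: int | None = None,
    range_model: RangeEnergyModel | None = None,
    depth_offset_mm: float = 0.0,
    in_phantom_spread: bool = True,
) -> DoseGrid:
    """Score the planned scanned irradiation on a labelled grid.

    ``depth_offset_mm`` is added to every column's water-equivalent depth;
    it represents the ranging offset between the residual-range reference
    plane of the layer table and the phantom surface (set by
    :func:`align_depth_offset` for target-conforming irradiations).
    """
    if mode not in ("analytic", "mc"):
        raise ValueError("mode must be 'analytic' or 'mc'")
    if mode == "mc":
        if seed is None:
            raise ValueError("mc mode requires a seed (reproducibility contract)")
        if n_primaries <= 0:
            raise ValueError("mc mode requires n_primaries > 0")
    model = range_model or default_range_model()

    xs = target.axis_coords(0)
    ys = target.axis_coords(1)
    zs = target.axis_coords(2)
    dx = target.voxel_size[0]
    # water-equivalent depth at each voxel center, column by column
    wed = np.cumsum(target.wer * dx, axis=0) - 0.5 * dx * target.wer
    wed = wed + depth_offset_mm

    weights = plan.weights
    wsum = weights.sum()
    rng = np.random.default_rng(seed) if mode == "mc" else None

    dose = np.zeros(target.shape)
    n_alloc = None
    if mode == "mc":
        n_alloc = rng.multinomial(n_primaries, weights / wsum)

    dy = ys[1] - ys[0] if len(ys) > 1 else target.voxel_size[1]
    dz = zs[1] - zs[0] if len(zs) > 1 else target.voxel_size[2]

    for i, (layer, curve) in enumerate(zip(plan.layers, plan.curves)):
        source = _layer_source(layer.nominal_energy, model)
        if rng is None:
            F, sig_iso, mom_iso = _fluence_map(layout, source, scan, ys, zs, model)
            layer_norm = weights[i]
        else:
            if n_alloc[i] == 0:
                continue
            F, sig_iso, mom_iso = _fluence_map(
                layout, source, scan, ys, zs, model, rng=rng, n_samples=int(n_alloc[i])
            )
            layer_norm = weights[i]  # fluence map is normalized per primary
        # per-slice extra lateral spread relative to the isocenter plane
        if in_phantom_spread:
            depth_cols = wed.mean(axis=(1, 2)) - depth_offset_mm
            sig_mcs = lateral_mcs_sigma_water(depth_cols, layer.residual_range, model)
            drift = xs - layout.active_isocenter
            sig2_x = mom_iso.a2 + 2 * drift * mom_iso.a1 + drift**2 * mom_iso.a0
            extra = np.sqrt(np.clip(sig2_x + sig_mcs**2 - mom_iso.a2, 0.0, None))
        else:
            extra = np.zeros(len(xs))
        ddd = curve(wed)
        for k in range(len(xs)):
            Fk = F
            if extra[k] > 0.05:
                Fk = gaussian_filter(
                    F, sigma=(extra[k] / dy, extra[k] / dz), mode="constant"
                )
            dose[k] += layer_norm * Fk * ddd[k]
    return DoseGrid(
        grid=target, dose=dose, n_primaries=n_primaries, seed=seed, mode=mode
    )


def align_depth_offset(
    plan: SOBPPlan,
    target: LabeledGrid,
    structure: str = "tumor",
    coverage_level: float = 0.95,
) -> float:
    """Ranging offset that puts the SOBP distal coverage level at the
    structure's deepest water-equivalent depth (distal-edge alignment, the
    standard clinical ranging step)."""
    dx = target.voxel_size[0]
    wed = np.cumsum(target.wer * dx, axis=0) - 0.5 * dx * target.wer
    m = target.mask(structure)
    if not m.any():
        raise PlanError(f"target grid contains no {structure!r} voxels")
    wed_max = float(wed[m].max())
    sobp = plan.depth_dose()
    z = plan.depth_grid
    pm = (z >= min(c.peak_depth for c in plan.curves)) & (
        z <= max(c.peak_depth for c in plan.curves)
    )
    plateau = sobp[pm].mean()
    lvl = coverage_level * plateau
    i = int(np.argmax(sobp))
    below = np.nonzero(sobp[i:] <= lvl)[0]
    j = below[0] + i
    z_distal = float(np.interp(lvl, [sobp[j], sobp[j - 1]], [z[j], z[j - 1]]))
    return z_distal - wed_max
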