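"""Closed-form proton physics in water and slabs.

The depth-dose engine is the analytical Bragg-curve model of Bortfeld
(power-law range-energy relation, Gaussian range straggling, linear fluence
reduction), evaluated with parabolic-cylinder functions near the peak and
with its asymptotic closed form far upstream.  Multiple Coulomb scattering
uses the Highland formula with the Lynch-Dahl logarithmic correction and
internal sub-slab integration for thick degraders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import gamma as _gamma
from scipy.special import pbdv

from .materials import MaterialSpec

PROTON_MASS_MEV = 938.272

# Bortfeld model shape constants (cm units internally):
#   BETA  - slope of the fluence reduction per unit depth (1/cm)
#   GAMMA - fraction of the locally released energy from nuclear interactions
#           that is deposited locally
#   EPS   - fraction of the primary fluence contributing to the low-energy
#           "tail"; 0.2 is Bortfeld's upper recommended value and suits the
#           degraded sub-100 MeV beams modelled here.
BETA_CM = 0.012
GAMMA_NUC = 0.6
EPS_TAIL = 0.2

#: sigma_mono = STRAGGLE_K * R^STRAGGLE_P, R and sigma in cm (range straggling
#: of an initially monoenergetic beam in water).
STRAGGLE_K = 0.012
STRAGGLE_P = 0.935


class PhysicsError(ValueError):
    pass


class ExtrapolationWarning(UserWarning):
    """Energy far outside the calibration interval of a range-energy fit."""


# ---------------------------------------------------------------------------
# Range-energy law
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RangeEnergyModel:
    """Power-law range-energy relation R = alpha * E^p (R in mm, E in MeV)."""

    alpha: float
    p: float
    calibration_points: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        if self.alpha <= 0:
            raise PhysicsError("alpha must be positive")
        if not (1.0 < self.p < 2.2):
            raise PhysicsError(f"implausible range-law exponent p={self.p}")

    def range_mm(self, energy_mev) -> np.ndarray | float:
        return self.alpha * np.asarray(energy_mev, float) ** self.p

    def energy_mev(self, range_mm) -> np.ndarray | float:
        return (np.asarray(range_mm, float) / self.alpha) ** (1.0 / self.p)


def fit_range_energy(points) -> RangeEnergyModel:
    """Least-squares fit of R = alpha*E^p in log-log space.

    Parameters
    ----------
    points : sequence of (energy MeV, range mm)
    """
    pts = [(float(e), float(r)) for e, r in points]
    if len(pts) < 2:
        raise PhysicsError("need at least two calibration points")
    E = np.array([p[0] for p in pts])
    R = np.array([p[1] for p in pts])
    if np.any(E <= 0) or np.any(R <= 0):
        raise PhysicsError("energies and ranges must be positive")
    if len(np.unique(E)) != len(E):
        raise PhysicsError("energies must be distinct")
    A = np.vstack([np.ones_like(E), np.log(E)]).T
    (c, p), *_ = np.linalg.lstsq(A, np.log(R), rcond=None)
    model = RangeEnergyModel(float(np.exp(c)), float(p), tuple(pts))
    for e, r in pts:
        if abs(model.range_mm(e) - r) / r > 0.015:
            raise PhysicsError(
                f"fit misses calibration point ({e} MeV, {r} mm) by >1.5%"
            )
    return model


def range_in_water(model: RangeEnergyModel, energy_mev: float) -> float:
    """Range in water (distal 80% depth) at the given energy, in mm."""
    if model.calibration_points:
        emin = min(e for e, _ in model.calibration_points)
        emax = max(e for e, _ in model.calibration_points)
        if not (0.5 * emin <= energy_mev <= 1.5 * emax):
            warnings.warn(
                f"{energy_mev} MeV far outside calibration interval "
                f"[{emin}, {emax}] MeV",
                ExtrapolationWarning,
                stacklevel=2,
            )
    return float(model.range_mm(energy_mev))


def proton_pv(energy_mev) -> np.ndarray | float:
    """Relativistic momentum*velocity (MeV) of a proton of kinetic energy T."""
    T = np.asarray(energy_mev, float)
    m = PROTON_MASS_MEV
    return T * (T + 2 * m) / (T + m)


# ---------------------------------------------------------------------------
# Water-equivalent thickness
# ---------------------------------------------------------------------------

def water_equivalent_thickness(material: MaterialSpec, thickness_mm: float) -> float:
    """WET of a slab in mm of water (linear in thickness)."""
    if thickness_mm < 0:
        raise PhysicsError("thickness must be non-negative")
    return material.wer * thickness_mm


# ---------------------------------------------------------------------------
# Analytical Bragg curves
# ---------------------------------------------------------------------------

def straggling_sigma_mm(
    total_range_mm: float, sigmaE_rel: float = 0.0, p: float = 1.84,
    extra_mm: float = 0.0,
) -> float:
    """Total range-straggling sigma in mm.

    Combines in quadrature: intrinsic straggling over the total
    water-equivalent path, the range spread from the relative beam energy
    spread (dR = p*R*sigmaE/E), and any extra contribution.
    """
    s_mono = 10.0 * STRAGGLE_K * (total_range_mm / 10.0) ** STRAGGLE_P
    s_espread = p * total_range_mm * sigmaE_rel
    return float(np.sqrt(s_mono**2 + s_espread**2 + extra_mm**2))


def _bortfeld_raw(z_mm, range_mm, sigma_mm, p, alpha_mm):
    """Bortfeld depth dose (arbitrary units); stable for all depths."""
    z = np.asarray(z_mm, float) / 10.0
    R = range_mm / 10.0
    sig = max(sigma_mm / 10.0, 1e-4)
    alpha = alpha_mm / 10.0
    norm = 1.0 / (p * alpha ** (1 / p) * (1 + BETA_CM * R))
    coef = BETA_CM / p + GAMMA_NUC * BETA_CM + EPS_TAIL * p / R

    zeta = (R - z) / sig
    D = np.zeros_like(z)

    far = zeta > 8.0  # asymptote: unstraggled closed form
    if np.any(far):
        u = R - z[far]
        D[far] = norm * (u ** (1 / p - 1) + coef * p * u ** (1 / p))
    near = ~far
    if np.any(near):
        zt = zeta[near]
        pre = np.exp(-(zt**2) / 4) * sig ** (1 / p) * _gamma(1 / p) / np.sqrt(2 * np.pi) * norm
        Dn = pre * (pbdv(-1 / p, -zt)[0] / sig + coef * pbdv(-1 / p - 1, -zt)[0])
        D[near] = np.where(np.isfinite(Dn) & (Dn > 0), Dn, 0.0)
    return D


def _distal_level_depth(z, dose, level_frac):
    """Depth where the distal edge crosses level_frac of the curve maximum."""
    i = int(np.argmax(dose))
    target = level_frac * dose[i]
    tail = dose[i:]
    below = np.nonzero(tail <= target)[0]
    if below.size == 0:
        raise PhysicsError("profile never falls below the requested level")
    j = below[0] + i
    return float(np.interp(target, [dose[j], dose[j - 1]], [z[j], z[j - 1]]))


@dataclass(frozen=True)
class PristineCurve:
    """Sampled depth dose of one energy layer in water.

    ``range_water`` is the depth of the distal 80% dose point; the stored
    interpolator covers depths up to range + several sigma.
    """

    energy: float
    range_water: float
    sigma_straggle: float
    depth_grid: np.ndarray
    dose: np.ndarray
    degrader_wet: float = 0.0

    def __call__(self, depth_mm):
        return np.interp(np.asarray(depth_mm, float), self.depth_grid, self.dose,
                         left=self.dose[0], right=0.0)

    @property
    def peak_depth(self) -> float:
        return float(self.depth_grid[int(np.argmax(self.dose))])

    @property
    def peak_dose(self) -> float:
        return float(self.dose.max())


def pristine_depth_dose(
    energy_mev: float,
    model: RangeEnergyModel,
    sigmaE_rel: float = 5e-4,
    extra_straggle_mm: float = 0.0,
    grid_mm: np.ndarray | None = None,
    degrader_wet_mm: float = 0.0,
) -> PristineCurve:
    """Analytical Bragg curve for one beam energy, optionally degraded.

    A degraded beam is modelled as the deep portion of the undegraded curve:
    the full-range curve (with straggling accumulated over the total
    water-equivalent path) is shifted upstream by the degrader WET, and the
    shift is calibrated so the distal 80% depth equals the residual range
    predicted by the range-energy law.
    """
    if energy_mev <= 0:
        raise PhysicsError("energy must be positive")
    full_range = float(model.range_mm(energy_mev))
    resid_range = full_range - degrader_wet_mm
    if resid_range <= 0:
        raise PhysicsError(
            f"degrader WET {degrader_wet_mm} mm exhausts the "
            f"{full_range:.1f} mm range"
        )
    sigma = straggling_sigma_mm(
        full_range, sigmaE_rel=sigmaE_rel, p=model.p, extra_mm=extra_straggle_mm
    )
    if grid_mm is None:
        grid_mm = np.arange(0.0, resid_range + 8 * sigma + 2.0, 0.05)
    grid_mm = np.asarray(grid_mm, float)
    if grid_mm.size == 0:
        raise PhysicsError("empty depth grid")
    if np.any(np.diff(grid_mm) <= 0):
        raise PhysicsError("depth grid must be strictly increasing")

    zfine = np.arange(0.0, full_range + 8 * sigma + 2.0, 0.02)
    dfull = _bortfeld_raw(zfine, full_range, sigma, model.p, model.alpha)
    # calibrate: distal 80% of the shifted curve == residual range
    d80 = _distal_level_depth(zfine, dfull, 0.8)
    shift = d80 - resid_range
    dose = np.interp(grid_mm + shift, zfine, dfull, left=dfull[0], right=0.0)
    return PristineCurve(
        energy=energy_mev,
        range_water=resid_range,
        sigma_straggle=sigma,
        depth_grid=grid_mm,
        dose=dose,
        degrader_wet=degrader_wet_mm,
    )


# ---------------------------------------------------------------------------
# Multiple Coulomb scattering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AngularSpread:
    """Plane-projected RMS multiple-scattering angle of a slab traversal."""

    sigma_theta: float  # rad
    material: MaterialSpec
    path_length: float  # mm
    energy_in: float
    energy_out: float


def highland_sigma(
    material: MaterialSpec,
    thickness_mm: float,
    energy_in_mev: float,
    model: RangeEnergyModel,
    max_step_mm: float = 1.0,
) -> AngularSpread:
    """Highland/Lynch-Dahl scattering angle of a slab, with energy loss.

    Slabs are internally subdivided (default 1 mm steps; anything above is
    integrated piecewise) and the local angle uses the local energy; the
    logarithmic correction is evaluated once on the full slab thickness, as
    recommended for composite absorbers.
    """
    if thickness_mm < 0:
        raise PhysicsError("thickness must be non-negative")
    if thickness_mm == 0:
        return AngularSpread(0.0, material, 0.0, energy_in_mev, energy_in_mev)
    x0_mm = material.radiation_length_mm
    range_w = float(model.range_mm(energy_in_mev))
    wet = water_equivalent_thickness(material, thickness_mm)
    if wet >= range_w:
        raise PhysicsError("beam stops inside the slab")
    n = max(1, int(np.ceil(thickness_mm / max_step_mm)))
    edges = np.linspace(0.0, thickness_mm, n + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    resid = range_w - material.wer * mids  # residual water range at sub-slab
    e_mid = model.energy_mev(resid)
    pv = proton_pv(e_mid)
    log_corr = 1.0 + 0.038 * np.log(thickness_mm / x0_mm)
    log_corr = max(log_corr, 0.25)
    dtheta2 = (13.6 / pv) ** 2 * (np.diff(edges) / x0_mm) * log_corr**2
    sigma = float(np.sqrt(dtheta2.sum()))
    e_out = float(model.energy_mev(range_w - wet))
    return AngularSpread(sigma, material, thickness_mm, energy_in_mev, e_out)


def scattering_power(
    material: MaterialSpec,
    depth_in_slab_mm: np.ndarray,
    total_thickness_mm: float,
    energy_in_mev: float,
    model: RangeEnergyModel,
) -> np.ndarray:
    """d<theta^2>/dx (rad^2/mm) at given depths inside a slab traversal."""
    x0_mm = material.radiation_length_mm
    range_w = float(model.range_mm(energy_in_mev))
    resid = range_w - material.wer * np.asarray(depth_in_slab_mm, float)
    if np.any(resid <= 0):
        raise PhysicsError("beam stops inside the slab")
    pv = proton_pv(model.energy_mev(resid))
    log_corr = max(1.0 + 0.038 * np.log(max(total_thickness_mm, 1e-3) / x0_mm), 0.25)
    return (13.6 / pv) ** 2 / x0_mm * log_corr**2


def lateral_mcs_sigma_water(
    depth_mm: np.ndarray, range_water_mm: float, model: RangeEnergyModel
) -> np.ndarray:
    """In-phantom lateral spread (mm, 1 sigma) at each depth in water.

    Fermi-Eyges A2 moment of the accumulated multiple Coulomb scattering,
    sigma^2(z) = int_0^z T(u) (z-u)^2 du with T the scattering power.
    """
    z = np.asarray(depth_mm, float)
    zmax = min(z.max() if z.size else 0.0, range_water_mm - 0.3)
    if zmax <= 0:
        return np.zeros_like(z)
    grid = np.linspace(0.0, zmax, 200)
    water_x0_mm = 10.0 * 36.08 / 1.0
    resid = np.clip(range_water_mm - grid, 0.3, None)
    pv = proton_pv(model.energy_mev(resid))
    log_corr = max(1.0 + 0.038 * np.log(max(zmax, 1e-3) / water_x0_mm), 0.25)
    T = (13.6 / pv) ** 2 / water_x0_mm * log_corr**2
    out = np.zeros_like(z)
    for i, zi in enumerate(z):
        m = grid <= min(zi, zmax)
        if m.sum() > 1:
            out[i] = np.sqrt(np.trapezoid(T[m] * (zi - grid[m]) ** 2, grid[m]))
    return out


def export_curve_csv(curve: PristineCurve, path) -> None:
    """Write a two-column depth/dose comma-separated table."""
    np.savetxt(
        path,
        np.column_stack([curve.depth_grid, curve.dose]),
        delimiter=",",
        header="depth_mm,dose_rel",
        comments="",
    )
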