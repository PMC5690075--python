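"""Derived observables: FWHM, lateral penumbra, transverse uniformity,
SOBP width/falloff/entrance ratio, and per-structure cumulative DVHs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .eye import LabeledGrid


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class Profile:
    """A sampled 1-D dose profile along depth, Y or Z."""

    coordinate: np.ndarray  # mm, strictly increasing
    value: np.ndarray  # relative dose, >= 0
    axis: str = "Y"

    def __post_init__(self):
        c = np.asarray(self.coordinate, float)
        v = np.asarray(self.value, float)
        if np.any(np.diff(c) <= 0):
            raise MetricError("profile coordinates must be strictly increasing")
        if np.any(v < 0):
            raise MetricError("profile values must be non-negative")
        object.__setattr__(self, "coordinate", c)
        object.__setattr__(self, "value", v)

    def central_value(self) -> float:
        """Value at coordinate 0 (interpolated)."""
        return float(np.interp(0.0, self.coordinate, self.value))


def _cross_up(x, v, level, strict: bool = False):
    """First upward crossing of `level`, scanning from the left."""
    above = np.nonzero(v >= level)[0]
    if above.size == 0:
        raise MetricError("profile never reaches the requested level")
    i = above[0]
    if i == 0:
        if strict:
            raise MetricError("profile does not cross the level on this side")
        return float(x[0])
    return float(np.interp(level, [v[i - 1], v[i]], [x[i - 1], x[i]]))


def _cross_down(x, v, level, strict: bool = False):
    """Last downward crossing of `level`, scanning from the right."""
    above = np.nonzero(v >= level)[0]
    if above.size == 0:
        raise MetricError("profile never reaches the requested level")
    i = above[-1]
    if i == len(v) - 1:
        if strict:
            raise MetricError("profile does not cross the level on this side")
        return float(x[-1])
    return float(np.interp(level, [v[i + 1], v[i]], [x[i + 1], x[i]]))


def fwhm(profile: Profile) -> float:
    """Linear-interpolated full width at half maximum."""
    v = profile.value
    x = profile.coordinate
    half = v.max() / 2.0
    if v[0] >= half or v[-1] >= half:
        raise MetricError("profile does not fall below half maximum at the edges")
    return _cross_down(x, v, half) - _cross_up(x, v, half)


def penumbra_80_20(profile: Profile, side: str = "right") -> float:
    """Lateral 80%-20% falloff distance relative to the central value."""
    c = profile.central_value()
    if c <= 0:
        raise MetricError("central value is zero")
    x, v = profile.coordinate, profile.value
    try:
        if side == "right":
            x80 = _cross_down(x, v, 0.8 * c, strict=True)
            x20 = _cross_down(x, v, 0.2 * c, strict=True)
            return x20 - x80
        if side == "left":
            x80 = _cross_up(x, v, 0.8 * c, strict=True)
            x20 = _cross_up(x, v, 0.2 * c, strict=True)
            return x80 - x20
    except MetricError as err:
        raise MetricError(f"undefined penumbra: {err}") from err
    raise ValueError("side must be 'left' or 'right'")


def transverse_uniformity(
    profile: Profile,
    method: str = "gaussian_fit",
    region_level: float = 0.8,
) -> float:
    """Percent dose spread over the plateau region (value >= 80% of central).

    The film-style readout distributes the plateau values "in a Gaussian
    shape"; the default estimator therefore fits a Gaussian to the histogram
    of the in-region values and reports 2 sigma / mu in percent, which is
    robust against the deterministic shoulder at the region border.
    Alternatives: ``"std"`` (plain 2*std/mean) and ``"range"``
    ((max-min)/(max+min)).
    """
    c = profile.central_value()
    if c <= 0:
        raise MetricError("central value is zero")
    vals = profile.value[profile.value >= region_level * c] / c * 100.0
    if vals.size < 3:
        raise MetricError("empty plateau region")
    if method == "range":
        return float(
            100.0 * (vals.max() - vals.min()) / (vals.max() + vals.min())
        )
    if method == "std":
        return float(200.0 * vals.std() / vals.mean())
    if method != "gaussian_fit":
        raise ValueError(f"unknown uniformity method {method!r}")

    if np.ptp(vals) < 1e-9:
        return 0.0
    med = np.median(vals)
    mad = np.median(np.abs(vals - med)) * 1.4826
    width = max(mad, np.ptp(vals) / 40.0, 1e-3)
    bins = np.linspace(vals.min() - width, vals.max() + width, 41)
    hist, edges = np.histogram(vals, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def gauss(x, a, mu, sig):
        return a * np.exp(-((x - mu) ** 2) / (2 * sig**2))

    try:
        popt, _ = curve_fit(
            gauss,
            centers,
            hist,
            p0=[hist.max(), med, max(mad, width)],
            bounds=([0.0, vals.min(), 1e-3], [np.inf, vals.max() + 1, np.ptp(vals) + 1]),
            maxfev=5000,
        )
        mu, sig = popt[1], abs(popt[2])
    except RuntimeError:  # fit failed: fall back to the robust moments
        mu, sig = med, max(mad, width)
    return float(200.0 * sig / mu)


@dataclass(frozen=True)
class SOBPMetrics:
    width: float
    distal_falloff_80_20: float
    entrance_plateau_ratio: float  # percent
    flatness: float  # percent
    plateau_dose: float

    def __post_init__(self):
        if self.width <= self.distal_falloff_80_20:
            raise MetricError("SOBP width must exceed its distal falloff")


def sobp_metrics(depth_profile: Profile, width_level: float = 0.95) -> SOBPMetrics:
    """Width, distal falloff, entrance/plateau ratio and flatness of a SOBP.

    The plateau dose is the mean of the samples above 90% of the profile
    maximum; the width spans the outermost crossings of ``width_level`` times
    the plateau; the distal falloff is the 80%-to-20%-of-plateau distance
    beyond the distal edge; flatness is (max-min)/(max+min) over the central
    80% of the span between the width crossings (field-core convention).
    """
    z, v = depth_profile.coordinate, depth_profile.value
    plateau = float(v[v >= 0.9 * v.max()].mean())
    lvl = width_level * plateau
    z_prox = _cross_up(z, v, lvl)
    z_dist = _cross_down(z, v, lvl)
    margin = 0.1 * (z_dist - z_prox)
    inside = (z >= z_prox + margin) & (z <= z_dist - margin)
    vin = v[inside]
    flat = 100.0 * (vin.max() - vin.min()) / (vin.max() + vin.min())
    z80 = _cross_down(z, v, 0.8 * plateau)
    z20 = _cross_down(z, v, 0.2 * plateau)
    return SOBPMetrics(
        width=z_dist - z_prox,
        distal_falloff_80_20=z20 - z80,
        entrance_plateau_ratio=100.0 * float(v[0]) / plateau,
        flatness=flat,
        plateau_dose=plateau,
    )


@dataclass(frozen=True)
class DVHCurve:
    """Cumulative dose-volume histogram of one structure."""

    structure: str
    thresholds: np.ndarray
    volume_fraction: np.ndarray  # percent

    def fraction_at(self, threshold: float) -> float:
        return float(
            np.interp(threshold, self.thresholds, self.volume_fraction)
        )


def dvh(
    dose,
    labels: LabeledGrid | None = None,
    n_bins: int = 400,
    structures=None,
) -> list[DVHCurve]:
    """Cumulative volume-fraction-above-threshold per structure.

    ``dose`` may be a DoseGrid (labels taken from it) or a plain array with
    an explicit LabeledGrid.
    """
    from .delivery import DoseGrid

    if isinstance(dose, DoseGrid):
        grid = dose.grid
        arr = dose.dose
    else:
        arr = np.asarray(dose)
        grid = labels
    if grid is None:
        raise MetricError("need structure labels")
    if arr.shape != grid.labels.shape:
        raise MetricError("dose and label grids have different geometry")
    thresholds = np.linspace(0.0, float(arr.max()), n_bins)
    out = []
    names = structures or grid.structure_names()
    for name in names:
        m = grid.mask(name)
        n = int(m.sum())
        if n == 0:
            continue
        vals = np.sort(arr[m])
        # fraction of voxels with dose >= t
        frac = 100.0 * (n - np.searchsorted(vals, thresholds, side="left")) / n
        frac[0] = 100.0
        out.append(DVHCurve(name, thresholds, frac))
    return out


def coverage_level(curve: DVHCurve, coverage_pct: float = 100.0) -> float:
    """Highest threshold at which the structure still keeps the requested
    cumulative volume fraction (e.g. the 100%-coverage iso-level)."""
    ok = curve.volume_fraction >= coverage_pct - 1e-9
    if not ok.any():
        raise MetricError("structure never reaches the requested coverage")
    return float(curve.thresholds[np.nonzero(ok)[0][-1]])


def export_dvh_csv(curves, path_prefix: str) -> None:
    for c in curves:
        np.savetxt(
            f"{path_prefix}_{c.structure}.csv",
            np.column_stack([c.thresholds, c.volume_fraction]),
            delimiter=",",
            header="threshold,volume_fraction_pct",
            comments="",
        )
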