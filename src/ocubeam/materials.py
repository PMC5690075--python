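"""Material definitions for the beamline and the eye phantom.

Every material is described by elemental mass fractions, a density and a
radiation length; the water-equivalent ratio (WER) used by the dose engine is
either derived from the composition (relative stopping power approximated by
density times the Z/A ratio relative to water, ignoring the mean-excitation
correction) or set explicitly where a calibrated value is required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import yaml

# Elemental constants: atomic number Z, standard atomic weight A (g/mol) and
# radiation length X0 (g/cm^2).
ELEMENTS: dict[str, tuple[int, float, float]] = {
    "H": (1, 1.008, 63.04),
    "C": (6, 12.011, 42.70),
    "N": (7, 14.007, 37.99),
    "O": (8, 15.999, 34.24),
    "Na": (11, 22.990, 27.74),
    "P": (15, 30.974, 21.21),
    "S": (16, 32.06, 19.50),
    "Cl": (17, 35.45, 19.28),
    "Al": (13, 26.982, 24.01),
    "Cu": (29, 63.546, 12.86),
    "Zn": (30, 65.38, 12.43),
    "Pb": (82, 207.2, 6.37),
}




class MaterialError(ValueError):
    """Invalid material definition."""


def formula_mass_fractions(formula: dict[str, float]) -> dict[str, float]:
    """Elemental mass fractions of a stoichiometric formula {element: count}."""
    masses = {}
    for el, n in formula.items():
        if el not in ELEMENTS:
            raise MaterialError(f"unknown element {el!r}")
        masses[el] = n * ELEMENTS[el][1]
    total = sum(masses.values())
    return {el: m / total for el, m in masses.items()}


def _check_normalized(fractions: dict[str, float], name: str) -> dict[str, float]:
    s = sum(fractions.values())
    if abs(s - 1.0) > 1e-9:
        warnings.warn(
            f"mass fractions of {name!r} sum to {s:.6f}; renormalizing",
            stacklevel=3,
        )
        fractions = {k: v / s for k, v in fractions.items()}
    return fractions


def mix_mass_fractions(
    components: dict[str, float],
    resolved: dict[str, dict[str, float]],
    name: str = "mixture",
) -> dict[str, float]:
    """Combine component elemental fractions weighted by mass fraction."""
    components = _check_normalized(components, name)
    out: dict[str, float] = {}
    for comp, w in components.items():
        if comp not in resolved:
            raise MaterialError(f"unknown component {comp!r} in {name!r}")
        for el, f in resolved[comp].items():
            out[el] = out.get(el, 0.0) + w * f
    return out


def za_ratio(composition: dict[str, float]) -> float:
    """Mean Z/A of an elemental mass-fraction map."""
    return sum(w * ELEMENTS[el][0] / ELEMENTS[el][1] for el, w in composition.items())


_ZA_WATER = za_ratio(formula_mass_fractions({"H": 2, "O": 1}))


def radiation_length(composition: dict[str, float]) -> float:
    """Radiation length of a mixture in g/cm^2 (Bragg additivity)."""
    inv = sum(w / ELEMENTS[el][2] for el, w in composition.items())
    return 1.0 / inv


@dataclass(frozen=True)
class MaterialSpec:
    """A slab material as seen by the proton beam.

    Attributes
    ----------
    name : str
    density : float
        g/cm^3.
    composition : dict
        Elemental mass fractions, summing to 1.
    radiation_length : float
        g/cm^2.
    wer : float
        Water-equivalent ratio, mm water per mm of material.
    """

    name: str
    density: float
    composition: dict[str, float]
    radiation_length: float = field(default=0.0)
    wer: float = field(default=0.0)

    def __post_init__(self):
        if self.density <= 0:
            raise MaterialError(f"{self.name}: density must be positive")
        s = sum(self.composition.values())
        if abs(s - 1.0) > 1e-9:
            raise MaterialError(f"{self.name}: mass fractions sum to {s}")
        if self.radiation_length == 0.0:
            object.__setattr__(
                self, "radiation_length", radiation_length(self.composition)
            )
        if self.wer == 0.0:
            object.__setattr__(self, "wer", stopping_power_ratio(self))
        if self.wer <= 0:
            raise MaterialError(f"{self.name}: WER must be positive")

    @property
    def radiation_length_mm(self) -> float:
        """Radiation length in mm of material."""
        return 10.0 * self.radiation_length / self.density


def stopping_power_ratio(material: MaterialSpec) -> float:
    """Approximate relative stopping power (water-equivalent ratio).

    rho * (Z/A)_material / (Z/A)_water; the logarithmic mean-excitation term is
    ignored, which is adequate at the few-percent level for tissue-like media.
    """
    return material.density * za_ratio(material.composition) / _ZA_WATER


def make_material(
    name: str,
    density: float,
    formula: dict[str, float] | None = None,
    mass_fractions: dict[str, float] | None = None,
    wer: float | None = None,
) -> MaterialSpec:
    if formula is not None:
        comp = formula_mass_fractions(formula)
    elif mass_fractions is not None:
        comp = _check_normalized(dict(mass_fractions), name)
    else:
        raise MaterialError("need formula or mass_fractions")
    return MaterialSpec(name, density, comp, wer=(wer or 0.0))


# PMMA water-equivalent ratio calibrated from the CNAO range measurements:
# the 100.51 MeV beam range in water (74.00 mm, power-law fit) minus its
# residual range behind the 43 mm shifter (35.50 mm) gives a WET of ~38.2 mm,
# i.e. WER ~0.888.  The physically standard value (~1.16 from the composition)
# is available via ``beamline_materials(pmma_wer="physical")``.
PMMA_WER_CALIBRATED = 0.888


def beamline_materials(pmma_wer: float | str = PMMA_WER_CALIBRATED) -> dict[str, MaterialSpec]:
    """The stock materials of the transport line.

    Parameters
    ----------
    pmma_wer : float or "physical"
        Water-equivalent ratio assigned to the PMMA range shifter.  The
        default is the value calibrated on the measured residual ranges;
        ``"physical"`` selects the composition-derived stopping-power ratio.
    """
    mats = {
        "water": make_material("water", 1.0, formula={"H": 2, "O": 1}),
        "pmma": make_material(
            "pmma",
            1.19,
            formula={"C": 5, "H": 8, "O": 2},
            wer=None if pmma_wer == "physical" else float(pmma_wer),
        ),
        "mylar": make_material("mylar", 1.40, formula={"C": 10, "H": 8, "O": 4}),
        "kapton": make_material(
            "kapton", 1.42, formula={"C": 22, "H": 10, "N": 2, "O": 5}
        ),
        "aluminum": make_material("aluminum", 2.699, formula={"Al": 1}),
        "copper": make_material("copper", 8.96, formula={"Cu": 1}),
        # brass alloy used for the patient collimator
        "brass": make_material(
            "brass", 8.52, mass_fractions={"Cu": 0.615, "Zn": 0.352, "Pb": 0.033}
        ),
        "carbon_fiber": make_material("carbon_fiber", 1.78, formula={"C": 1}),
        "nitrogen": make_material("nitrogen", 1.1653e-3, formula={"N": 2}),
        "air": make_material(
            "air",
            1.2048e-3,
            mass_fractions={"N": 0.7556, "O": 0.2315, "C": 0.0001 + 0.0128},
        ),
    }
    return mats


# ---------------------------------------------------------------------------
# Eye-tissue chemistry: elementary mixtures and component tissues.
# ---------------------------------------------------------------------------

#: The ten elementary mixtures used to compose the ocular tissues.  Formulas
#: are stoichiometric; percentage recipes are mass fractions.  Each carries a
#: default density of 1 g/cm^3.
ELEMENTARY_MIXTURES: dict[str, dict] = {
    "proline": {"formula": {"H": 9, "C": 5, "O": 2, "N": 1}},
    "idrossiproline": {"formula": {"H": 9, "C": 5, "O": 3, "N": 1}},
    "collagen": {"mixture": {"proline": 0.86, "idrossiproline": 0.14}},
    "lipids": {"formula": {"H": 48, "C": 24, "O": 6, "P": 1, "N": 2}},
    "lactate": {"formula": {"H": 5, "C": 3, "O": 2}},
    "sugar": {"formula": {"H": 2, "C": 1, "O": 1}},
    "naa": {"formula": {"H": 9, "C": 6, "O": 5, "N": 1}},
    "choline": {"formula": {"H": 14, "C": 5, "O": 1, "N": 1}},
    "creatine": {"formula": {"H": 9, "C": 4, "O": 2, "N": 3}},
    "protein": {"mass_fractions": {"H": 0.50, "C": 0.28, "O": 0.13, "N": 0.08, "S": 0.01}},
    "h2o": {"formula": {"H": 2, "O": 1}},
    "nacl": {"formula": {"Na": 1, "Cl": 1}},
}

#: Component tissues: recipe (mass fractions of elementary mixtures) and the
#: density assigned in the simulation.
TISSUE_RECIPES: dict[str, dict] = {
    "aqueous_humor": {"recipe": {"h2o": 0.985, "nacl": 0.015}, "density": 1.0080},
    "vitreous_humor": {"recipe": {"h2o": 0.985, "protein": 0.015}, "density": 1.0050},
    "sclera": {
        "recipe": {"collagen": 0.50, "protein": 0.25, "sugar": 0.25},
        "density": 1.0710,
    },
    "lens": {"recipe": {"h2o": 0.60, "protein": 0.40}, "density": 1.0670},
    "retina": {
        "recipe": {"h2o": 0.80, "naa": 0.10, "choline": 0.05, "creatine": 0.05},
        "density": 1.0174,
    },
    "tumor": {
        "recipe": {
            "h2o": 0.80,
            "naa": 0.03,
            "choline": 0.12,
            "creatine": 0.03,
            "lipids": 0.01,
            "lactate": 0.01,
        },
        "density": 1.0174,
    },
}

# cornea and ciliary body share the scleral collagen recipe; the optic nerve
# (not listed in the component table) is assigned the retinal nervous-tissue
# recipe
TISSUE_ALIASES = {"cornea": "sclera", "ciliary_body": "sclera", "optic_nerve": "retina"}


@dataclass(frozen=True)
class TissueMaterial:
    """A resolved ocular tissue: recipe, density, elemental fractions, WER."""

    component: str
    recipe: dict[str, float]
    density: float
    composition: dict[str, float]
    wer: float

    def as_material(self) -> MaterialSpec:
        return MaterialSpec(self.component, self.density, self.composition, wer=self.wer)


def resolve_mixture(name: str) -> dict[str, float]:
    """Elemental mass fractions of one elementary mixture, resolved recursively."""
    spec = ELEMENTARY_MIXTURES[name]
    if "formula" in spec:
        return formula_mass_fractions(spec["formula"])
    if "mass_fractions" in spec:
        return _check_normalized(dict(spec["mass_fractions"]), name)
    resolved = {k: resolve_mixture(k) for k in spec["mixture"]}
    return mix_mass_fractions(spec["mixture"], resolved, name)


def material_wer(tissue: TissueMaterial) -> float:
    """Water-equivalent ratio of a tissue from its resolved composition."""
    return stopping_power_ratio(tissue.as_material())


def make_materials() -> list[TissueMaterial]:
    """Build the six stock ocular tissues (plus cornea/ciliary aliases)."""
    out = []
    names = list(TISSUE_RECIPES) + list(TISSUE_ALIASES)
    for name in names:
        base = TISSUE_RECIPES[TISSUE_ALIASES.get(name, name)]
        mixtures = {k: resolve_mixture(k) for k in base["recipe"]}
        comp = mix_mass_fractions(base["recipe"], mixtures, name)
        t = TissueMaterial(name, dict(base["recipe"]), base["density"], comp, wer=0.0)
        object.__setattr__(t, "wer", material_wer(t))
        out.append(t)
    return out


def tissue_table() -> dict[str, TissueMaterial]:
    return {t.component: t for t in make_materials()}


# ---------------------------------------------------------------------------
# Plain-text (YAML) material configs
# ---------------------------------------------------------------------------

def load_materials(path) -> dict[str, MaterialSpec]:
    """Load extra material definitions from a YAML config.

    Each entry: ``name: {density: g/cm3, mass_fractions: {el: f}, wer: optional}``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out = {}
    for name, spec in raw.items():
        out[name] = make_material(
            name,
            float(spec["density"]),
            formula=spec.get("formula"),
            mass_fractions=spec.get("mass_fractions"),
            wer=spec.get("wer"),
        )
    return out


def save_materials(materials: dict[str, MaterialSpec], path) -> None:
    data = {
        m.name: {
            "density": m.density,
            "mass_fractions": m.composition,
            "wer": m.wer,
        }
        for m in materials.values()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
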