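"""Target-material definitions.

A :class:`Material` is an "average molecule" description of an element,
compound or molar mixture: number density, electron shells (ionisation
potential + occupancy) and, per shell, the nine-parameter fit set used by
the secondary-electron production cross-section model.

Shell data policy
-----------------
* Compounds with bundled molecular shell data (H2O, CO2, CH4, H2, O2) use it.
* Compounds with only a known molecular ionisation potential pool their
  valence electrons into one outer shell at that potential.
* Anything else decomposes into constituent atoms: the outermost shell uses
  the element's first ionisation potential, inner shells use X-ray binding
  energies (bundled for Z <= 36, screened-hydrogenic estimate beyond).
  This fallback can overestimate cross sections and emits a log warning.

Parameter-set policy (noble-gas analogy)
----------------------------------------
The outermost shell of an atom maps to the noble gas whose outermost shell
has the same principal quantum number (K -> He, L -> Ne, M -> Ar, N -> Kr);
all non-outermost shells use the generic inner-shell set.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace

from .constants import N_AVOGADRO

logger = logging.getLogger(__name__)

__all__ = [
    "RuddParameterSet",
    "ElectronShell",
    "Material",
    "PARAMETER_SETS",
    "load_material",
    "material_to_config",
    "assign_rudd_parameters",
    "mass_to_molar_fractions",
    "water",
    "teg",
    "helium",
]


# --------------------------------------------------------------------------
# parameter sets
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RuddParameterSet:
    """Nine fit parameters (plus cutoff slope ``alpha``) of the proton-impact
    singly-differential ionisation cross-section model, one set per target
    species / shell class."""

    id: str
    A1: float
    B1: float
    C1: float
    D1: float
    E1: float
    A2: float
    B2: float
    C2: float
    D2: float
    alpha: float = 0.66


#: Fit-parameter table transcribed from the published per-target fits.
#: ``inner`` is the generic any-shell set used for non-outermost shells.
PARAMETER_SETS: dict[str, RuddParameterSet] = {
    "H2": RuddParameterSet("H2", 0.96, 2.6, 0.38, 0.23, 2.2, 1.04, 5.9, 1.15, 0.20, 0.87),
    "He": RuddParameterSet("He", 1.02, 2.4, 0.70, 1.15, 0.70, 0.84, 6.0, 1.00, 1.19, 0.86),
    "Ne": RuddParameterSet("Ne", 1.02, 4.2, 0.20, 0.15, 2.7, 1.07, 14.5, 1.15, 0.34, 0.60),
    "Ar": RuddParameterSet("Ar", 1.04, 6.3, 0.65, 0.93, 0.48, 1.32, 12.6, 0.95, 0.59, 0.75),
    "Kr": RuddParameterSet("Kr", 1.01, 8.2, 0.94, 1.29, 0.38, 1.42, 14.1, 0.95, 0.60, 0.70),
    "H2O": RuddParameterSet("H2O", 0.97, 82.0, 0.40, -0.30, 0.38, 1.04, 17.3, 0.76, 0.04, 0.64),
    "O2": RuddParameterSet("O2", 1.10, 11.1, 0.40, 0.00, 1.10, 1.11, 13.1, 0.79, 0.01, 0.88),
    "CO2": RuddParameterSet("CO2", 1.00, 40.0, 0.60, -0.10, 0.50, 1.07, 15.0, 0.80, 0.05, 0.75),
    "CH4": RuddParameterSet("CH4", 1.02, 5.0, 0.66, 0.20, 1.20, 1.07, 12.8, 1.00, 0.18, 0.75),
    "inner": RuddParameterSet("inner", 1.25, 0.50, 1.00, 1.00, 3.00, 1.10, 1.30, 1.00, 0.00, 0.66),
}

#: Noble-gas analog for the outermost shell, keyed by principal quantum number.
_NOBLE_ANALOG = {1: "He", 2: "Ne", 3: "Ar", 4: "Kr"}


@dataclass(frozen=True)
class ElectronShell:
    """One electron shell (or molecular orbital) of the target molecule."""

    label: str
    ionisation_potential: float  # eV
    occupancy: int               # electrons per molecule (or per atom)
    parameter_set: RuddParameterSet

    def __post_init__(self):
        if self.ionisation_potential <= 0:
            raise ValueError(f"shell {self.label}: ionisation potential must be > 0")
        if self.occupancy < 1 or int(self.occupancy) != self.occupancy:
            raise ValueError(f"shell {self.label}: occupancy must be a positive integer")


# --------------------------------------------------------------------------
# element data (Z <= 36 bundled)
# --------------------------------------------------------------------------

# symbol: (Z, atomic mass [g/mol], first ionisation potential [eV])
_ELEMENTS: dict[str, tuple[int, float, float]] = {
    "H": (1, 1.008, 13.598), "He": (2, 4.0026, 24.587),
    "Li": (3, 6.94, 5.392), "Be": (4, 9.0122, 9.323), "B": (5, 10.81, 8.298),
    "C": (6, 12.011, 11.260), "N": (7, 14.007, 14.534), "O": (8, 15.999, 13.618),
    "F": (9, 18.998, 17.423), "Ne": (10, 20.180, 21.565),
    "Na": (11, 22.990, 5.139), "Mg": (12, 24.305, 7.646), "Al": (13, 26.982, 5.986),
    "Si": (14, 28.085, 8.152), "P": (15, 30.974, 10.487), "S": (16, 32.06, 10.360),
    "Cl": (17, 35.45, 12.968), "Ar": (18, 39.948, 15.760),
    "K": (19, 39.098, 4.341), "Ca": (20, 40.078, 6.113), "Sc": (21, 44.956, 6.561),
    "Ti": (22, 47.867, 6.828), "V": (23, 50.942, 6.746), "Cr": (24, 51.996, 6.767),
    "Mn": (25, 54.938, 7.434), "Fe": (26, 55.845, 7.902), "Co": (27, 58.933, 7.881),
    "Ni": (28, 58.693, 7.640), "Cu": (29, 63.546, 7.726), "Zn": (30, 65.38, 9.394),
    "Ga": (31, 69.723, 5.999), "Ge": (32, 72.63, 7.899), "As": (33, 74.922, 9.789),
    "Se": (34, 78.971, 9.752), "Br": (35, 79.904, 11.814), "Kr": (36, 83.798, 13.9996),
}

# Inner-shell binding energies [eV] per principal shell (K=1, L=2, M=3),
# representative (outer-subshell) values; inner contributions scale as the
# inverse cube of the potential so coarse values suffice.
_INNER_BINDING: dict[str, dict[int, float]] = {
    "Li": {1: 54.7}, "Be": {1: 111.5}, "B": {1: 188.0}, "C": {1: 284.2},
    "N": {1: 409.9}, "O": {1: 543.1}, "F": {1: 696.7}, "Ne": {1: 870.2},
    "Na": {1: 1070.8, 2: 30.8}, "Mg": {1: 1303.0, 2: 49.8},
    "Al": {1: 1559.6, 2: 72.7}, "Si": {1: 1839.0, 2: 99.4},
    "P": {1: 2145.5, 2: 135.0}, "S": {1: 2472.0, 2: 162.5},
    "Cl": {1: 2822.4, 2: 200.0}, "Ar": {1: 3205.9, 2: 248.4},
    "K": {1: 3608.4, 2: 294.6, 3: 18.3}, "Ca": {1: 4038.5, 2: 346.2, 3: 25.4},
    "Sc": {1: 4492.0, 2: 398.7, 3: 28.3}, "Ti": {1: 4966.0, 2: 453.8, 3: 32.6},
    "V": {1: 5465.0, 2: 512.1, 3: 37.2}, "Cr": {1: 5989.0, 2: 574.1, 3: 42.2},
    "Mn": {1: 6539.0, 2: 638.7, 3: 47.2}, "Fe": {1: 7112.0, 2: 706.8, 3: 52.7},
    "Co": {1: 7709.0, 2: 778.1, 3: 58.9}, "Ni": {1: 8333.0, 2: 852.7, 3: 66.2},
    "Cu": {1: 8979.0, 2: 932.5, 3: 75.1}, "Zn": {1: 9659.0, 2: 1021.8, 3: 88.6},
    "Ga": {1: 10367.0, 2: 1116.4, 3: 103.5}, "Ge": {1: 11103.0, 2: 1217.0, 3: 120.8},
    "As": {1: 11867.0, 2: 1323.6, 3: 140.2}, "Se": {1: 12658.0, 2: 1433.9, 3: 161.9},
    "Br": {1: 13474.0, 2: 1550.0, 3: 181.5}, "Kr": {1: 14326.0, 2: 1678.4, 3: 214.4},
}

# Madelung filling order as (n, capacity) pairs.
_FILL_ORDER = [
    (1, 2), (2, 2), (2, 6), (3, 2), (3, 6), (4, 2), (3, 10), (4, 6),
    (5, 2), (4, 10), (5, 6), (6, 2), (4, 14), (5, 10), (6, 6), (7, 2),
    (5, 14), (6, 10), (7, 6),
]

# Ground-state exceptions that move one electron between shells (by n).
_AUFBAU_EXCEPTIONS: dict[int, dict[int, int]] = {
    24: {3: 13, 4: 1},   # Cr
    29: {3: 18, 4: 1},   # Cu
    42: {4: 17, 5: 1},   # Mo
    47: {4: 18, 5: 1},   # Ag
    79: {5: 17, 6: 1},   # Au
}


def shell_occupancies(z: int) -> dict[int, int]:
    """Ground-state electron count per principal shell for atomic number ``z``."""
    occ: dict[int, int] = {}
    remaining = z
    for n, cap in _FILL_ORDER:
        if remaining <= 0:
            break
        take = min(cap, remaining)
        occ[n] = occ.get(n, 0) + take
        remaining -= take
    if z in _AUFBAU_EXCEPTIONS:
        occ.update(_AUFBAU_EXCEPTIONS[z])
    return occ


def _slater_binding(z: int, occ: dict[int, int], n: int) -> float:
    """Screened-hydrogenic binding-energy estimate [eV] for shell ``n``."""
    same = occ[n] - 1
    inner_adjacent = occ.get(n - 1, 0)
    deeper = sum(v for k, v in occ.items() if k < n - 1)
    s = (0.30 if n == 1 else 0.35) * same + 0.85 * inner_adjacent + 1.0 * deeper
    zeff = max(z - s, 1.0)
    return 13.606 * (zeff / n) ** 2


_SHELL_NAMES = {1: "K", 2: "L", 3: "M", 4: "N", 5: "O", 6: "P", 7: "Q"}


def assign_rudd_parameters(shell_n: int, species: str, *, outermost: bool) -> RuddParameterSet:
    """Pick the parameter set for a shell of an atomic species.

    Outermost shells map to the noble gas sharing the same outermost
    principal quantum number; everything else uses the inner-shell set.
    """
    if not outermost:
        return PARAMETER_SETS["inner"]
    if shell_n not in _NOBLE_ANALOG:
        raise ValueError(
            f"{species}: no noble-gas analog for outermost shell n={shell_n}; "
            "assign a parameter set explicitly via a shell override"
        )
    return PARAMETER_SETS[_NOBLE_ANALOG[shell_n]]


def element_shells(symbol: str) -> list[ElectronShell]:
    """Electron shells of a free atom (outermost at the first ionisation
    potential, inner shells at bundled/estimated binding energies)."""
    if symbol not in _ELEMENTS:
        raise ValueError(f"unknown element: {symbol!r}")
    z, _, first_ip = _ELEMENTS[symbol]
    occ = shell_occupancies(z)
    n_outer = max(occ)
    shells = []
    for n in sorted(occ):
        outer = n == n_outer
        if outer:
            eps = first_ip
        else:
            eps = _INNER_BINDING.get(symbol, {}).get(n)
            if eps is None:
                eps = _slater_binding(z, occ, n)
                logger.warning(
                    "%s shell n=%d: no bundled binding energy, using screened-"
                    "hydrogenic estimate %.1f eV", symbol, n, eps)
        pset = assign_rudd_parameters(n, symbol, outermost=outer)
        shells.append(ElectronShell(_SHELL_NAMES[n], eps, occ[n], pset))
    return shells


# --------------------------------------------------------------------------
# molecular data
# --------------------------------------------------------------------------

# (label, ionisation potential [eV], occupancy, parameter-set id)
_MOLECULAR_SHELLS: dict[str, list[tuple[str, float, int, str]]] = {
    "H2O": [("1b1", 12.61, 2, "H2O"), ("3a1", 14.73, 2, "H2O"),
            ("1b2", 18.55, 2, "H2O"), ("2a1", 32.2, 2, "H2O"),
            ("O1s", 539.7, 2, "inner")],
    "CO2": [("valence", 13.78, 16, "CO2"), ("C1s", 297.7, 2, "inner"),
            ("O1s", 541.3, 4, "inner")],
    "CH4": [("valence", 12.61, 8, "CH4"), ("C1s", 290.7, 2, "inner")],
    "H2": [("1sg", 15.43, 2, "H2")],
    "O2": [("valence", 12.07, 12, "O2"), ("O1s", 543.1, 4, "inner")],
}

# Molecular first ionisation potentials [eV] for compounds without a native
# parameter set: valence electrons are pooled at this potential.
_MOLECULAR_IP: dict[str, float] = {
    "NH3": 10.07, "NH2": 11.14, "CH3": 9.84, "C2H2": 11.40, "C2H4": 10.51,
    "C2H6": 11.52, "C6H6": 9.24, "SF6": 15.32,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an empirical formula like ``C3H8`` into element counts."""
    pos = 0
    counts: dict[str, int] = {}
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        sym, num = m.group(1), m.group(2)
        if sym not in _ELEMENTS:
            raise ValueError(f"unknown element {sym!r} in formula {formula!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def molar_mass(formula: str) -> float:
    return sum(_ELEMENTS[s][1] * k for s, k in parse_formula(formula).items())


def _valence_electrons(counts: dict[str, int]) -> tuple[int, int]:
    """(valence-electron count, principal n of the heaviest atom's valence shell)."""
    total = 0
    n_heaviest = 1
    z_max = 0
    for sym, k in counts.items():
        z = _ELEMENTS[sym][0]
        occ = shell_occupancies(z)
        n_outer = max(occ)
        total += occ[n_outer] * k
        if z > z_max:
            z_max, n_heaviest = z, n_outer
    return total, n_heaviest


def species_shells(species: str) -> list[tuple[ElectronShell, float]]:
    """Shells of one constituent species with per-molecule multiplicities.

    Returns ``[(shell, multiplicity), ...]`` where multiplicity is the number
    of copies of that shell per molecule of the species.
    """
    if species in _MOLECULAR_SHELLS:
        return [
            (ElectronShell(lbl, ip, occ, PARAMETER_SETS[pid]), 1.0)
            for lbl, ip, occ, pid in _MOLECULAR_SHELLS[species]
        ]
    counts = parse_formula(species)
    if len(counts) == 1 and next(iter(counts.values())) == 1:
        sym = next(iter(counts))
        return [(sh, 1.0) for sh in element_shells(sym)]
    if species in _MOLECULAR_IP:
        # pooled valence shell at the molecular potential + atomic inner shells
        nv, n_heavy = _valence_electrons(counts)
        pset = PARAMETER_SETS[_NOBLE_ANALOG.get(n_heavy, "Kr")]
        out = [(ElectronShell("valence", _MOLECULAR_IP[species], nv, pset), 1.0)]
        for sym, k in counts.items():
            for sh in element_shells(sym):
                if sh.parameter_set.id == "inner":
                    out.append((sh, float(k)))
        return out
    logger.warning(
        "%s: no molecular shell data; decomposing into constituent atoms "
        "(may overestimate cross sections)", species)
    out = []
    for sym, k in counts.items():
        for sh in element_shells(sym):
            out.append((sh, float(k)))
    return out


# --------------------------------------------------------------------------
# material
# --------------------------------------------------------------------------

@dataclass
class Material:
    """An average-molecule description of a target substance.

    ``shells`` carries per-shell multiplicities per *average molecule* of the
    mixture (molar fraction x per-molecule copies), so all macroscopic
    quantities are ``number_density`` x shell-weighted sums.
    """

    name: str
    constituents: list[tuple[str, float]]       # (species, molar fraction)
    mass_density: float                         # g/cm^3
    number_density: float                       # molecules/cm^3
    shells: list[tuple[ElectronShell, float]]   # (shell, weight per avg molecule)
    electron_density: float = field(init=False) # electrons/cm^3
    molar_mass: float = field(init=False)       # g/mol

    def __post_init__(self):
        if self.mass_density <= 0 or self.number_density <= 0:
            raise ValueError("densities must be positive")
        total = sum(f for _, f in self.constituents)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"molar fractions sum to {total}, expected 1")
        self.molar_mass = sum(f * molar_mass(sp) for sp, f in self.constituents)
        epm = sum(w * sh.occupancy for sh, w in self.shells)
        self.electron_density = self.number_density * epm

    @property
    def electrons_per_molecule(self) -> float:
        return sum(w * sh.occupancy for sh, w in self.shells)

    def with_density(self, rho: float) -> "Material":
        """Same composition at a different mass density."""
        scale = rho / self.mass_density
        m = replace(self, mass_density=rho, number_density=self.number_density * scale)
        return m


def _build_shells(constituents: list[tuple[str, float]]) -> list[tuple[ElectronShell, float]]:
    shells: list[tuple[ElectronShell, float]] = []
    for species, frac in constituents:
        for sh, mult in species_shells(species):
            shells.append((sh, frac * mult))
    return shells


def load_material(config) -> Material:
    """Build a :class:`Material` from a config mapping (or YAML path).

    Schema::

        name: str
        density: float            # g/cm^3   (or number_density: molecules/cm^3)
        composition: {species: molar fraction, ...}
        mass_composition: {...}   # alternative to `composition`
        shell_overrides:          # optional, per species
          SPECIES: [{label, ionisation_potential, occupancy, parameter_set}, ...]
    """
    if isinstance(config, (str, bytes)) or hasattr(config, "read"):
        import yaml
        if hasattr(config, "read"):
            config = yaml.safe_load(config)
        else:
            with open(config) as fh:
                config = yaml.safe_load(fh)
    cfg = dict(config)
    name = cfg.get("name", "material")
    comp = cfg.get("composition")
    if comp is None and "mass_composition" in cfg:
        comp = mass_to_molar_fractions(cfg["mass_composition"])
    if not comp:
        raise ValueError("config must provide `composition` or `mass_composition`")
    constituents = [(str(sp), float(f)) for sp, f in comp.items()]
    for sp, f in constituents:
        if f <= 0:
            raise ValueError(f"molar fraction of {sp} must be positive, got {f}")
    total = sum(f for _, f in constituents)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"molar fractions sum to {total}, expected 1")

    shells = _build_shells(constituents)

    overrides = cfg.get("shell_overrides") or {}
    if overrides:
        shells = []
        for species, frac in constituents:
            if species in overrides:
                for o in overrides[species]:
                    pset = PARAMETER_SETS[o.get("parameter_set", "inner")]
                    shells.append((
                        ElectronShell(o["label"], float(o["ionisation_potential"]),
                                      int(o["occupancy"]), pset),
                        frac * float(o.get("multiplicity", 1.0)),
                    ))
            else:
                for sh, mult in species_shells(species):
                    shells.append((sh, frac * mult))

    mbar = sum(f * molar_mass(sp) for sp, f in constituents)
    if "number_density" in cfg:
        n = float(cfg["number_density"])
        rho = n * mbar / N_AVOGADRO
    else:
        rho = float(cfg["density"])
        n = rho * N_AVOGADRO / mbar
    return Material(name, constituents, rho, n, shells)


def material_to_config(material: Material) -> dict:
    """Serialize a material back into the ``load_material`` schema."""
    return {
        "name": material.name,
        "density": material.mass_density,
        "composition": {sp: f for sp, f in material.constituents},
    }


def mass_to_molar_fractions(mass_fractions: dict) -> dict:
    """Convert mass fractions to molar fractions."""
    mols = {sp: float(w) / molar_mass(sp) for sp, w in mass_fractions.items()}
    total = sum(mols.values())
    return {sp: v / total for sp, v in mols.items()}


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

def water(density: float = 1.0) -> Material:
    """Liquid water at the given density [g/cm^3]."""
    return load_material({"name": "water", "density": density,
                          "composition": {"H2O": 1.0}})


def teg(density: float = 1.0) -> Material:
    """Tissue-equivalent gas: 54.7% propane, 39.7% CO2, 5.6% N2 by mole."""
    return load_material({"name": "TEG", "density": density,
                          "composition": {"C3H8": 0.547, "CO2": 0.397, "N2": 0.056}})


def helium(number_density: float = 1.0e24) -> Material:
    """Helium at a given atom number density [atoms/cm^3]."""
    return load_material({"name": "helium", "number_density": number_density,
                          "composition": {"He": 1.0}})
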