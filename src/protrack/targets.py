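"""Molecular targets and bulk media.

A scatterer is described the way ion-molecule collision theory needs it: a
set of molecular orbitals (MOs), each with a binding energy ``eps_i`` (eV,
negative) and an LCAO population split over atomic components, each atomic
component carrying an effective occupation number ``c_kj`` and a principal
quantum number ``n`` from which the hydrogenic effective charge

    Ztilde = sqrt(-2 n^2 eps_i)   (eps_i in hartree)

follows.  Water vapor uses the CNDO population table; the five DNA
components (adenine, cytosine, guanine, thymine, sugar-phosphate) are read
from packaged per-MO tables.  Bulk media combine targets with mass
fractions, a density and a molar mass, from which the molecular number
density n = N_A rho / A_mol follows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

from .constants import AVOGADRO, HARTREE_EV

__all__ = [
    "AtomicComponent",
    "MolecularOrbital",
    "MolecularTarget",
    "CompositeMedium",
    "build_water_vapor",
    "build_dna_component",
    "build_hydrated_dna_medium",
    "build_dry_dna_medium",
    "build_water_medium",
    "number_density",
    "DNA_COMPONENTS",
]

#: electron counts Z' of the DNA components (also used by the loss rescaling)
DNA_COMPONENTS = {
    "adenine": 70,
    "cytosine": 58,
    "guanine": 78,
    "thymine": 66,
    "sugar-phosphate": 96,
}

_DNA_MO_COUNTS = {
    "adenine": 35,
    "cytosine": 29,
    "guanine": 39,
    "thymine": 33,
    "sugar-phosphate": 48,
}

_DNA_MOLAR_MASS = {
    "adenine": 135.14,
    "cytosine": 111.11,
    "guanine": 151.14,
    "thymine": 126.12,
    "sugar-phosphate": 180.0,
}

WATER_MOLAR_MASS = 18.015


@dataclass(frozen=True)
class AtomicComponent:
    """One atomic-orbital contribution to a molecular orbital."""

    label: str          # e.g. "O_2p"
    n_principal: int    # principal quantum number of the atomic orbital
    occupation: float   # effective electron number c_kj, >= 0

    def __post_init__(self):
        if self.occupation < 0:
            raise ValueError(f"negative occupation for {self.label}")
        if self.n_principal < 1:
            raise ValueError(f"n_principal must be >= 1 for {self.label}")


@dataclass(frozen=True)
class MolecularOrbital:
    label: str
    binding_energy: float               # eps_i in eV, < 0
    components: tuple[AtomicComponent, ...]

    def __post_init__(self):
        if self.binding_energy >= 0:
            raise ValueError(
                f"MO {self.label}: binding energy must be negative (bound)")

    @property
    def occupation(self) -> float:
        return sum(c.occupation for c in self.components)

    def effective_charge(self, component: AtomicComponent) -> float:
        """Hydrogenic effective charge matched to the MO binding energy."""
        eps_h = self.binding_energy / HARTREE_EV
        return math.sqrt(-2.0 * component.n_principal ** 2 * eps_h)


@dataclass(frozen=True)
class MolecularTarget:
    name: str
    molar_mass: float       # g/mol
    electron_count: int     # Z
    orbitals: tuple[MolecularOrbital, ...]

    def __post_init__(self):
        total = sum(mo.occupation for mo in self.orbitals)
        if abs(total - self.electron_count) > 0.02 * self.electron_count:
            raise ValueError(
                f"{self.name}: MO populations sum to {total:.3f}, "
                f"expected {self.electron_count} (+-2%)")

    @property
    def total_occupation(self) -> float:
        return sum(mo.occupation for mo in self.orbitals)


@dataclass(frozen=True)
class CompositeMedium:
    name: str
    density: float          # g/cm^3
    molar_mass: float       # g/mol of the transported "molecule"
    components: tuple[tuple[MolecularTarget, float], ...] = field(default=())

    def __post_init__(self):
        if self.density <= 0:
            raise ValueError("density must be positive")
        w = sum(f for _, f in self.components)
        if abs(w - 1.0) > 2e-3:
            raise ValueError(f"mass fractions sum to {w}, expected 1")

    def mass_fraction(self, name: str) -> float:
        for tgt, w in self.components:
            if tgt.name == name:
                return w
        return 0.0


def _parse_components(spec_str: str) -> tuple[AtomicComponent, ...]:
    comps = []
    for item in spec_str.split(";"):
        label, occ = item.split(":")
        # principal quantum number from the subshell tag, e.g. O_2p -> 2
        n = int(label.split("_")[1][0])
        comps.append(AtomicComponent(label=label, n_principal=n,
                                     occupation=float(occ)))
    return tuple(comps)


def _load_mo_table(fname: str) -> tuple[MolecularOrbital, ...]:
    text = resources.files("protrack.data").joinpath(fname).read_text()
    orbitals = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, eps, comps = line.split("\t")
        orbitals.append(MolecularOrbital(
            label=label, binding_energy=float(eps),
            components=_parse_components(comps)))
    return tuple(orbitals)


def build_water_vapor() -> MolecularTarget:
    """Water vapor in the CNDO description: five MOs, ten electrons."""
    orbitals = _load_mo_table("water_vapor.tsv")
    if len(orbitals) != 5:
        raise ValueError("water vapor table must have exactly 5 MOs")
    return MolecularTarget(name="water", molar_mass=WATER_MOLAR_MASS,
                           electron_count=10, orbitals=orbitals)


def build_dna_component(name: str) -> MolecularTarget:
    """One of the five DNA components from its packaged per-MO table.

    The numeric orbital tables are synthetic stand-ins for an RHF/3-21G +
    Mulliken analysis: they preserve the documented MO counts, atomic
    compositions, electron counts and literature Koopmans HOMO energies.
    """
    if name not in DNA_COMPONENTS:
        raise KeyError(f"unknown DNA component {name!r}; "
                       f"expected one of {sorted(DNA_COMPONENTS)}")
    fname = f"dna_{name.replace('-', '_')}_synthetic.tsv"
    orbitals = _load_mo_table(fname)
    if len(orbitals) != _DNA_MO_COUNTS[name]:
        raise ValueError(
            f"{name}: table has {len(orbitals)} MOs, "
            f"expected {_DNA_MO_COUNTS[name]}")
    return MolecularTarget(name=name, molar_mass=_DNA_MOLAR_MASS[name],
                           electron_count=DNA_COMPONENTS[name],
                           orbitals=orbitals)


# stoichiometry of the equivalent hydrated nucleotide:
# 0.58 (A-T) + 0.42 (C-G) + 2 sugar-phosphate + 18 H2O
_NUCLEOTIDE_STOICH = {
    "adenine": 0.58,
    "thymine": 0.58,
    "cytosine": 0.42,
    "guanine": 0.42,
    "sugar-phosphate": 2.0,
    "water": 18.0,
}

HYDRATED_DNA_MOLAR_MASS = 947.8
HYDRATED_DNA_DENSITY = 1.29
DRY_DNA_MOLAR_MASS = 662.0
DRY_DNA_DENSITY = 1.35


def _stoich_mass_fractions(include_water: bool) -> dict[str, float]:
    masses = {}
    for name, count in _NUCLEOTIDE_STOICH.items():
        if name == "water":
            if not include_water:
                continue
            masses[name] = count * WATER_MOLAR_MASS
        else:
            masses[name] = count * _DNA_MOLAR_MASS[name]
    total = sum(masses.values())
    return {k: v / total for k, v in masses.items()}


def build_hydrated_dna_medium() -> CompositeMedium:
    """Hydrated-DNA bulk medium (equivalent nucleotide + 18 waters)."""
    fractions = _stoich_mass_fractions(include_water=True)
    comps = tuple(
        (build_water_vapor() if n == "water" else build_dna_component(n), w)
        for n, w in fractions.items())
    return CompositeMedium(name="dna", density=HYDRATED_DNA_DENSITY,
                           molar_mass=HYDRATED_DNA_MOLAR_MASS,
                           components=comps)


def build_dry_dna_medium() -> CompositeMedium:
    """Dry DNA: the water contribution removed, rho=1.35, A_mol=662."""
    fractions = _stoich_mass_fractions(include_water=False)
    comps = tuple((build_dna_component(n), w) for n, w in fractions.items())
    return CompositeMedium(name="dry-dna", density=DRY_DNA_DENSITY,
                           molar_mass=DRY_DNA_MOLAR_MASS, components=comps)


def build_water_medium(density: float = 1.0) -> CompositeMedium:
    """Bulk water at the given density (g/cm^3)."""
    name = "water" if density == 1.0 else f"water-{density:g}"
    return CompositeMedium(name=name, density=density,
                           molar_mass=WATER_MOLAR_MASS,
                           components=((build_water_vapor(), 1.0),))


def number_density(medium: CompositeMedium) -> float:
    """Molecules per cm^3: n = N_A rho / A_mol."""
    return AVOGADRO * medium.density / medium.molar_mass
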