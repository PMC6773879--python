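"""Molecular targets and bulk media: tabulated values, electron-count
closure and stoichiometric consistency."""

import math

import numpy as np
import pytest

from protrack.constants import HARTREE_EV
from protrack.targets import (DNA_COMPONENTS, build_dna_component,
                              build_dry_dna_medium,
                              build_hydrated_dna_medium,
                              build_water_medium, build_water_vapor,
                              number_density, CompositeMedium)

WATER_MOS = {  # label: (binding eV, total population)
    "1a1": (-539.7, 2.0), "2a1": (-32.2, 2.0), "1b2": (-18.4, 2.0),
    "3a1": (-14.7, 2.0), "1b1": (-12.6, 2.0),
}


def test_water_vapor_cndo_table():
    w = build_water_vapor()
    assert w.electron_count == 10
    assert w.molar_mass == pytest.approx(18.015)
    assert len(w.orbitals) == 5
    for mo in w.orbitals:
        eps, pop = WATER_MOS[mo.label]
        assert mo.binding_energy == pytest.approx(eps)
        assert mo.occupation == pytest.approx(pop, abs=1e-9)
    assert w.total_occupation == pytest.approx(10.0, abs=1e-9)


def test_water_1b1_effective_charge():
    w = build_water_vapor()
    mo = [m for m in w.orbitals if m.label == "1b1"][0]
    zt = mo.effective_charge(mo.components[0])
    # sqrt(-2 n^2 eps), n = 2, eps = -12.6 eV
    assert zt == pytest.approx(
        math.sqrt(-2 * 4 * (-12.6 / HARTREE_EV)), rel=1e-12)
    assert zt == pytest.approx(1.925, abs=2e-3)


@pytest.mark.parametrize("name,n_mo,z", [
    ("adenine", 35, 70), ("cytosine", 29, 58), ("guanine", 39, 78),
    ("thymine", 33, 66), ("sugar-phosphate", 48, 96)])
def test_dna_components(name, n_mo, z):
    t = build_dna_component(name)
    assert len(t.orbitals) == n_mo
    assert t.electron_count == z
    assert t.total_occupation == pytest.approx(z, rel=0.02)
    # every occupied MO carries close to 2 electrons
    for mo in t.orbitals:
        assert mo.occupation == pytest.approx(2.0, rel=0.05)
    # all bound states: effective charges real and positive
    for mo in t.orbitals:
        for comp in mo.components:
            assert mo.effective_charge(comp) > 0


def test_unknown_component_rejected():
    with pytest.raises(KeyError):
        build_dna_component("uracil")


def test_hydrated_dna_mass_fractions():
    m = build_hydrated_dna_medium()
    printed = {"adenine": 0.083, "thymine": 0.077, "cytosine": 0.049,
               "guanine": 0.067, "sugar-phosphate": 0.381,
               "water": 0.343}
    for name, w in printed.items():
        assert m.mass_fraction(name) == pytest.approx(w, abs=0.002)
    assert sum(f for _, f in m.components) == pytest.approx(1.0, abs=2e-3)
    assert m.density == pytest.approx(1.29)


def test_hydrated_dna_stoichiometric_oracle():
    """Recompute the molar mass and fractions from first principles."""
    masses = dict(adenine=135.14, thymine=126.12, cytosine=111.11,
                  guanine=151.14)
    total = (0.58 * (masses["adenine"] + masses["thymine"])
             + 0.42 * (masses["cytosine"] + masses["guanine"])
             + 2 * 180.0 + 18 * 18.015)
    m = build_hydrated_dna_medium()
    assert m.molar_mass == pytest.approx(947.8, rel=0.005)
    assert total == pytest.approx(947.8, rel=0.005)
    assert m.mass_fraction("adenine") == pytest.approx(
        0.58 * masses["adenine"] / total, abs=1e-9)


def test_dry_dna_medium():
    d = build_dry_dna_medium()
    assert d.density == pytest.approx(1.35)
    assert d.molar_mass == pytest.approx(662.0)
    assert d.mass_fraction("water") == 0.0
    assert sum(f for _, f in d.components) == pytest.approx(1.0, abs=2e-3)


def test_number_density():
    assert number_density(build_water_medium()) == pytest.approx(
        3.34e22, rel=2e-3)
    assert number_density(build_hydrated_dna_medium()) == pytest.approx(
        8.20e20, rel=2e-3)
    w1 = build_water_medium(1.0)
    w2 = build_water_medium(2.0)
    assert number_density(w2) == pytest.approx(2 * number_density(w1))


def test_invalid_media_rejected():
    with pytest.raises(ValueError):
        CompositeMedium(name="bad", density=-1.0, molar_mass=18.0,
                        components=((build_water_vapor(), 1.0),))
    with pytest.raises(ValueError):
        CompositeMedium(name="bad", density=1.0, molar_mass=18.0,
                        components=((build_water_vapor(), 0.5),))
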