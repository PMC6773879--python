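"""Classical elastic scattering: Rutherford closed-form oracles and
screened-potential behavior."""

import math

import numpy as np
import pytest

from protrack.elastic import (DeflectionTable, cm_energy_hartree,
                              coulomb_potential, deflection_angle,
                              elastic_energy_transfer_ev,
                              h0_elastic_ratio, water_potential)


@pytest.mark.parametrize("rho", [0.05, 0.3, 1.0, 5.0])
def test_rutherford_deflection_closed_form(rho):
    """tan(theta/2) = Z1 Z2 / (2 E rho) for the bare Coulomb potential."""
    z12, e_cm = 8.0, 10.0
    th = deflection_angle(coulomb_potential(z12), e_cm, rho)
    ref = 2.0 * math.atan(z12 / (2.0 * e_cm * rho))
    assert th == pytest.approx(ref, rel=1e-6)


def test_head_on_and_grazing_limits():
    pot = water_potential()
    assert deflection_angle(pot, 100.0, 0.0) == pytest.approx(math.pi)
    assert deflection_angle(pot, 100.0, 50.0) == pytest.approx(0.0,
                                                              abs=1e-6)


def test_rutherford_dcs_closed_form():
    z12, e_cm = 8.0, 10.0
    tab = DeflectionTable(coulomb_potential(z12), e_cm, n_rho=160,
                          rho_max=300.0)
    for th in (0.5, 1.5, 2.5):
        ruth = (z12 / (4.0 * e_cm)) ** 2 / math.sin(th / 2.0) ** 4
        assert tab.dcs(th) == pytest.approx(ruth, rel=0.01)


def test_screened_dcs_finite_at_small_angles():
    """The screened potential removes the Coulomb forward divergence."""
    e_cm = cm_energy_hartree(100.0, 18.015)
    tab = DeflectionTable(water_potential(), e_cm, n_rho=96)
    small = tab.dcs(1e-3)
    ruth_like = tab.dcs(0.3) * (math.sin(0.15) / math.sin(5e-4)) ** 4
    assert np.isfinite(small)
    assert small < ruth_like          # far below the unscreened growth


def test_tcs_monotone_in_cutoff_and_energy():
    pot = water_potential()
    e_cm = cm_energy_hartree(100.0, 18.015)
    tab = DeflectionTable(pot, e_cm, n_rho=96)
    cuts = [1e-4, 1e-3, 1e-2, 1e-1]
    vals = [tab.tcs(c) for c in cuts]
    assert all(a > b for a, b in zip(vals, vals[1:]))
    assert all(np.isfinite(v) and v > 0 for v in vals)

    sig = []
    for e_kev in (10.0, 100.0, 1000.0):
        t = DeflectionTable(pot, cm_energy_hartree(e_kev, 18.015),
                            n_rho=64)
        sig.append(t.tcs(1e-4))
    assert sig[0] > sig[1] > sig[2]


def test_screened_tcs_grows_only_logarithmically():
    """For a screened potential the classical TCS grows ~log^2(1/cut)
    as the cutoff vanishes, in contrast to the 1/cut^2 Coulomb
    divergence."""
    e_cm = cm_energy_hartree(100.0, 18.015)
    tab = DeflectionTable(water_potential(), e_cm, n_rho=96)
    v1 = tab.tcs(1e-5)
    v2 = tab.tcs(1e-6)
    assert v2 / v1 < 10.0             # Coulomb would grow by 100x
    coul = DeflectionTable(coulomb_potential(8.0), e_cm, n_rho=96,
                           rho_max=1e6)
    assert coul.tcs(1e-6) / coul.tcs(1e-5) == pytest.approx(100.0,
                                                            rel=0.05)


def test_h0_ratio_values():
    assert h0_elastic_ratio(1.0) == pytest.approx(1.0)
    assert h0_elastic_ratio(100.0) == pytest.approx(1.096, abs=1e-3)
    # close to unity (within 1.3) up to 10 MeV with the log10/keV
    # convention; by 100 MeV the quadratic term lifts it to 1.43
    e = np.geomspace(10.0, 1.0e4, 40)
    r = h0_elastic_ratio(e)
    assert np.all(r >= 1.0) and np.all(r <= 1.3)
    assert h0_elastic_ratio(1.0e5) == pytest.approx(1.433, abs=2e-3)


def test_energy_transfer_kinematics():
    e_kev = 100.0
    m = 18.015
    t_max = elastic_energy_transfer_ev(e_kev, m, math.pi)
    for th in (0.01, 0.5, 2.0, math.pi):
        t = elastic_energy_transfer_ev(e_kev, m, th)
        assert 0.0 <= t <= t_max + 1e-9
    mt = m / 1.00727646688
    assert t_max == pytest.approx(
        4.0 * mt / (1.0 + mt) ** 2 * e_kev * 1e3, rel=1e-12)
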