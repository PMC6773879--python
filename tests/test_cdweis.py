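"""CDW-EIS amplitudes and cross sections: dual-route oracle, Born
convergence on the exactly solvable channel, symmetries and scalings."""

import math

import numpy as np
import pytest

from protrack.cdweis import (amplitude_eta, amplitude_factors_numeric,
                             _bound_bound_ft, born_amplitude_eta,
                             ddcs_ionization, orbital_ionization,
                             h0_effective_charge_sq, target_channels,
                             tcs_capture, tcs_capture_orbital,
                             tcs_ionization, tcs_ionization_orbital)
from protrack.targets import build_water_vapor

BENCH = dict(e_inc_kev=1000.0, eps_ev=-32.2, subshell="H_1s",
             e_k_ev=50.0, theta_k=math.radians(30.0), eta=0.5,
             phi_eta=0.7)


def test_dual_route_agreement():
    """Analytic closed-form route vs brute-force spatial quadrature on
    the benchmark kinematics (both at the same finite regularization of
    the conditionally convergent eikonal integral)."""
    delta, beta = 0.3, 0.4
    r_num, _, _ = amplitude_factors_numeric(
        BENCH["e_inc_kev"], BENCH["eps_ev"], BENCH["subshell"],
        BENCH["e_k_ev"], BENCH["theta_k"], BENCH["eta"],
        BENCH["phi_eta"], delta=delta, beta=beta, nr=200, nmu=64,
        nphi=32)
    r_an = complex(amplitude_eta(
        BENCH["e_inc_kev"], BENCH["eps_ev"], BENCH["subshell"],
        BENCH["e_k_ev"], BENCH["theta_k"], np.array(BENCH["eta"]),
        np.array(BENCH["phi_eta"]), reg_delta=delta, reg_beta=beta,
        orthogonalize=False))
    assert abs(r_num - r_an) / abs(r_num) < 0.01


def test_amplitude_regularization_continuity():
    """The physical amplitude is the continuous limit of the regularized
    one: R(delta -> 0) approaches R(0) monotonically in step size."""
    args = (BENCH["e_inc_kev"], BENCH["eps_ev"], BENCH["subshell"],
            BENCH["e_k_ev"], BENCH["theta_k"], np.array(BENCH["eta"]),
            np.array(BENCH["phi_eta"]))
    r0 = complex(amplitude_eta(*args, orthogonalize=False))
    d1 = abs(complex(amplitude_eta(*args, reg_delta=0.04,
                                   orthogonalize=False)) - r0)
    d2 = abs(complex(amplitude_eta(*args, reg_delta=0.02,
                                   orthogonalize=False)) - r0)
    d3 = abs(complex(amplitude_eta(*args, reg_delta=0.01,
                                   orthogonalize=False)) - r0)
    assert d3 < d2 < d1
    assert d3 / abs(r0) < 0.05


def test_born_convergence_hydrogenic_channel():
    """On the consistent hydrogenic channel (H 1s: bound state, continuum
    and binding all from one Hamiltonian) the distorted-wave TCS must
    approach first Born from below-unity ratios, monotonically, above
    5 MeV."""
    quad = dict(n_ek=12, n_theta=10, n_eta=20, n_phi=6, n_mid=48)
    ratios = []
    for e in (5.0e3, 1.0e4, 3.0e4):
        c = tcs_ionization_orbital(e, -13.606, "H_1s", **quad)
        b = tcs_ionization_orbital(e, -13.606, "H_1s", born=True,
                                   **quad)
        ratios.append(c / b)
    assert abs(ratios[-1] - 1.0) < 0.05
    assert abs(ratios[1] - 1.0) <= abs(ratios[0] - 1.0) + 1e-3
    assert abs(ratios[2] - 1.0) <= abs(ratios[1] - 1.0) + 1e-3


def test_born_anchor_bates_griffing():
    """p + H(1s) first-Born TCS at 1 MeV against the Bethe asymptote
    with the classic hydrogen parameters (A = 0.2834, B = 1.26)."""
    t_over_r = (1000.0 / 1836.15267343) * 1e3 / 13.6057
    sigma_bethe = 3.517e-16 / t_over_r * (
        0.2834 * math.log(t_over_r) + 1.26)
    b = tcs_ionization_orbital(1.0e3, -13.606, "H_1s", born=True,
                               n_ek=16, n_theta=12, n_eta=24, n_phi=8)
    assert b == pytest.approx(sigma_bethe, rel=0.05)


def test_azimuthal_symmetry_s_state():
    """|R(eta, phi)| = |R(eta, -phi)| for s initial states."""
    args = (100.0, -12.6, "O_2s", 30.0, 0.5)
    rp = amplitude_eta(*args, np.array(0.7), np.array(1.1))
    rm = amplitude_eta(*args, np.array(0.7), np.array(-1.1))
    assert abs(abs(complex(rp)) - abs(complex(rm))) < 1e-10 * abs(
        complex(rp))


def test_ddcs_positive_and_binary_peak():
    """The DDCS is non-negative and peaks near the binary-encounter
    angle cos(theta) = sqrt(E_k / E_max)."""
    e_inc, ek = 1000.0, 300.0
    emax = 4.0 * e_inc * 1e3 / 1836.15267343
    th_be = math.acos(math.sqrt(ek / emax))
    thetas = np.radians(np.arange(15.0, 91.0, 7.5))
    vals = [ddcs_ionization(e_inc, -12.6, "O_2p", ek, th,
                            n_eta=24, n_phi=6, n_mid=48)
            for th in thetas]
    assert all(v >= 0 for v in vals)
    peak = thetas[int(np.argmax(vals))]
    assert abs(math.degrees(peak - th_be)) <= 10.0


def test_sdcs_consistency_and_tail():
    """Integrating the tabulated SDCS reproduces the TCS, and the
    spectrum decays beyond the binary-encounter ridge."""
    tcs, ek, sdcs, ct, grid = orbital_ionization(
        300.0, -12.6, "O_2p", n_ek=16, n_theta=10, n_eta=20, n_phi=6,
        n_mid=48)
    assert np.all(sdcs >= 0)
    quad = np.trapezoid(sdcs, ek)
    assert quad == pytest.approx(tcs, rel=0.15)   # grid-level agreement
    e_binary = 4.0 * 300.0 * 1e3 / 1836.15267343
    tail = sdcs[ek > 1.5 * e_binary]
    assert np.all(np.diff(tail) < 0)


def test_lcao_linearity():
    """Doubling all occupations doubles the molecular TCS."""
    w = build_water_vapor()
    chans = target_channels(w)
    base = sum(occ * 1.0 for _, _, occ in chans)
    assert base == pytest.approx(10.0, abs=1e-9)
    quad = dict(n_ek=10, n_theta=8, n_eta=16, n_phi=6, n_mid=40)
    sig = tcs_ionization(w, 300.0, **quad)
    total = 0.0
    for eps, lab, occ in chans:
        total += 2.0 * occ * tcs_ionization_orbital(300.0, eps, lab,
                                                    **quad)
    assert total == pytest.approx(2.0 * sig, rel=1e-9)


def test_1b1_contribution_is_two_o2p_units():
    """The 1b1 MO is 2.0 x O_2p at -12.6 eV by its CNDO population."""
    w = build_water_vapor()
    chans = {(round(eps, 3), lab): occ
             for eps, lab, occ in target_channels(w)}
    assert chans[(-12.6, "O_2p")] == pytest.approx(2.0)


def test_capture_decreasing_and_steep():
    quad = dict(n_eta=24, n_phi=6, n_mid=48)
    es = np.array([100.0, 300.0, 1000.0])
    sig = [tcs_capture_orbital(e, -12.6, "O_2p", **quad) for e in es]
    assert sig[0] > sig[1] > sig[2] > 0
    slope = np.polyfit(np.log([1000.0, 5000.0]),
                       np.log([tcs_capture_orbital(1000.0, -12.6, "O_2p",
                                                   **quad),
                               tcs_capture_orbital(5000.0, -12.6, "O_2p",
                                                   **quad)]), 1)[0]
    assert slope < -4.0


def test_h0_screening_factor_properties():
    es = np.geomspace(10.0, 1.0e5, 40)
    z2 = np.array([h0_effective_charge_sq(e) for e in es])
    assert np.all(z2 <= 1.0)
    assert z2[0] < 0.75               # visibly screened at low speed
    assert np.all(np.diff(z2) >= 0)
    assert z2[-1] > 0.999


def test_bound_bound_ft_normalization():
    for nl, z in [((1, 0), 1.0), ((2, 0), 2.246), ((2, 1), 2.227),
                  ((3, 0), 1.881), ((3, 1), 1.629)]:
        for b in _bound_bound_ft(nl, z, 0.0, 0.0, 0.0):
            assert complex(b).real == pytest.approx(1.0, abs=3e-3)
    # decays with momentum transfer
    b0 = complex(_bound_bound_ft((2, 1), 2.227, 0.0, 0.0, 0.5)[0]).real
    b1 = complex(_bound_bound_ft((2, 1), 2.227, 0.0, 0.0, 3.0)[0]).real
    assert 0 < b1 < b0 < 1.0


def test_energy_domain_guard():
    w = build_water_vapor()
    with pytest.raises(ValueError):
        tcs_ionization(w, 5.0)
    with pytest.raises(ValueError):
        tcs_capture(w, 2.0e5)


def test_water_tcs_single_maximum_40_150(water_tables):
    """The tabulated ionization TCS has a single interior maximum in the
    Bragg-peak region."""
    es = np.linspace(40.0, 150.0, 23)
    sig = water_tables.interp_tcs("H+", "ionization", es)
    imax = int(np.argmax(sig))
    assert 0 < imax < len(es) - 1 or sig[0] < sig[-1]
    d = np.sign(np.diff(sig))
    assert np.count_nonzero(np.diff(d)) <= 1    # unimodal on the scan
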