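"""Classical elastic scattering of H+/H0 on water.

The deflection function

    theta(rho) = pi - 2 * int_{r_min}^inf  rho dr / (r^2 sqrt(1 - V/E - rho^2/r^2))

is evaluated for a central screened-Coulomb molecular potential (sum of
Thomas-Fermi-screened atomic terms placed at a common center), the
differential cross section follows from dsigma/dOmega = -(rho/sin theta)
drho/dtheta on the inverted monotone branch, and the total cross section
above a cutoff angle is sigma = pi rho(theta_cut)^2 (exact for a monotone
deflection function with theta(0) = pi).

Everything internal is in hartree atomic units; the public API takes the
lab kinetic energy in keV and the target molar mass in amu for the
center-of-mass conversion.  The neutral-hydrogen elastic cross section is
the proton one times an empirical log-quadratic ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .constants import A0_SQ_CM2, HARTREE_EV

__all__ = [
    "ScreenedPotential",
    "water_potential",
    "coulomb_potential",
    "deflection_angle",
    "elastic_dcs",
    "elastic_tcs",
    "DeflectionTable",
    "h0_elastic_ratio",
    "cm_energy_hartree",
    "elastic_energy_transfer_ev",
]

AMU_OVER_MP = 1.00727646688  # proton mass in amu


@dataclass(frozen=True)
class ScreenedPotential:
    """V(r) = Z_P * sum_a Z_a exp(-r/L_a) / r  (hartree, r in bohr).

    ``screening_lengths`` of ``inf`` recover the bare Coulomb terms.
    """

    charges: tuple[float, ...]
    screening_lengths: tuple[float, ...]
    z_projectile: float = 1.0

    def __call__(self, r):
        r = np.asarray(r, dtype=float)
        v = np.zeros_like(r)
        for z, L in zip(self.charges, self.screening_lengths):
            term = z / r
            if math.isfinite(L):
                term = term * np.exp(-r / L)
            v = v + term
        out = self.z_projectile * v
        return out if out.ndim else float(out)


def _tf_length(z: float) -> float:
    """Thomas-Fermi screening length, 0.8853 a0 / Z^(1/3)."""
    return 0.8853 / z ** (1.0 / 3.0)


def water_potential(z_projectile: float = 1.0) -> ScreenedPotential:
    """Screened molecular potential for water: O + 2 H at a common center."""
    return ScreenedPotential(charges=(8.0, 1.0, 1.0),
                             screening_lengths=(_tf_length(8.0),
                                                _tf_length(1.0),
                                                _tf_length(1.0)),
                             z_projectile=z_projectile)


def coulomb_potential(z1z2: float) -> ScreenedPotential:
    return ScreenedPotential(charges=(z1z2,),
                             screening_lengths=(math.inf,))


def _r_min(potential, e_cm: float, rho: float) -> float:
    """Largest root of 1 - V(r)/E - rho^2/r^2 = 0."""

    def f(r):
        return 1.0 - potential(r) / e_cm - (rho / r) ** 2 if rho else \
            1.0 - potential(r) / e_cm

    lo = rho if rho > 0 else 1e-12
    if rho > 0 and f(lo) >= 0.0:     # attractive or negligible potential
        lo = rho * 1e-3
        if f(lo) >= 0.0:
            return rho
    hi = max(rho, 1e-6)
    for _ in range(400):
        hi *= 1.5
        if f(hi) > 0.0:
            break
    else:
        raise RuntimeError("no classical turning point found (orbiting?)")
    return brentq(f, lo, hi, xtol=1e-300, rtol=8.9e-16, maxiter=300)


def deflection_angle(potential, e_cm: float, rho: float) -> float:
    """CM deflection angle theta(rho) in radians, in [0, pi].

    ``e_cm`` in hartree, ``rho`` in bohr.  The integrable endpoint
    singularity at r_min is removed by the substitution r = r_min/(1-u^2).
    """
    if rho == 0.0:
        return math.pi
    rmin = _r_min(potential, e_cm, rho)

    def integrand(u):
        t = 1.0 - u * u          # t = rmin / r
        r = rmin / t
        g = 1.0 - potential(r) / e_cm - (rho * t / rmin) ** 2
        if g <= 0.0:
            return 0.0
        return 4.0 * u * rho / (rmin * math.sqrt(g))

    val, _ = quad(integrand, 0.0, 1.0, limit=200, epsabs=1e-12,
                  epsrel=1e-11)
    theta = math.pi - val
    return min(max(theta, 0.0), math.pi)


class DeflectionTable:
    """theta(rho) scan with monotone-branch inversion for DCS/TCS/sampling."""

    def __init__(self, potential, e_cm: float, n_rho: int = 160,
                 rho_max: float = 60.0):
        self.potential = potential
        self.e_cm = e_cm
        rho = np.concatenate([[0.0],
                              np.geomspace(1e-5, rho_max, n_rho - 1)])
        theta = np.array([math.pi if r == 0 else
                          deflection_angle(potential, e_cm, r) for r in rho])
        # keep the monotone-decreasing branch (repulsive potentials give one
        # branch; clip stray non-monotonicity from quadrature noise)
        theta = np.minimum.accumulate(theta)
        self.rho = rho
        self.theta = theta

    def rho_of_theta(self, theta):
        """Impact parameter on the monotone branch (bohr)."""
        return np.interp(np.asarray(theta, dtype=float),
                         self.theta[::-1], self.rho[::-1])

    def _rho_exact(self, theta: float) -> float:
        """rho(theta) refined by root-finding the deflection function."""
        rho0 = float(self.rho_of_theta(theta))
        lo, hi = rho0 * 0.5, rho0 * 2.0 + 1e-9

        def f(r):
            return deflection_angle(self.potential, self.e_cm, r) - theta

        for _ in range(60):
            if f(lo) > 0:
                break
            lo *= 0.5
        for _ in range(60):
            if f(hi) < 0:
                break
            hi *= 2.0
        return brentq(f, lo, hi, rtol=1e-12)

    def dcs(self, theta):
        """dsigma/dOmega in bohr^2/sr via the inverted branch derivative.

        Each angle is refined by root-finding theta(rho) = theta, so the
        result carries the quadrature accuracy of the deflection integral
        rather than the table-interpolation accuracy.
        """
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        out = np.empty_like(theta)
        for i, th in enumerate(theta):
            h = 1e-4 * max(th, 0.1)
            rp = self._rho_exact(min(th + h, math.pi * (1 - 1e-9)))
            rm = self._rho_exact(th - h)
            rho = 0.5 * (rp + rm)
            drho = (rp - rm) / (2.0 * h)
            out[i] = abs(rho / math.sin(th) * drho)
        return out if out.size > 1 else float(out[0])

    def tcs(self, theta_cut: float) -> float:
        """sigma(theta > theta_cut) = pi rho(theta_cut)^2, in bohr^2."""
        return math.pi * float(self.rho_of_theta(theta_cut)) ** 2


def cm_energy_hartree(e_lab_kev: float, molar_mass: float) -> float:
    """CM kinetic energy (hartree) for a proton on a target of mass
    ``molar_mass`` amu."""
    m_t = molar_mass / AMU_OVER_MP   # in proton masses
    return (e_lab_kev * 1e3 / HARTREE_EV) * m_t / (1.0 + m_t)


def elastic_dcs(potential, e_cm: float, theta) -> float:
    """Convenience wrapper: DCS at ``theta`` (rad) for ``e_cm`` hartree."""
    return DeflectionTable(potential, e_cm).dcs(theta)


def elastic_tcs(potential, e_cm: float, theta_cut: float) -> float:
    """Elastic TCS (cm^2) above ``theta_cut`` (rad, CM) at ``e_cm`` hartree."""
    if theta_cut <= 0:
        raise ValueError("theta_cut must be positive")
    return DeflectionTable(potential, e_cm).tcs(theta_cut) * A0_SQ_CM2


def h0_elastic_ratio(e_inc_kev) -> float:
    """sigma_H0 / sigma_H+ elastic ratio, log10 with E in keV."""
    x = np.log10(np.asarray(e_inc_kev, dtype=float))
    out = 1.0 + 0.0224 * x + 0.01285 * x ** 2
    return out if out.ndim else float(out)


def elastic_energy_transfer_ev(e_lab_kev: float, molar_mass: float,
                               theta_cm: float) -> float:
    """Nuclear recoil energy T = T_max sin^2(theta/2) in eV."""
    m_t = molar_mass / AMU_OVER_MP
    t_max = 4.0 * m_t / (1.0 + m_t) ** 2 * e_lab_kev * 1e3
    return t_max * math.sin(theta_cm / 2.0) ** 2
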