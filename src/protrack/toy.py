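"""Analytic toy medium for oracle-exact transport tests.

A single-process table (constant ionization cross section ``sigma_cm2``
with a fixed local energy deposit ``delta_e_ev`` and no secondary
electron) on top of a water-density medium.  Its macroscopic quantities
have closed forms:

    SP    = n sigma delta_e
    IMFP  = 1 / (n sigma)
    range = (E0 - E_cut) / SP  (+ the fixed sub-cutoff correction)

which the Monte Carlo estimators must reproduce within statistics.
"""

from __future__ import annotations

import numpy as np

from .tables import XsTables
from .targets import CompositeMedium, build_water_vapor

__all__ = ["generate_toy_medium", "toy_sp_kev_um", "toy_imfp_nm",
           "toy_range_um"]


def generate_toy_medium(sigma_cm2: float = 1.0e-16,
                        delta_e_ev: float = 20.0,
                        density: float = 1.0,
                        n_e: int = 16, n_ek: int = 16, n_theta: int = 10,
                        n_x: int = 32) -> tuple[CompositeMedium, XsTables]:
    medium = CompositeMedium(
        name="toy", density=density, molar_mass=18.015,
        components=((build_water_vapor(), 1.0),))
    e_grid = np.geomspace(10.0, 1.0e5, n_e)
    tab = XsTables(medium="toy", density=density, molar_mass=18.015,
                   e_grid=e_grid)
    zeros = np.zeros(n_e)
    tab.tcs = {("H+", "ionization"): np.full(n_e, sigma_cm2),
               ("H+", "excitation"): zeros.copy(),
               ("H+", "capture"): np.full(n_e, 1e-40),
               ("H+", "elastic"): zeros.copy(),
               ("H0", "ionization"): np.full(n_e, sigma_cm2),
               ("H0", "excitation"): zeros.copy(),
               ("H0", "loss"): np.full(n_e, 1e-16),
               ("H0", "elastic"): zeros.copy()}
    # ionization deposits exactly delta_e: binding = delta_e, E_k ~ 0
    tab.ek_grid = np.full((n_e, n_ek), 1e-9)
    tab.ek_grid[:] = np.linspace(1e-9, 2e-9, n_ek)[None, :]
    tab.ek_cdf = np.tile(np.linspace(0.0, 1.0, n_ek), (n_e, 1))
    tab.binding_mean = np.full(n_e, delta_e_ev)
    tab.cos_nodes = np.polynomial.legendre.leggauss(n_theta)[0]
    tab.theta_cdf = np.tile(np.linspace(0.0, 1.0, n_ek * n_theta)
                            .reshape(n_ek, n_theta)[None], (n_e, 1, 1))
    tab.theta_cdf = np.tile(np.linspace(0.0, 1.0, n_theta)[None, None, :],
                            (n_e, n_ek, 1))
    tab.exc_weights = np.full((n_e, 5), 0.2)
    tab.elastic_x = np.concatenate([[0.0],
                                    np.geomspace(1e-8, 1.0, n_x - 1)])
    tab.elastic_theta = np.zeros((n_e, n_x))
    tab.meta = dict(electron_scale=1.0, toy=True,
                    sigma_cm2=sigma_cm2, delta_e_ev=delta_e_ev)
    return medium, tab


def toy_sp_kev_um(tab: XsTables) -> float:
    """Closed-form stopping power n sigma delta_e in keV/um."""
    return (tab.number_density * tab.meta["sigma_cm2"]
            * tab.meta["delta_e_ev"] * 1e-3 * 1e-4)


def toy_imfp_nm(tab: XsTables) -> float:
    return 1.0 / (tab.number_density * tab.meta["sigma_cm2"]) * 1e7


def toy_range_um(tab: XsTables, e0_kev: float,
                 correction_um: float = 0.322) -> float:
    sp = toy_sp_kev_um(tab)
    return (e0_kev - 10.0) / sp + correction_um
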