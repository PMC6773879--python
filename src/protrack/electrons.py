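"""Simplified, pluggable secondary-electron transport.

Electrons are followed event-by-event with analytic water cross sections
(binary-encounter-style ionization per molecular orbital, excitation by
velocity scaling of the proton fits, screened-Rutherford elastic
scattering) down to a 7.4 eV cutoff, below which the remaining energy is
deposited locally.  In other media the cross sections are scaled by the
electron-count ratio to water.  Per-history energy is conserved exactly:
the deposits of a history sum to its initial energy.

The in-phantom transport runs inside the numba kernels; this module
exposes the same physics as a python-level reference that returns the
spatially resolved deposit list, plus the analytic model functions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import kernels
from .constants import CM_PER_UM
from .targets import CompositeMedium, number_density

__all__ = ["ElectronState", "transport_electron", "electron_sigma_ion",
           "electron_sigma_exc", "electron_sigma_el", "E_CUTOFF_EV"]

E_CUTOFF_EV = kernels.E_CUTOFF_EV


@dataclass
class ElectronState:
    energy_ev: float
    position_um: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        if self.energy_ev < 0:
            raise ValueError("negative electron energy")


def electron_sigma_ion(t_ev: float) -> float:
    """Ionization TCS (cm^2) per water molecule."""
    return float(kernels._e_sigma_ion(t_ev))


def electron_sigma_exc(t_ev: float) -> float:
    return float(kernels._e_sigma_exc(t_ev))


def electron_sigma_el(t_ev: float) -> float:
    return float(kernels._e_sigma_el(t_ev))


def _electron_scale(medium: CompositeMedium) -> float:
    z = 0.0
    for tgt, w in medium.components:
        z += (w * medium.molar_mass / tgt.molar_mass) * tgt.electron_count
    return z / 10.0


def transport_electron(state: ElectronState, medium: CompositeMedium,
                       rng: np.random.Generator):
    """Follow one electron to the cutoff in an infinite medium.

    Returns a list of (position_um, deposit_ev); the deposits sum to the
    initial energy exactly.
    """
    nd = number_density(medium) * _electron_scale(medium)
    deposits = []
    stack = [(state.energy_ev, state.position_um.astype(float).copy(),
              state.direction.astype(float).copy())]
    b_arr = kernels._E_B
    while stack:
        e, pos, u = stack.pop()
        while e > E_CUTOFF_EV:
            s_ion = electron_sigma_ion(e)
            s_exc = electron_sigma_exc(e)
            s_el = electron_sigma_el(e)
            s_tot = s_ion + s_exc + s_el
            if s_ion + s_exc <= 0.0:
                break      # sub-excitation: deposit on the spot
            lam_um = 1.0 / (nd * s_tot) / CM_PER_UM
            pos = pos + u * rng.exponential(lam_um)
            x = rng.random() * s_tot
            if x < s_ion:
                open_b = [b for b in b_arr if b < e]
                b = float(open_b[rng.integers(len(open_b))])
                wmax = 0.5 * (e - b)
                if wmax <= 0:
                    break
                u3 = rng.random()
                w = b * u3 * wmax / (b + wmax - u3 * wmax)
                deposits.append((pos.copy(), b))
                e = e - b - w
                if w <= E_CUTOFF_EV:
                    deposits.append((pos.copy(), w))
                else:
                    ct = 2.0 * rng.random() - 1.0
                    st = math.sqrt(max(0.0, 1.0 - ct * ct))
                    ph = 2.0 * math.pi * rng.random()
                    stack.append((w, pos.copy(),
                                  np.array([st * math.cos(ph),
                                            st * math.sin(ph), ct])))
            elif x < s_ion + s_exc:
                w_ev = min(8.17 + rng.random() * (14.50 - 8.17), e)
                deposits.append((pos.copy(), w_ev))
                e -= w_ev
            else:
                tau = e / 511.0e3
                eta = 1.7e-5 * 10.0 ** (2.0 / 3.0) / max(
                    tau * (tau + 2.0), 1e-12)
                uu = rng.random()
                ct = min(1.0, max(-1.0, 1.0 - 2.0 * eta * uu
                                  / (1.0 + eta - uu)))
                ph = 2.0 * math.pi * rng.random()
                ux, uy, uz = kernels._rotate(u[0], u[1], u[2], ct, ph)
                u = np.array([ux, uy, uz])
        if e > 0.0:
            deposits.append((pos.copy(), e))
    return deposits
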