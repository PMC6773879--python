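"""Charge-state-mixed Monte Carlo transport of H+/H0 and the macroscopic
estimators: equilibrium charge fractions, total TCS, inelastic mean free
path, stationary-mode stopping power and slowing-down range.

The stationary stopping power follows each projectile only to its first
inelastic interaction and combines the per-species estimators with the
equilibrium charge fractions,

    SP = f_H+ (SP)_H+ + f_H0 (SP)_H0,
    f_H+ = sigma_L / (sigma_L + sigma_C),

where sigma_L and sigma_C are the electron-loss and electron-capture
cross sections at the current energy.  The slowing-down range follows
each primary (with charge-changing cycles) until its energy falls below
the 10 keV proton cutoff, and adds a fixed sub-cutoff path correction
(0.322 um by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import kernels
from .constants import ME_MP, H_BINDING_EV
from .tables import XsTables, charge_fractions_at, imfp, total_tcs

__all__ = [
    "ChargeFractions",
    "ProjectileState",
    "InteractionRecord",
    "charge_fractions",
    "pack_tables",
    "sample_interaction",
    "stationary_stopping_power",
    "slowing_down_range",
    "total_tcs",
    "imfp",
]

RANGE_CORRECTION_UM = 0.322


@dataclass(frozen=True)
class ChargeFractions:
    f_hplus: float
    f_h0: float

    def __post_init__(self):
        if not (0.0 <= self.f_hplus <= 1.0 and 0.0 <= self.f_h0 <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
        if abs(self.f_hplus + self.f_h0 - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1")


def charge_fractions(sigma_loss: float, sigma_capture: float) -> ChargeFractions:
    """Equilibrium fractions f_H+ = sigma_L/(sigma_L + sigma_C)."""
    tot = sigma_loss + sigma_capture
    if tot <= 0.0:
        raise ZeroDivisionError("sigma_L + sigma_C must be positive")
    return ChargeFractions(sigma_loss / tot, sigma_capture / tot)


@dataclass
class ProjectileState:
    species: str                      # "H+" or "H0"
    energy_kev: float
    position_um: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self):
        if self.species not in ("H+", "H0"):
            raise ValueError(self.species)
        if self.energy_kev < 0:
            raise ValueError("negative energy")
        n = float(np.linalg.norm(self.direction))
        if abs(n - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")


@dataclass
class InteractionRecord:
    process: str          # ionization|excitation|capture|loss|elastic
    path_cm: float
    deposit_ev: float     # locally deposited energy
    secondary_ev: float   # ejected/stripped electron energy (0 if none)
    new_species: str


class PackedTables:
    """Flat array bundle shared by the numba kernels."""

    def __init__(self, tabs: list[XsTables]):
        n_e = len(tabs[0].e_grid)
        n_ek = tabs[0].ek_grid.shape[1]
        n_th = len(tabs[0].cos_nodes)
        n_x = len(tabs[0].elastic_x)
        m = len(tabs)
        for tb in tabs:
            if (len(tb.e_grid) != n_e or tb.ek_grid.shape[1] != n_ek
                    or len(tb.cos_nodes) != n_th):
                raise ValueError("all packed tables must share grid sizes")
        self.tabs = tabs
        self.log_e_grid = np.log(tabs[0].e_grid)
        self.log_tcs = np.full((m, 2, 4, n_e), -700.0)
        self.ek_grid = np.zeros((m, n_e, n_ek))
        self.ek_cdf = np.zeros((m, n_e, n_ek))
        self.binding = np.zeros((m, n_e))
        self.exc_cdf = np.zeros((m, n_e, 5))
        self.exc_w = tabs[0].exc_w_ev.copy()
        self.cos_nodes = tabs[0].cos_nodes.copy()
        self.theta_cdf = np.zeros((m, n_e, n_ek, n_th))
        self.el_x = tabs[0].elastic_x.copy()
        self.el_theta = np.zeros((m, n_e, n_x))
        self.nd = np.zeros(m)
        self.e_scale = np.zeros(m)
        self.elastic_mass = np.zeros(m)
        proc_idx = {"ionization": 0, "excitation": 1,
                    "capture": 2, "loss": 2, "elastic": 3}
        for i, tb in enumerate(tabs):
            for (spn, prn), arr in tb.tcs.items():
                sp = 0 if spn == "H+" else 1
                self.log_tcs[i, sp, proc_idx[prn]] = np.log(
                    np.maximum(arr, 1e-300))
            self.ek_grid[i] = tb.ek_grid
            self.ek_cdf[i] = tb.ek_cdf
            self.binding[i] = tb.binding_mean
            self.exc_cdf[i] = np.cumsum(tb.exc_weights, axis=1)
            self.theta_cdf[i] = tb.theta_cdf
            self.el_theta[i] = tb.elastic_theta
            self.nd[i] = tb.number_density
            self.e_scale[i] = tb.meta.get("electron_scale", 1.0)
            self.elastic_mass[i] = tb.elastic_mass


def pack_tables(tabs) -> PackedTables:
    if isinstance(tabs, XsTables):
        tabs = [tabs]
    return PackedTables(list(tabs))


def sample_interaction(state: ProjectileState, tab: XsTables,
                       rng: np.random.Generator,
                       include_elastic=False) -> InteractionRecord:
    """One free path + one interaction, following the energy-loss
    bookkeeping of the transport kernels (pure-python reference used by
    the unit tests)."""
    e_kev = state.energy_kev
    e_ev = e_kev * 1e3
    sp = state.species
    procs = (["ionization", "excitation",
              "capture" if sp == "H+" else "loss"]
             + (["elastic"] if include_elastic else []))
    sig = np.array([float(tab.interp_tcs(sp, p, e_kev)) for p in procs])
    tot = sig.sum()
    lam = 1.0 / (tab.number_density * tot)
    path = float(rng.exponential(lam))
    proc = procs[int(rng.choice(len(procs), p=sig / tot))]
    ie = int(np.argmin(np.abs(np.log(tab.e_grid) - math.log(e_kev))))
    new_species = sp
    secondary = 0.0
    if proc == "ionization":
        u = rng.random()
        ek = float(np.interp(u, tab.ek_cdf[ie], tab.ek_grid[ie]))
        deposit = float(tab.binding_mean[ie])
        secondary = ek
    elif proc == "excitation":
        iw = int(rng.choice(5, p=tab.exc_weights[ie]))
        deposit = float(tab.exc_w_ev[iw])
    elif proc == "capture":
        deposit = max(0.0, float(tab.binding_mean[ie])
                      + ME_MP * e_ev - H_BINDING_EV)
        new_species = "H0"
    elif proc == "loss":
        secondary = ME_MP * e_ev
        deposit = H_BINDING_EV
        new_species = "H+"
    else:
        deposit = 0.0
    return InteractionRecord(process=proc, path_cm=path,
                             deposit_ev=deposit, secondary_ev=secondary,
                             new_species=new_species)


def stationary_stopping_power(tab: XsTables, e_kev: float,
                              n_projectiles: int = 100_000,
                              seed: int = 1) -> dict:
    """Stationary-mode stopping power (keV/um) with statistical error.

    Both pure-species estimators and the charge-fraction-weighted total
    are returned.
    """
    if n_projectiles < 1000:
        raise ValueError("use at least 1e3 projectiles")
    pk = pack_tables(tab)
    out = kernels.stationary_sp(
        e_kev, n_projectiles, seed, 0, pk.log_e_grid, pk.log_tcs,
        pk.ek_grid, pk.ek_cdf, pk.binding, pk.exc_cdf, pk.exc_w, pk.nd[0])
    f_p, f_0 = charge_fractions_at(tab, e_kev)
    ev_cm_to_kev_um = 1e-3 * 1e-4
    sp_p = out[0] * ev_cm_to_kev_um
    sp_0 = out[1] * ev_cm_to_kev_um
    err = math.hypot(f_p * out[2], f_0 * out[3]) * ev_cm_to_kev_um
    return dict(sp_hplus=sp_p, sp_h0=sp_0,
                sp_total=f_p * sp_p + f_0 * sp_0,
                f_hplus=float(f_p), f_h0=float(f_0), err=err,
                err_hplus=out[2] * ev_cm_to_kev_um,
                err_h0=out[3] * ev_cm_to_kev_um)


def slowing_down_range(tab: XsTables, e0_kev: float,
                       n_histories: int = 1000, seed: int = 1,
                       correction_um: float = RANGE_CORRECTION_UM,
                       start_h0_fraction: float = 0.0) -> dict:
    """Mean slowing-down path length to the 10 keV cutoff, plus the
    fixed sub-cutoff correction; in um."""
    if e0_kev <= 10.0:
        raise ValueError("start energy must exceed the 10 keV cutoff")
    pk = pack_tables(tab)
    mean_cm, err_cm = kernels.slowing_down_path(
        e0_kev, n_histories, seed, 0, pk.log_e_grid, pk.log_tcs,
        pk.ek_grid, pk.ek_cdf, pk.binding, pk.exc_cdf, pk.exc_w,
        pk.nd[0], start_h0_fraction)
    return dict(range_um=mean_cm * 1e4 + correction_um,
                err_um=err_cm * 1e4, path_um=mean_cm * 1e4)
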