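"""Cross-section tables for transport.

`build_tables` evaluates every interaction channel of a medium on a
log-spaced incident-energy grid and packs total cross sections plus the
sampling marginals the Monte Carlo needs:

* H+ : CDW-EIS ionization (TCS + ejected-energy CDF + ejection-angle CDF
  + mean binding), Miller-Green excitation (per-state weights), CDW-EIS
  electron capture, classical elastic scattering;
* H0 : ionization (screened effective-charge scaling of the H+ table),
  Miller-Green excitation (3/4-a rule), Miller-Green electron loss,
  elastic scattering (empirical H0/H+ ratio).

Composite media combine per-component cross sections with the
stoichiometric counts of the transported "molecule" (e.g. the hydrated
nucleotide), so that n_medium * sigma_medium = sum_i n_i sigma_i.

The quantum channels are costly, and across the DNA components many
molecular orbitals share an atomic label with smoothly varying binding
energy; each label is therefore evaluated on a few binding-energy nodes
and per-MO values interpolated in log|eps| (exact when a label occurs at
a single binding energy, as for water).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import cdweis, elastic, semiempirical
from .constants import HARTREE_EV
from .targets import (CompositeMedium, MolecularTarget, build_dry_dna_medium,
                      build_hydrated_dna_medium, build_water_medium,
                      number_density)

__all__ = ["XsTables", "build_tables", "medium_by_name", "total_tcs",
           "charge_fractions_at", "imfp"]

SPECIES = ("H+", "H0")
PROCESSES = {"H+": ("ionization", "excitation", "capture", "elastic"),
             "H0": ("ionization", "excitation", "loss", "elastic")}

EXC_W_EV = np.array([8.17, 10.13, 11.31, 12.91, 14.50])


@dataclass
class XsTables:
    """Per-medium cross sections and sampling marginals on an energy grid.

    All TCS are per medium molecule in cm^2; energies in keV on
    ``e_grid``; sampling grids in eV (ejected electrons) and radians
    (elastic angles).
    """

    medium: str
    density: float
    molar_mass: float
    e_grid: np.ndarray                       # (n_e,) keV
    tcs: dict = field(default_factory=dict)  # (species, process) -> (n_e,)
    # ionization sampling
    ek_grid: np.ndarray | None = None        # (n_e, n_ek) eV
    ek_cdf: np.ndarray | None = None         # (n_e, n_ek)
    binding_mean: np.ndarray | None = None   # (n_e,) eV
    cos_nodes: np.ndarray | None = None      # (n_th,)
    theta_cdf: np.ndarray | None = None      # (n_e, n_ek, n_th)
    # excitation sampling
    exc_weights: np.ndarray | None = None    # (n_e, 5) normalized
    exc_w_ev: np.ndarray = field(default_factory=lambda: EXC_W_EV.copy())
    # elastic sampling: theta(x rho_c), x in [0,1]; recoil via target mass
    elastic_x: np.ndarray | None = None      # (n_x,)
    elastic_theta: np.ndarray | None = None  # (n_e, n_x) CM rad
    elastic_mass: float = 18.015             # amu of the elastic scatterer
    meta: dict = field(default_factory=dict)

    @property
    def number_density(self) -> float:
        from .constants import AVOGADRO
        return AVOGADRO * self.density / self.molar_mass

    def interp_tcs(self, species: str, process: str, e_kev):
        """Log-log linear interpolation of a TCS on the grid."""
        y = self.tcs[(species, process)]
        return _loglog_interp(self.e_grid, y, e_kev)


def _loglog_interp(xg, yg, x):
    x = np.asarray(x, dtype=float)
    lo = math.log(xg[0])
    hi = math.log(xg[-1])
    lx = np.clip(np.log(x), lo, hi)
    safe = np.where(yg > 0, yg, 1e-300)
    ly = np.interp(lx, np.log(xg), np.log(safe))
    out = np.exp(ly)
    out = np.where(out <= 1e-250, 0.0, out)
    return out if out.ndim else float(out)


def _stoichiometry(medium: CompositeMedium) -> list[tuple[MolecularTarget, float]]:
    """Counts nu_i of each component in one medium molecule."""
    out = []
    for tgt, w in medium.components:
        out.append((tgt, w * medium.molar_mass / tgt.molar_mass))
    return out


def _label_eps_nodes(targets, n_nodes=5):
    """Binding-energy nodes per atomic label across all targets."""
    eps_by_label: dict[str, set] = {}
    for tgt in targets:
        for eps, lab, occ in cdweis.target_channels(tgt):
            eps_by_label.setdefault(lab, set()).add(eps)
    nodes = {}
    for lab, eps_set in eps_by_label.items():
        eps_arr = np.array(sorted(eps_set))
        if len(eps_arr) <= 3:
            nodes[lab] = eps_arr
        else:
            nodes[lab] = -np.geomspace(-eps_arr[-1], -eps_arr[0],
                                       n_nodes)[::-1]
    return nodes


class _ChannelInterp:
    """Per-label ionization (or capture) results on eps nodes with
    log-binding interpolation of TCS, SDCS and angle marginals."""

    def __init__(self, nodes_eps, results):
        self.eps = np.asarray(nodes_eps)      # ascending (more negative first)
        self.results = results                # list aligned with eps

    def at(self, eps):
        if len(self.eps) == 1:
            return self.results[0]
        x = math.log(-eps)
        xs = np.log(-self.eps)
        # xs descending in -eps? self.eps ascending (eps negative):
        # eps[-1] closest to zero -> -eps descending -> xs descending
        order = np.argsort(xs)
        xs_o = xs[order]
        idx = np.searchsorted(xs_o, x)
        idx = min(max(idx, 1), len(xs_o) - 1)
        i0, i1 = order[idx - 1], order[idx]
        t = (x - xs_o[idx - 1]) / (xs_o[idx] - xs_o[idx - 1])
        t = min(max(t, 0.0), 1.0)
        r0, r1 = self.results[i0], self.results[i1]
        return tuple((1.0 - t) * a + t * b for a, b in zip(r0, r1))


def _ion_label_tables(e_kev, labels_nodes, quad):
    """Evaluate ionization for every (label, eps node) at one energy."""
    out = {}
    for lab, eps_nodes in labels_nodes.items():
        results = []
        for eps in eps_nodes:
            tcs, ek, sdcs, ct, grid = cdweis.orbital_ionization(
                e_kev, float(eps), lab, **quad)
            results.append((np.array([tcs]), sdcs, grid))
        out[lab] = _ChannelInterp(eps_nodes, results)
    return out


def _cap_label_tables(e_kev, labels_nodes, quad):
    out = {}
    for lab, eps_nodes in labels_nodes.items():
        results = []
        for eps in eps_nodes:
            s = cdweis.tcs_capture_orbital(e_kev, float(eps), lab,
                                           n_eta=quad.get("n_eta", 24),
                                           n_phi=quad.get("n_phi", 8),
                                           n_mid=quad.get("n_mid", 64))
            results.append((np.array([s]),))
        out[lab] = _ChannelInterp(eps_nodes, results)
    return out


def build_tables(medium: CompositeMedium, n_e: int = 16,
                 e_min_kev: float = 10.0, e_max_kev: float = 1.0e5,
                 n_ek: int = 16, n_theta: int = 10, n_eta: int = 20,
                 n_phi: int = 6, n_mid: int = 48,
                 theta_cut_lab_mrad: float = 0.1,
                 h0_screening=(0.35, 2.0),
                 include_elastic: bool = True,
                 progress: bool = False) -> XsTables:
    """Tabulate every process for ``medium`` on a log energy grid."""
    e_grid = np.geomspace(e_min_kev, e_max_kev, n_e)
    stoich = _stoichiometry(medium)
    targets = [t for t, _ in stoich]
    labels_nodes = _label_eps_nodes(targets)
    quad = dict(n_ek=n_ek, n_theta=n_theta, n_eta=n_eta, n_phi=n_phi,
                n_mid=n_mid)

    tab = XsTables(medium=medium.name, density=medium.density,
                   molar_mass=medium.molar_mass, e_grid=e_grid)
    n_th = n_theta
    tab.cos_nodes = np.polynomial.legendre.leggauss(n_th)[0]
    tab.ek_grid = np.empty((n_e, n_ek))
    tab.ek_cdf = np.empty((n_e, n_ek))
    tab.binding_mean = np.empty(n_e)
    tab.theta_cdf = np.empty((n_e, n_ek, n_th))
    tab.exc_weights = np.empty((n_e, 5))
    for key in [("H+", "ionization"), ("H+", "excitation"),
                ("H+", "capture"), ("H+", "elastic"),
                ("H0", "ionization"), ("H0", "excitation"),
                ("H0", "loss"), ("H0", "elastic")]:
        tab.tcs[key] = np.zeros(n_e)

    ct_w = np.polynomial.legendre.leggauss(n_th)[1]

    for ie, e_kev in enumerate(e_grid):
        ion = _ion_label_tables(e_kev, labels_nodes, quad)
        cap = _cap_label_tables(e_kev, labels_nodes, quad)
        ek_h, jac = cdweis._ek_nodes(e_kev, n_ek)
        ek_ev = ek_h * HARTREE_EV

        sig_ion = 0.0
        sig_cap = 0.0
        sdcs_sum = np.zeros(n_ek)
        ddcs_sum = np.zeros((n_ek, n_th))
        eps_weighted = 0.0
        exc_sum = np.zeros(5)
        sig_loss = 0.0
        for tgt, nu_count in stoich:
            for eps, lab, occ in cdweis.target_channels(tgt):
                w = nu_count * occ
                tcs_a, sdcs, grid = ion[lab].at(eps)
                sig_ion += w * float(tcs_a[0])
                sdcs_sum += w * sdcs
                ddcs_sum += w * grid
                eps_weighted += w * float(tcs_a[0]) * abs(eps)
                (cap_a,) = cap[lab].at(eps)
                sig_cap += w * float(cap_a[0])
            if tgt.name == "water":
                exc = semiempirical.excitation_tcs_water(e_kev, "H+")
                sig_loss += nu_count * semiempirical.eloss_tcs(e_kev)
            else:
                exc = semiempirical.excitation_tcs_dna(e_kev, tgt.name,
                                                       "H+")
                sig_loss += nu_count * semiempirical.eloss_tcs(
                    e_kev, tgt.name)
            exc_sum += nu_count * np.asarray(exc)

        tab.tcs[("H+", "ionization")][ie] = sig_ion
        tab.tcs[("H+", "capture")][ie] = sig_cap
        tab.tcs[("H+", "excitation")][ie] = exc_sum.sum()
        tab.tcs[("H0", "loss")][ie] = sig_loss
        zeff2 = cdweis.h0_effective_charge_sq(e_kev, *h0_screening)
        tab.tcs[("H0", "ionization")][ie] = zeff2 * sig_ion
        # H0 excitation: a -> (3/4) a changes each state by (3/4)^Omega
        h0_exc = exc_sum * np.array(
            [semiempirical.H0_A_FACTOR ** om
             for om in (0.85, 0.88, 0.88, 0.78, 0.78)])
        tab.tcs[("H0", "excitation")][ie] = h0_exc.sum()
        tab.exc_weights[ie] = (exc_sum / exc_sum.sum()
                               if exc_sum.sum() > 0 else np.full(5, 0.2))
        tab.binding_mean[ie] = (eps_weighted / sig_ion
                                if sig_ion > 0 else 15.0)

        # ejected-energy CDF on the log grid (trapezoid increments)
        pdf = np.maximum(sdcs_sum, 0.0)
        inc = np.zeros(n_ek)
        inc[1:] = 0.5 * (pdf[1:] + pdf[:-1]) * np.diff(ek_ev)
        cdf = np.cumsum(inc)
        tab.ek_grid[ie] = ek_ev
        tab.ek_cdf[ie] = cdf / cdf[-1] if cdf[-1] > 0 else np.linspace(
            0, 1, n_ek)
        # polar-angle CDF per ejected energy (over Gauss cos nodes)
        wgrid = np.maximum(ddcs_sum, 0.0) * ct_w[None, :]
        ccdf = np.cumsum(wgrid, axis=1)
        tot = ccdf[:, -1:]
        tab.theta_cdf[ie] = np.where(tot > 0, ccdf / tot,
                                     np.linspace(0, 1, n_th)[None, :])

    if include_elastic:
        _add_elastic(tab, medium, stoich, theta_cut_lab_mrad)
    electron_scale = sum(nu * t.electron_count for t, nu in stoich) / 10.0
    tab.meta = dict(n_ek=n_ek, n_theta=n_theta, n_eta=n_eta, n_phi=n_phi,
                    n_mid=n_mid, theta_cut_lab_mrad=theta_cut_lab_mrad,
                    h0_screening=list(h0_screening),
                    electron_scale=electron_scale)
    return tab


def _add_elastic(tab: XsTables, medium, stoich, theta_cut_lab_mrad):
    """Classical elastic scattering on the water component (the DNA
    elastic channel is disabled by default), with the empirical H0/H+
    ratio for neutral hydrogen."""
    nu_water = 0.0
    for tgt, nu_count in stoich:
        if tgt.name == "water":
            nu_water = nu_count
    n_x = 48
    # log-spaced rho^2-fraction grid: the hard-collision core (tiny
    # fractions, large angles) must be resolved or the interpolated
    # recoil energy is grossly overestimated
    tab.elastic_x = np.concatenate([[0.0],
                                    np.geomspace(1e-8, 1.0, n_x - 1)])
    tab.elastic_theta = np.zeros((len(tab.e_grid), n_x))
    if nu_water == 0.0:
        return
    m_t = 18.015
    # lab cutoff -> CM (small-angle conversion factor 1 + m_p/M)
    theta_cut_cm = theta_cut_lab_mrad * 1e-3 * (1.0 + 1.008 / m_t)
    pot = elastic.water_potential()
    for ie, e_kev in enumerate(tab.e_grid):
        e_cm = elastic.cm_energy_hartree(e_kev, m_t)
        dt = elastic.DeflectionTable(pot, e_cm, n_rho=96)
        rho_c = float(dt.rho_of_theta(theta_cut_cm))
        sigma = math.pi * rho_c ** 2 * elastic.A0_SQ_CM2
        tab.tcs[("H+", "elastic")][ie] = nu_water * sigma
        tab.tcs[("H0", "elastic")][ie] = (
            nu_water * sigma * elastic.h0_elastic_ratio(e_kev))
        # sampling: theta at rho = sqrt(u) rho_c  (P(>theta) = (rho/rhoc)^2)
        tab.elastic_theta[ie] = np.interp(
            np.sqrt(tab.elastic_x) * rho_c, dt.rho, dt.theta)
    tab.elastic_mass = m_t


def with_density(tab: XsTables, density: float,
                 name: str | None = None) -> XsTables:
    """Clone a table set with the bulk density rescaled (the per-molecule
    cross sections are unchanged; only the number density follows rho)."""
    import copy
    t2 = copy.deepcopy(tab)
    t2.density = density
    t2.medium = name or f"{tab.medium}-{density:g}"
    return t2


def medium_by_name(name: str) -> CompositeMedium:
    """'water', 'water-1.29', 'dna' or 'dry-dna'."""
    if name == "water":
        return build_water_medium()
    if name.startswith("water-"):
        return build_water_medium(float(name.split("-", 1)[1]))
    if name == "dna":
        return build_hydrated_dna_medium()
    if name == "dry-dna":
        return build_dry_dna_medium()
    raise KeyError(f"unknown medium {name!r}")


# ----------------------------------------------------------------------
# macroscopic estimators (Eqs. of the transport model)
# ----------------------------------------------------------------------

def charge_fractions_at(tab: XsTables, e_kev):
    """Equilibrium fractions f_H+ = sigma_L/(sigma_L+sigma_C)."""
    sl = tab.interp_tcs("H0", "loss", e_kev)
    sc = tab.interp_tcs("H+", "capture", e_kev)
    tot = sl + sc
    if np.any(np.asarray(tot) <= 0):
        raise ZeroDivisionError("sigma_L + sigma_C vanished")
    return sl / tot, sc / tot


def total_tcs(tab: XsTables, e_kev, include_elastic=False):
    """Charge-fraction-weighted total inelastic TCS (Eq. sigma_T)."""
    f_p, f_0 = charge_fractions_at(tab, e_kev)
    procs_p = ["ionization", "excitation", "capture"]
    procs_0 = ["ionization", "excitation", "loss"]
    if include_elastic:
        procs_p.append("elastic")
        procs_0.append("elastic")
    s_p = sum(tab.interp_tcs("H+", p, e_kev) for p in procs_p)
    s_0 = sum(tab.interp_tcs("H0", p, e_kev) for p in procs_0)
    return f_p * s_p + f_0 * s_0


def imfp(tab: XsTables, e_kev, unit="nm"):
    """Total inelastic mean free path 1/(n sigma_T)."""
    n = tab.number_density
    lam_cm = 1.0 / (n * total_tcs(tab, e_kev))
    if unit == "nm":
        return lam_cm * 1.0e7
    if unit == "um":
        return lam_cm * 1.0e4
    if unit == "cm":
        return lam_cm
    raise ValueError(unit)
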