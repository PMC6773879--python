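"""Physical constants and unit conversions.

Energies are stored in eV (or keV where noted) at module boundaries and
converted to hartree atomic units inside the quantum formulas; lengths are
kept in cm for cross-section bookkeeping and in um for geometry.
"""

HARTREE_EV = 27.211386245988
BOHR_CM = 5.29177210903e-9
BOHR_NM = 5.29177210903e-2
AVOGADRO = 6.02214076e23
# projectile/electron mass ratio (proton)
MP_ME = 1836.15267343
ME_MP = 1.0 / MP_ME
RYDBERG_EV = HARTREE_EV / 2.0
A0_SQ_CM2 = BOHR_CM ** 2  # 2.800e-17 cm^2

# hydrogen 1s binding energy, used in capture/loss bookkeeping
H_BINDING_EV = 13.605693122994

EV_PER_KEV = 1.0e3
KEV_PER_MEV = 1.0e3
CM_PER_UM = 1.0e-4
NM_PER_CM = 1.0e7
GRAY_PER_EV_PER_KG = 1.602176634e-19


def velocity_au(e_inc_kev: float) -> float:
    """Projectile speed in atomic units for a proton of kinetic energy
    ``e_inc_kev`` (non-relativistic; v = 1 a.u. at 24.98 keV/u)."""
    e_h = e_inc_kev * EV_PER_KEV / HARTREE_EV
    return (2.0 * e_h / MP_ME) ** 0.5


def electron_momentum_au(e_k_ev: float) -> float:
    """Ejected-electron momentum k (a.u.) from its energy in eV."""
    return (2.0 * e_k_ev / HARTREE_EV) ** 0.5
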