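"""Miller-Green semi-empirical total cross sections.

The analytic form

    sigma(E) = a0 * (Z a)^Omega * (E - W)^nu / (J^(Omega+nu) + E^(Omega+nu))

with a0 = 1e-16 cm^2 covers three ingredients of the H+/H0 transport model:

* proton-impact electronic excitation of water (five excited states, the
  Dingfelder parameter set),
* neutral-hydrogen excitation, identical except that the parameter ``a`` is
  3/4 of the proton value,
* the H0 electron-loss cross section (single channel, keV-scale a and J).

DNA components reuse the water fits rescaled by the electron-count ratio
Z'/Z (loss) or by Z'/Z-scaled ``a`` (excitation); both are exact analytic
ratios tested to machine precision.

All parameters are loaded from the packaged ``semiempirical.yaml`` so that
they can be overridden at tabulation time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np
import yaml

from .targets import DNA_COMPONENTS

A0_CM2 = 1.0e-16
H0_A_FACTOR = 0.75  # neutral-hydrogen rule: a -> (3/4) a

__all__ = [
    "MillerGreenParams",
    "miller_green_tcs",
    "excitation_tcs_water",
    "excitation_tcs_dna",
    "eloss_tcs",
    "excitation_states_water",
    "mean_excitation_energy",
    "ELOSS_W_EV",
]


@dataclass(frozen=True)
class MillerGreenParams:
    """Parameters of the Miller-Green analytic cross section.

    ``a``, ``J`` and ``W`` must share one energy unit (eV here); ``E`` is
    converted to that unit before evaluation.
    """

    name: str
    Z: float
    a_ev: float
    J_ev: float
    W_ev: float
    Omega: float
    nu: float

    def __post_init__(self):
        if min(self.a_ev, self.J_ev, self.W_ev) < 0:
            raise ValueError("a, J, W must be non-negative")
        if self.Omega <= 0 or self.nu <= 0:
            raise ValueError("Omega, nu must be positive")


def _load_params() -> dict:
    text = resources.files("protrack.data").joinpath(
        "semiempirical.yaml").read_text()
    return yaml.safe_load(text)


_PARAMS = None


def _params() -> dict:
    global _PARAMS
    if _PARAMS is None:
        _PARAMS = _load_params()
    return _PARAMS


def miller_green_tcs(e_inc_kev, params: MillerGreenParams):
    """Miller-Green cross section in cm^2; 0 at and below threshold W."""
    e_ev = np.asarray(e_inc_kev, dtype=float) * 1e3
    Omega = params.Omega
    nu = params.nu
    num = (params.Z * params.a_ev) ** Omega * np.where(
        e_ev > params.W_ev, np.maximum(e_ev - params.W_ev, 0.0), 0.0) ** nu
    den = params.J_ev ** (Omega + nu) + e_ev ** (Omega + nu)
    out = A0_CM2 * num / den
    return out if out.ndim else float(out)


def excitation_states_water(projectile: str = "H+") -> list[MillerGreenParams]:
    """The five excitation channels of water for H+ or H0 impact."""
    rows = []
    for row in _params()["water_excitation"]:
        p = MillerGreenParams(name=row["state"], Z=10,
                              a_ev=row["a_ev"], J_ev=row["J_ev"],
                              W_ev=row["W_ev"], Omega=row["Omega"],
                              nu=row["nu"])
        if projectile == "H0":
            p = replace(p, a_ev=H0_A_FACTOR * p.a_ev)
        elif projectile != "H+":
            raise ValueError(f"unknown projectile {projectile!r}")
        rows.append(p)
    return rows


def excitation_tcs_water(e_inc_kev, projectile: str = "H+"):
    """Per-state excitation cross sections (cm^2), five states."""
    return [miller_green_tcs(e_inc_kev, p)
            for p in excitation_states_water(projectile)]


def excitation_tcs_dna(e_inc_kev, component: str, projectile: str = "H+"):
    """Per-state excitation cross sections for one DNA component.

    The packaged DNA parameters are the water set with ``a`` scaled by
    Z'/Z (provisional defaults, overridable in ``semiempirical.yaml``).
    """
    if component not in DNA_COMPONENTS:
        raise KeyError(f"unknown DNA component {component!r}")
    scale = DNA_COMPONENTS[component] / 10.0
    out = []
    for p in excitation_states_water(projectile):
        out.append(miller_green_tcs(
            e_inc_kev, replace(p, name=f"{component}:{p.name}",
                               a_ev=scale * p.a_ev)))
    return out


def _eloss_params() -> MillerGreenParams:
    row = _params()["electron_loss"]
    return MillerGreenParams(name="eloss", Z=10,
                             a_ev=row["a_kev"] * 1e3, J_ev=row["J_kev"] * 1e3,
                             W_ev=row["W_ev"], Omega=row["Omega"],
                             nu=row["nu"])


ELOSS_W_EV = 12.6  # water outermost binding energy, the loss threshold


def eloss_tcs(e_inc_kev, target: str = "water"):
    """H0 electron-loss cross section (cm^2).

    Water uses the Miller-Green fit directly; DNA components rescale the
    water value by the electron-count ratio Z'/10.
    """
    sigma_w = miller_green_tcs(e_inc_kev, _eloss_params())
    if target == "water":
        return sigma_w
    if target in DNA_COMPONENTS:
        return sigma_w * (DNA_COMPONENTS[target] / 10.0)
    raise KeyError(f"unknown target {target!r}")


def mean_excitation_energy(e_inc_kev, projectile: str = "H+",
                           target: str = "water") -> float:
    """Cross-section-weighted mean excitation threshold (eV) at E_inc."""
    if target == "water":
        sigmas = excitation_tcs_water(e_inc_kev, projectile)
    else:
        sigmas = excitation_tcs_dna(e_inc_kev, target, projectile)
    ws = [p.W_ev for p in excitation_states_water("H+")]
    tot = float(sum(sigmas))
    if tot == 0.0:
        return 0.0
    return float(sum(w * s for w, s in zip(ws, sigmas)) / tot)
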