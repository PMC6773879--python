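"""Generate the synthetic per-MO tables for the five DNA components.

The published transport model describes each DNA component by N molecular
orbitals (35/29/39/33/48 for adenine/cytosine/guanine/thymine/
sugar-phosphate) obtained from an RHF/3-21G optimization with Mulliken
populations, rescaled so the Koopmans HOMO energy matches experiment.  The
numeric orbital data themselves are not published, so this script builds
SYNTHETIC stand-in tables that preserve everything the model states:

  * the MO count and the electron count (every MO doubly occupied),
  * the atomic composition (core MOs are atom-localized 1s/2s/2p shells at
    typical XPS energies; valence MOs mix the valence atomic orbitals),
  * per-MO population sums of exactly 2,
  * per-atom valence electron budgets (iterative proportional fitting),
  * the experimental Koopmans first ionization energy at the HOMO, with a
    smooth valence energy ladder below it.

Deterministic; writes src/protrack/data/dna_*_synthetic.tsv.
"""

from __future__ import annotations

import pathlib

import numpy as np

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "protrack" / "data"

# atom -> (core shells with energies eV, valence orbitals with electron count)
CORE_SHELLS = {
    "C": [("C_1s", -305.0)],
    "N": [("N_1s", -425.0)],
    "O": [("O_1s", -540.0)],
    "P": [("P_1s", -2150.0), ("P_2s", -200.0),
          ("P_2p", -145.0), ("P_2p", -145.0), ("P_2p", -145.0)],
}
VALENCE = {
    "C": [("C_2s", 2.0), ("C_2p", 2.0)],
    "N": [("N_2s", 2.0), ("N_2p", 3.0)],
    "O": [("O_2s", 2.0), ("O_2p", 4.0)],
    "H": [("H_1s", 1.0)],
    "P": [("P_3s", 2.0), ("P_3p", 3.0)],
}

# composition, MO count, experimental first ionization energy (eV)
COMPONENTS = {
    "adenine": (dict(C=5, H=5, N=5), 35, 8.44),
    "cytosine": (dict(C=4, H=5, N=3, O=1), 29, 8.94),
    "guanine": (dict(C=5, H=5, N=5, O=1), 39, 8.24),
    "thymine": (dict(C=5, H=6, N=2, O=2), 33, 9.14),
    # composition chosen so Z = 96 with every MO doubly occupied
    "sugar_phosphate": (dict(C=5, H=11, O=5, P=1), 48, 10.51),
}

VALENCE_BOTTOM_EV = -38.0   # deepest valence MO energy


def build_component(name, atoms, n_mo, ip_ev):
    rows = []
    n_electrons = 0
    # --- core MOs -------------------------------------------------------
    for atom, count in atoms.items():
        n_electrons += count * {"C": 6, "N": 7, "O": 8, "H": 1, "P": 15}[atom]
        for _ in range(count):
            for label, eps in CORE_SHELLS.get(atom, []):
                rows.append((label.lower() + "_core", eps, [(label, 2.0)]))
    n_core = len(rows)
    n_val = n_mo - n_core
    # --- valence electron pools ----------------------------------------
    pools = {}
    for atom, count in atoms.items():
        for label, electrons in VALENCE[atom]:
            pools[label] = pools.get(label, 0.0) + count * electrons
    pool_total = sum(pools.values())
    assert abs(pool_total - 2.0 * n_val) < 1e-9, (name, pool_total, 2 * n_val)

    # valence energy ladder: HOMO at -ip, deeper levels stretch to the
    # valence bottom with a mild power law (denser near the top, as in
    # typical organic-molecule spectra)
    j = np.arange(n_val, dtype=float)
    frac = (j / max(n_val - 1, 1)) ** 1.35
    energies = -ip_ev + (VALENCE_BOTTOM_EV + ip_ev) * frac  # j=0 -> HOMO

    # mixing weights: s-type orbitals weighted toward deep MOs, p/H toward
    # shallow ones; then iterative proportional fitting so each MO sums to
    # 2 and each atomic pool is exhausted
    labels = sorted(pools)
    depth = frac[:, None]                       # 0 (HOMO) .. 1 (deep)
    w = np.empty((n_val, len(labels)))
    for idx, lab in enumerate(labels):
        s_like = lab.endswith("s") and not lab.startswith("H")
        profile = (0.25 + 1.5 * depth[:, 0]) if s_like else (1.25 - 0.75 * depth[:, 0])
        w[:, idx] = pools[lab] * profile
    for _ in range(200):
        w *= (2.0 / w.sum(axis=1))[:, None]
        w *= np.array([pools[lab] for lab in labels]) / w.sum(axis=0)
    w *= (2.0 / w.sum(axis=1))[:, None]

    for i in range(n_val):
        comps = [(labels[idx], w[i, idx]) for idx in range(len(labels))
                 if w[i, idx] > 1e-3]
        # renormalize after dropping negligible entries
        s = sum(c for _, c in comps)
        comps = [(lab, c * 2.0 / s) for lab, c in comps]
        rows.append((f"v{n_val - i}", energies[i], comps))

    total_occ = sum(c for _, _, comps in rows for _, c in comps)
    assert abs(total_occ - n_electrons) < 0.02 * n_electrons, (
        name, total_occ, n_electrons)
    assert len(rows) == n_mo
    return rows, n_electrons


def main():
    for name, (atoms, n_mo, ip) in COMPONENTS.items():
        rows, z = build_component(name, atoms, n_mo, ip)
        # order: HOMO first is irrelevant; sort deep -> shallow for readability
        rows.sort(key=lambda r: r[1])
        path = OUT / f"dna_{name}_synthetic.tsv"
        with open(path, "w") as fh:
            fh.write(f"# SYNTHETIC per-MO table for {name} (Z={z}, "
                     f"{n_mo} MOs).\n")
            fh.write("# Stand-in for an unpublished RHF/3-21G + Mulliken "
                     "analysis; preserves MO count,\n# electron count, "
                     "atomic composition and the experimental Koopmans "
                     "HOMO energy.\n")
            for label, eps, comps in rows:
                comp_s = ";".join(f"{lab}:{occ:.4f}" for lab, occ in comps)
                fh.write(f"{label}\t{eps:.2f}\t{comp_s}\n")
        print(path.name, "Z =", z, "MOs =", n_mo)


if __name__ == "__main__":
    main()
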