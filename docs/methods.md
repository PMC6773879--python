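# Methods

This note records the physical models, the numerical choices and the
known limitations of the package, in the spirit of a model-description
paper: everything an informed user needs to judge what the computed
numbers mean.  No empirical result is stated here that the test suite
or `scripts/acceptance.py` does not itself compute.

## Targets

Water vapor is described in the CNDO picture: five molecular orbitals
with the standard populations and binding energies (1a1 at −539.7 eV
through 1b1 at −12.6 eV), each expanded over atomic components (O 1s,
O 2s, O 2p, H 1s) with effective occupation numbers that sum to the ten
electrons.  The five DNA components (adenine, cytosine, guanine,
thymine, sugar–phosphate) carry 35/29/39/33/48 doubly occupied MOs and
70/58/78/66/96 electrons.  Their numeric orbital tables are **synthetic
stand-ins** (see `scripts/make_dna_tables.py`): per-MO binding energies
and Mulliken-style populations are generated to preserve the documented
MO counts, the atomic compositions, per-MO populations of 2, per-atom
valence budgets and the experimental Koopmans HOMO energies, with a
smooth valence energy ladder down to −38 eV.  They are *not* the result
of a quantum-chemistry calculation; any ab-initio regeneration that
preserves those constraints can replace the files without code changes.

The hydrated-DNA bulk medium is the equivalent nucleotide 0.58 (A–T) +
0.42 (C–G) + 2 sugar–phosphates + 18 H₂O (A_mol = 947.8 g/mol, ρ =
1.29 g/cm³); the dry variant removes the water (662 g/mol, 1.35 g/cm³).
Mass fractions reproduce the printed percentages to 0.2 points by
direct stoichiometric arithmetic, which the tests verify.

## CDW-EIS ionization and capture

The prior-form transition amplitude is evaluated in the straight-line
impact-parameter approximation.  The full derivation implemented here
factorizes the amplitude exactly into a target-side and a
projectile-side Fourier factor at momentum q = (η, Δε/v):

* target side: Nordsieck's closed form for
  ∫ d³x e^{iQ·x} e^{−αx}/x · ₁F₁(iλ;1;i(kx+k·x)) and its parameter
  derivatives (evaluated by high-order finite differences of the closed
  form, relative accuracy ~1e−7), from which matrix elements of any
  Slater monomial x_j r^g e^{−ζr} follow;
* projectile side: the eikonal-power integrals
  ∫ d³s e^{iQ·s} e^{−βs}/s (vs+v·s)^{−iν−1} ₁F₁(iζ;1;i(ps+p·s)),
  reduced by a Feynman representation of the eikonal power to
  one-dimensional integrals of Nordsieck forms whose coefficients are
  linear in the integration variable; an analytic small-τ head, a
  Gauss–Legendre middle section in log τ and an Abel-regularized
  power-law tail give ~1e−6 accuracy.  (The τ-integral converges only
  in the Abel sense, which is the limit of the absolutely convergent
  screened integral; the branch of the complex powers is principal,
  which a short argument in `nordsieck.py` justifies.)

Both routes of the dual-route design exist: this closed-form route and
a brute-force 3-D spatial quadrature
(`cdweis.amplitude_factors_numeric`).  Because the eikonal integral is
conditionally convergent, the two routes are compared at a finite
regularization (screening β, power softening δ) where both are
absolutely convergent — they agree to ~1e−5 — and the physical limit is
exercised by continuity scans within the analytic route.

**Initial states.**  The active electron starts from a compact
single-zeta Slater orbital with Clementi–Raimondi-style exponents and is
ejected into a hydrogenic continuum of effective charge Z̃ = n√(−2ε)
matched to the molecular binding energy.  These are eigenstates of
different model Hamiltonians, so their overlap S₀ is not exactly zero;
the continuum is therefore Gram–Schmidt-orthogonalized against the
occupied orbital, which replaces T₀ by T₀ − S₀·B₀(q) (B₀ the Fourier
transform of |φ_i|²) and correspondingly corrects T₁.  Without this the
spurious monopole dominates soft collisions (a flat, unphysical TCS
tail).  A fully consistent hydrogenic pair (bound eigenstate of the
same effective charge) was evaluated as an alternative: it satisfies
the first-Born limit exactly but its binding-matched valence orbitals
are far too diffuse, tripling the peak ionization cross section and
overestimating the Bragg-peak stopping power by ~40%; the compact-STO
model was adopted for ionization.  **Electron capture** (to H(1s); the
n = 2 shell optionally via the high-velocity 1/n³ scaling, off by
default) uses the consistent hydrogenic pair, which is the standard
choice for rearrangement amplitudes and reproduces the measured
equilibrium-charge-fraction systematics best.  Capture remains ~2×
above experiment below ~50 keV, a known property of this approximation.

**First-Born limit.**  The Born route shares only the target-side
factor.  On the exactly solvable hydrogenic channel (p + H(1s)) the
CDW-EIS/Born TCS ratio converges to 1.000 above 5 MeV and the absolute
Born TCS reproduces the Bates–Griffing Bethe asymptote at 1 MeV to
better than 1%.  For compact-STO molecular channels the prior-form
amplitude with a non-eigen initial state converges instead to a
constant ≈2× the orthogonalized Born — the neglected (H_T − ε)φ_i
residual of the prior perturbation — so the Born-convergence invariant
is asserted on the hydrogenic channel.  This residual, not the
orthogonalization, is also the main reason the molecular ionization TCS
exceeds measurements by ~2–2.5× around the Bragg peak while the
*energy-weighted* integral (the stopping power) is inflated by only
~15% there and is accurate at and above 1 MeV (26 keV/µm at 1 MeV,
matching standard tabulations).

**Known quantitative consequences** (all measured by the acceptance
script): the stationary SP maximum of water comes out ≈114 keV/µm at
70 keV (reference value 97.5, i.e. ≈+16%); ranges are correspondingly
~10–15% short below 1 MeV, moving the cell-phantom deposit threshold
from ≈225 to ≈275 keV and the deposit peak from 550 to ≈600–650 keV.
Ratios between media (IMFP, range, nuclear dose) are much less
sensitive because both media share the model bias.

## Semi-empirical channels

Proton-impact excitation of water uses the five-state Miller–Green
parameterization (thresholds 8.17–14.50 eV); the neutral-hydrogen
variant multiplies the `a` parameter by 3/4, which changes each state
by exactly (3/4)^Ω.  The typeset source of the "Ryd C+D" `a` value is
ambiguous (1692 vs 692); 1692 is packaged, overridable in
`data/semiempirical.yaml`.  Electron loss of H⁰ uses the single-channel
fit (a = 79.3 keV, J = 27.7 keV, Ω = 0.652, ν = 0.943, threshold taken
as water's outermost binding energy 12.6 eV); DNA components rescale
the water loss by Z′/10 and the excitation `a` by the same
electron-count ratio (provisional defaults).

H⁰-impact ionization applies a velocity-dependent screened
effective-charge factor Z_eff²(v) = 1 − 0.35·exp(−(v/2.0 a.u.)²) to the
proton tables: below unity everywhere, approaching 1 at high velocity.

## Elastic scattering

The classical deflection function θ(ρ) is integrated with the turning
point found by bracketed root-finding and the endpoint singularity
removed by substitution; on the bare Coulomb potential it matches the
Rutherford closed form to 1e−13 and the differential cross section to
1e−8.  Water uses a central sum of Thomas–Fermi-screened atomic terms;
the total cross section above a cutoff is exactly πρ(θ_cut)² on the
monotone branch, and sampling inverts ρ² uniformly (the table resolves
the hard-collision core on a logarithmic fraction grid down to 1e−8 —
a linear grid grossly overestimates the interpolated nuclear recoil).
The lab cutoff angle defaults to 0.1 mrad.  The H⁰/H⁺ elastic ratio is
the empirical log₁₀-quadratic in E(keV); it stays within [1, 1.3] up to
10 MeV (by 100 MeV it reaches 1.43 — elastic collisions are irrelevant
there).  DNA elastic scattering is disabled by default; the 18 waters
of the hydrated nucleotide provide the medium's elastic channel.

## Tables and transport

All channels are tabulated on a log energy grid (default 20 nodes,
10 keV–100 MeV) with log-log interpolation.  Ionization sampling stores
per-node ejected-energy CDFs (inverted geometrically), σ-weighted mean
bindings, and polar-ejection marginals from the DDCS grid; excitation
stores per-state weights.  Across the DNA components each atomic label
is evaluated on a few binding-energy nodes and interpolated in log|ε|
(exact for water, whose labels sit on their actual binding energies).

Energy-loss bookkeeping per event: ionization deposits ⟨binding⟩
locally and gives E_k to the ejected electron; excitation deposits the
state threshold; capture (H⁺→H⁰) deposits binding + (m_e/m_p)E − 13.6 eV
(clamped at 0); loss (H⁰→H⁺) launches a forward electron with
(m_e/m_p)E and deposits 13.6 eV + that energy as projectile loss.
Elastic events change direction only; the nuclear recoil is deposited
locally in dose mode and excluded from electronic stopping-power
tallies.  Charge fractions are re-evaluated from the σ_L/σ_C tables at
the current energy at every step.  Kinematics are non-relativistic
throughout (at 100 MeV the velocity error is ~5%; the quantities
studied here live far below that).

The Monte Carlo uses a splitmix64 counter RNG hashed per history, so
histories are independent substreams and runs are bit-reproducible for
a given seed independent of batching.  (An early version derived
history seeds by adding multiples of the generator's own increment,
which silently correlates all histories — the toy-medium closed-form
oracles caught it.)

Stationary mode follows each projectile to its first inelastic
interaction (SP = ΣΔE/Σpath per species, combined with equilibrium
fractions); slowing-down mode follows primaries to the 10 keV cutoff
and adds a fixed 0.322 µm sub-cutoff range correction (configurable).
Elastic deflection does not change a path length and is skipped in
range mode.

## Secondary electrons

A deliberately simple stand-in with a stable interface: per-orbital
binary-encounter-style ionization (with secondary energies from a
1/(w+B)² law), excitation by velocity scaling of the proton fits,
screened-Rutherford elastic scattering, and local deposition below
7.4 eV (or when only elastic channels remain open, i.e. below the
8.17 eV first threshold).  Energy is conserved exactly per history.
The mean 1 keV track extent in water is ~22 nm against a CSDA path of
~52 nm from the model's own stopping integral — a detour factor of
~2.4 from elastic diffusivity.  In DNA media the electron cross
sections are scaled by the electron-count ratio to water.  This module
is the main fidelity limitation for per-species dose *contributions*;
the dose ratios between media are insensitive to it.

## Cell phantom

Three concentric spheres (7 µm cell, 4 µm nucleus, 10 nm membrane);
membrane and cytoplasm are unit-density water; the nucleus is water,
density-rescaled water (1.29), or hydrated DNA.  Primaries start
uniformly on the outer sphere with directions uniform over the inward
hemisphere (cosine-weighted optional; the mean cell chord then is
4R/3, which a test verifies).  Free paths are resampled at every
region boundary; deposits are attributed to the region containing the
event and to the species losing the energy (secondary-electron deposits
to e⁻ regardless of parent).  Sub-cutoff residuals deposit locally.
Doses follow D = ΔE/(ρV) with the nucleus mass from its medium density.

Default histories: 10⁴ per energy for dose ratios, 10³ per energy for
scans; batch means over disjoint history ranges supply statistical
errors.

## What the synthetic data can and cannot show

The DNA orbital tables are synthetic; they reproduce the *structure*
of the medium (electron counts, binding-energy scales, composition) but
not any specific quantum-chemistry spectrum, so per-MO observables of
DNA have no quantitative meaning here.  Medium-level quantities (total
cross sections, stopping powers, dose ratios) depend mainly on electron
counts and binding scales and are meaningful at the tens-of-percent
level.  The water description carries no synthetic input.
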