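# Methods

## Model overview

The package treats a chromophore dimer A–B in a six-state diabatic basis
[Qy1, Qx1, Qy2, Qx2, CT1, CT2] (site 1 = fragment A, site 2 = fragment B;
CT1 = A⁺B⁻, CT2 = A⁻B⁺). The ground state is excluded from the solved basis:
its coupling to the LE states vanishes by construction of the site energies,
and its coupling to the CT states is assumed to be in the weak-coupling
regime (checked by an explicit flag, see below). Diabatic states built from
different fragment orbital sets are not mutually orthogonal, so adiabatic
energies and coefficients come from the generalized eigenvalue problem
H C = E S C over the 6×6 matrices.

Block structure and its assumptions:

* **LE/LE overlap is the unit matrix** and the CT1/CT2 coupling and overlap
  are exactly zero (transfer of opposite polarity is a two-electron process;
  the one-electron model Hamiltonians used here cannot connect them).
* **LE states are pure single orbital transitions**: Qy = HOMO→LUMO,
  Qx = (HOMO−1)→LUMO of a fragment. A multi-configurational LE expansion
  would enter only as a weighted sum over role pairs and is not enabled by
  default.
* **LE–CT overlap entries** default to single-determinant products: the
  hole-orbital overlap (a Kronecker delta between frontier roles) times the
  electron-orbital overlap taken from the inter-fragment overlap matrix.
  They can be zeroed (`include_overlaps=False`), since reference data rarely
  tabulates them.

## Toy electronic-structure backend

No DFT engine is involved anywhere; the backend supplies analytically
integrable stand-ins with the structural features the coupling formulas
depend on:

* **1s Slater bases** (one function per site). Overlaps therefore decay as
  exp(−ζR) — the physically correct long-range behaviour of
  orbital-overlap-mediated couplings, which Gaussian bases would
  misrepresent. Equal-exponent overlap, two-center Coulomb and nuclear
  attraction integrals use closed forms; unequal exponents use 1-D
  quadratures (prolate-spheroidal factorization for overlaps, the analytic
  cloud potential for Coulomb integrals).
* **Fragments** are short site chains (default 4 sites, 2.0 bohr spacing,
  ζ = 1.2 bohr⁻¹). Orbital *shapes* come from a Hückel-like generalized
  eigenproblem over the chain; orbital *energies* are prescribed so the
  frontier gaps are controllable: defaults (−0.1934, −0.1842, −0.1100,
  −0.0500) hartree put the H→L gap at 2.02 eV and the H′→L gap at 2.27 eV
  (the chlorophyll-a Qy/Qx range) with the HOMO near −5 eV.
* **The supermolecular model Hamiltonian** in the union fragment-orbital
  basis is diagonal within a fragment and Wolfsberg–Helmholz between
  fragments, H_pq = ½K(ε_p+ε_q)S_pq with K = 1.75 (the standard value;
  configurable). This is a one-parameter model that reproduces level
  splitting qualitatively. A `overlap_scale` knob multiplies all
  inter-fragment overlaps (0 = exactly non-interacting), used for
  leading-order consistency checks.
* **Units**: hartree/bohr internally; every file interface uses eV/Å with
  1 hartree = 27.211386 eV, 1 bohr = 0.52917721 Å. Spin is integrated out;
  all orbitals are closed-shell spatial orbitals.

The default *toy dimer* is a slip-stacked pair (stacking distance 7 bohr
≈ 3.7 Å, longitudinal slip 1 bohr). A perfectly eclipsed stack makes several
couplings vanish by parity; real chromophore pairs are slip-stacked, and the
slip restores generic magnitudes. In this geometry the two "same-side" Qx
couplings (Qx with the CT state whose hole sits on the same fragment) are
parity-suppressed to the numerical floor — consistent with their omission
from typical coupling tabulations; the package still evaluates their
closed-form expressions, which carry only a hole-transfer term and are
second order in the inter-fragment overlap.

## LE–CT couplings (generalized fragment-orbital method)

Fragment orbitals are expanded in the supermolecular orbitals through
S′_{p,π} (supermolecule × fragment) and contracted with the diagonal
normal-ordered supermolecular Hamiltonian. The implemented closed formulas
(hartree) for the A-side LE states are

    V(QyA,CT1) =  Σ_a ε_a S′[a,L_A]S′[a,L_B] − Σ_i ε_i S[L_A,L_B] S′[i,H_A]²
    V(QxA,CT1) = −Σ_i ε_i S[L_A,L_B] S′[i,H′_A] S′[i,H_A]
    V(QyA,CT2) = −Σ_i ε_i S′[i,H_A]S′[i,H_B] + Σ_a ε_a S[H_A,H_B] S′[a,L_A]²
    V(QxA,CT2) = −Σ_i ε_i S′[i,H′_A]S′[i,H_B] + Σ_a ε_a S[H′_A,H_B] S′[a,L_A]²

with B-side analogues generated by mechanical A↔B exchange of every index —
an explicit assumption of this package. These truncated formulas are checked
two ways: against a naive term-by-term re-implementation (pure algebra,
1e-12) and against an independent determinant-expansion oracle that keeps
the full hole/particle expansion; the two agree to leading order in the
inter-fragment overlap (the difference decays at least linearly as overlaps
are scaled down), which is the designed level of agreement — exact equality
is not expected of a truncated expression. Orbital phases are fixed by
making each orbital's largest-magnitude coefficient positive, so coupling
signs are reproducible run to run; only magnitudes are physically meaningful.

## CT energetics

Diabatic CT energies are assembled as E_CT = E_ion + E_int. The
charged-fragment part uses Koopmans-style orbital-energy surrogates
(E_{A⁺}−E_A = −ε_{HOMO}, E_{B⁻}−E_B = +ε_{LUMO}): a ΔSCF treatment would
require a self-consistent engine, and the surrogate preserves the structure
of the method and every trend under study. Its known cost: the toy E_ion
equals the frontier gap and lacks the charging (Hubbard-U-like) energy, so
toy CT states sit *below* the toy LE states at close range, unlike
chlorophyll dimers where they sit above. Trend-level conclusions (distance
dependence, symmetry breaking by the environment, level repulsion) are
unaffected, and realistic spectra are obtained by supplying tabulated CT
energies instead.

E_int sums cloud–cloud, cloud–nucleus and nucleus–nucleus Coulomb terms of
the two charged site densities (Mulliken populations on 1s clouds) and obeys
E_int → q_A q_B / R as R → ∞. Non-additive exchange-correlation and kinetic
contributions are outside the toy density model and are recorded as exactly
zero in result metadata — always, not only asymptotically.

The weak-coupling validity flag compares |V₀₁|/|H₁₁−H₀₀| against 0.1
(configurable; no standard number exists). GS–CT coupling data (H₀₁, S₀₁)
are not computable in toy mode and enter only as user-supplied values.

## Polarizable environment (DRF)

Environment sites carry permanent charges and isotropic polarizabilities.
Induced dipoles solve μ_s = α_s[E_perm(s) + Σ_{t≠s}T⁽²⁾_{st}μ_t] as one
direct linear system; a fixed-point iteration serves as the test oracle.
Exponential Thole damping (a = 2.1304, the standard value for Thole's
exponential parameterization; toggleable) attenuates the site–site dipole
tensors and prevents the polarization catastrophe at close contacts.
Sources at the fragments are the state-difference Mulliken charges
(excited−ground for LE shifts, charged−neutral for CT shifts); the
self-consistency between environment dipoles and fragment orbitals that a
full embedding would iterate is replaced by this first-order state-charge
coupling. The response correction −Σ_s μ_s[δρ_A]·T⁽¹⁾ contracted with B's
transition charges applies to the LE/LE couplings only by default
(`apply_response_to_le`); whether it should also dress LE–CT couplings is
left as a flagged choice, defaulting to off.

## Ensembles and statistics

Snapshot tables are tidy records (snapshot, label, value in eV, provenance
vacuum|environment). Summaries use the population variance (divisor n) —
a deliberate convention choice that only affects synthetic runs. The
gap/shift report derives |ΔE_CT| per set and first-minus-last shifts,
rounding to two decimals only at presentation.

The sampled-ensemble generator draws each diabatic quantity independently
from a normal with prescribed mean and variance. The default statistics
(`CHLA_DIMER_FIRST` / `CHLA_DIMER_LAST`) describe a stacked chlorophyll-a
dimer before and after an equilibration that shortens the stacking distance:
CT energies drop (2.77/3.28 → 2.59/2.52 eV), and the LE/LE and LE/CT
couplings grow. Coupling signs are taken positive by default since reference
tabulations report magnitudes; a signed table can be supplied, and the sign
ambiguity is an intrinsic limitation when rebuilding Hamiltonians from
magnitude-only data. Independent sampling ignores cross-correlations between
matrix elements within a snapshot; the red-shift mechanism it probes (50
snapshots per set by default, seeded) is robust to this because it is driven
by the mean drift, not the covariances.

What passing the ensemble tests does and does not show: the generator
emulates the *statistics* of per-snapshot matrix elements, not the
electronic structure behind them — conclusions about real systems require
real per-snapshot inputs through the same file interfaces.

## Numerical choices

* Generalized eigensolver: `scipy.linalg.eigh(H, S)` with a positive
  definite S; metric eigenvalues below 1e-8 trigger canonical
  orthogonalization (directions discarded, warning logged); an indefinite S
  is an error.
* Character weights: Löwdin symmetric scheme, w_dk = (S^{1/2}C)²_dk, which
  is non-negative and sums to one per state; a Mulliken-style alternative
  (diagonal of C∘SC) is available behind a flag. No standard partition
  exists for non-orthogonal diabatic characters; Löwdin is the default for
  its positivity.
* Degenerate eigenvalues are ordered by descending LE fraction, then by
  diabatic label order, so serialized output is deterministic.
* Near-linear dependence of the union orbital basis (condition number above
  1e10) is an error naming the most-overlapping orbital pair.
* The determinant-expansion oracle is restricted to ≤14 fragment orbitals;
  it exists for testing, not production use.

## Problem sizes

Default sizes keep every computation interactive: 4-site fragments (8
orbitals per dimer), 50-snapshot sampled ensembles, and 10-snapshot toy
pipelines. All are parameters, not limits of the implementation.

## Known limitations

* Koopmans-style CT energetics (above): toy CT energies are trend-accurate,
  not absolute.
* Coulomb-only LE couplings: short-range exchange-correlation/kinetic kernel
  contributions are not representable with transition charges and are
  recorded as zero in metadata.
* Isotropic polarizabilities only; no frequency dependence in the
  environment response.
* No vibronic structure: rates, Franck–Condon factors and band shapes are
  outside the model; the output is the electronic-state ladder and its
  composition.
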