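# excitonct

Diabatic LE/CT model Hamiltonians for chromophore dimers.

## The problem

In photosynthetic antenna complexes, pairs of closely stacked chlorophylls
(such as the terminal-emitter pair of LHCII) host two kinds of low-lying
excited states: *locally excited* (LE) states — the Qy and Qx bands of each
pigment — and *charge-transfer* (CT) states in which an electron has moved
from one pigment to the other (A⁺B⁻ or A⁻B⁺). CT states are optically dark,
but when a conformational change brings the pigments closer, their energies
drop and their coupling to the LE states grows, producing red-shifted mixed
exciton/CT states that are believed to act as energy sinks and quenching
intermediates. Quantifying that mixing requires a model Hamiltonian over
*diabatic* states with clean LE/CT labels, which are mutually non-orthogonal
because each is built from its own fragment orbital set.

`excitonct` builds and solves that model. The six-state diabatic basis
(Qy1, Qx1, Qy2, Qx2, CT1, CT2) yields a 6×6 Hamiltonian **H**ᵈⁱᵃ and overlap
**S**ᵈⁱᵃ, and the adiabatic states solve the generalized eigenvalue problem

    H^dia C = E S^dia C.

The blocks of **H**ᵈⁱᵃ are computed independently, each with the method a
practitioner would use at that level:

* **LE block** — site energies on the diagonal; off-diagonal Förster-type
  Coulomb couplings between the fragments' transition densities, evaluated
  over discrete (Mulliken) transition charges,
  V = Σ_{s∈A,t∈B} q_s q_t / |r_s − r_t|, with the classical point-dipole
  approximation available for comparison.
* **CT block** — diabatic CT energies E_CT = E_ion + E_int in the
  weak-coupling (Marcus two-state) regime, where
  V₀₁ = [H₀₁ − S₀₁(H₀₀+H₁₁)/2]/(1−S₀₁²) and
  ΔE = √[(H₁₁−H₀₀)²/(1−S₀₁²) + 4V₀₁²]; the charged-pair interaction
  E_int sums electron–electron, electron–nuclear and nuclear repulsion
  terms and tends to q_A q_B/R at long range. The CT1–CT2 coupling and
  overlap are exactly zero (a two-electron process).
* **LE–CT block** — generalized fragment-orbital (FODFT) couplings: with
  fragment orbitals expanded in a fixed diagonal supermolecular Hamiltonian
  through the mixed overlaps S′ (supermolecule×fragment) and S
  (fragment×fragment), e.g.

      V(QyA, CT1) = Σ_a ε_a S′[a,L_A] S′[a,L_B] − Σ_i ε_i S[L_A,L_B] S′[i,H_A]²,

  and analogously for the remaining hole/electron-transfer channels.
* **Environment** — a Discrete Reaction Field (DRF) of point charges q_s and
  isotropic polarizabilities α_s with self-consistently induced dipoles
  (exponential Thole damping), shifting site and CT energies and adding a
  response correction to the LE couplings.

Because the full DFT machinery behind such calculations is out of scope, a
*toy electronic-structure backend* supplies everything the formulas consume:
fragments with 1s Slater bases (exponentially decaying overlaps, the correct
long-range behaviour for these couplings), prescribed chlorophyll-like
frontier gaps, and a Wolfsberg–Helmholz supermolecular model Hamiltonian.
Per-snapshot matrix elements from real calculations can equally be supplied
as tabular files.

## Worked example

Assemble the dimer Hamiltonian from ensemble-averaged energies (eV) of a
stacked chlorophyll-a pair before equilibration and solve it:

```python
from excitonct import SiteEnergies, assemble, solve

site = SiteEnergies({"Qy1": 2.02, "Qx1": 2.27, "Qy2": 2.01, "Qx2": 2.26})
le   = {("Qy1", "Qy2"): 0.021, ("Qx1", "Qx2"): 0.009}
ct   = {"CT1": 2.77, "CT2": 3.28}
lect = {("QyA", "CT1"): 0.009, ("QyA", "CT2"): 0.019, ("QxA", "CT2"): 0.017,
        ("QyB", "CT1"): 0.019, ("QyB", "CT2"): 0.009, ("QxB", "CT1"): 0.015}

sol = solve(assemble(site, le, ct, lect))
for e, w in zip(sol.energies, sol.weights):
    dom = max(w, key=w.get)
    print(f"E = {e:.4f} eV   dominant: {dom} ({w[dom]:.3f})   CT fraction: "
          f"{sum(w[l] for l in ('CT1','CT2')):.4f}")
```

prints

```
E = 1.9933 eV   dominant: Qy2 (0.619)   CT fraction: 0.0002
E = 2.0358 eV   dominant: Qy1 (0.619)   CT fraction: 0.0009
E = 2.2543 eV   dominant: Qx2 (0.745)   CT fraction: 0.0007
E = 2.2750 eV   dominant: Qx1 (0.746)   CT fraction: 0.0004
E = 2.7710 eV   dominant: CT1 (0.998)   CT fraction: 0.9983
E = 3.2806 eV   dominant: CT2 (0.999)   CT fraction: 0.9994
```

The two lowest states are Qy excitons split by the Coulomb coupling and
essentially free of CT character at this geometry; the CT states sit 0.7–1.3
eV higher and stay nearly pure. Feeding the post-equilibration statistics
(lower CT energies, larger couplings) instead red-shifts the lowest state
and mixes CT character into it — the mechanism `drift_ensemble_shift`
quantifies over sampled snapshot ensembles.

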