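"""Toy fragments and model dimers.

A ToyFragment is a minimal stand-in for a chromophore treated by an electronic
structure engine: a handful of sites carrying normalized 1s Slater functions,
a set of orthonormal molecular orbitals with energies, and a frontier-orbital
map (HOMO-1, HOMO, LUMO) from which the Qy-like (H -> L) and Qx-like
(H' -> L) excitations and the CT hole/particle orbitals are drawn.

A DimerSystem combines two fragments: a model supermolecular Hamiltonian of
Wolfsberg-Helmholz form is diagonalized in the union of the two fragments'
orbital spaces (a generalized eigenproblem in the non-orthogonal union
metric), yielding supermolecular orbitals/energies and the two overlap
matrices every coupling formula consumes:

* ``S``  -- fragment-A orbitals against fragment-B orbitals,
* ``Sprime`` -- supermolecular orbitals against all fragment orbitals.

Internal units: hartree and bohr.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

from .errors import (
    ConfigurationError,
    InvalidParameterError,
    NearLinearDependenceError,
    SingularityError,
)
from .slater import sto_overlap

__all__ = [
    "Site",
    "ToyFragment",
    "TransitionChargeSet",
    "DimerSystem",
    "make_toy_fragment",
    "build_dimer",
    "make_transition_charges",
]

#: default frontier orbital energies (hartree): HOMO-1, HOMO, LUMO, LUMO+1
#: chosen so the toy H->L and H'->L gaps sit at ~2.02 and ~2.27 eV, the
#: chlorophyll-a Qy/Qx range, with the HOMO near -5 eV.
DEFAULT_ORBITAL_ENERGIES = (-0.1934, -0.1842, -0.1100, -0.0500)

#: Wolfsberg-Helmholz proportionality constant for the inter-fragment block
DEFAULT_WH_K = 1.75


@dataclass(frozen=True)
class Site:
    tag: str
    position: np.ndarray  # (3,) bohr
    core_charge: float  # e


def _fix_sign(C: np.ndarray) -> np.ndarray:
    """Flip orbital phases so each column's largest-|coeff| entry is positive."""
    C = C.copy()
    for k in range(C.shape[1]):
        j = int(np.argmax(np.abs(C[:, k])))
        if C[j, k] < 0:
            C[:, k] *= -1.0
    return C


@dataclass
class ToyFragment:
    """A minimal chromophore with 1s Slater basis and orthonormal orbitals."""

    label: str
    sites: list[Site]
    basis: list[tuple[int, float]]  # (site index, zeta in bohr^-1)
    mo_coeffs: np.ndarray  # (nbasis, norb)
    orbital_energies: np.ndarray  # hartree, ascending
    n_occ: int
    frontier: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.mo_coeffs = np.asarray(self.mo_coeffs, dtype=float)
        self.orbital_energies = np.asarray(self.orbital_energies, dtype=float)
        if not self.frontier:
            self.frontier = {"H": self.n_occ - 1}
            if self.n_occ < self.n_orb:
                self.frontier["L"] = self.n_occ
            if self.n_occ >= 2:
                self.frontier["H'"] = self.n_occ - 2
        self.validate()

    # -- structure helpers -------------------------------------------------
    @property
    def n_orb(self) -> int:
        return self.mo_coeffs.shape[1]

    @property
    def n_basis(self) -> int:
        return len(self.basis)

    def basis_positions(self) -> np.ndarray:
        return np.array([self.sites[i].position for i, _ in self.basis])

    def basis_zetas(self) -> np.ndarray:
        return np.array([z for _, z in self.basis])

    def site_positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites])

    def intra_overlap(self) -> np.ndarray:
        pos = self.basis_positions()
        zet = self.basis_zetas()
        n = len(zet)
        S = np.eye(n)
        for a in range(n):
            for b in range(a + 1, n):
                R = float(np.linalg.norm(pos[a] - pos[b]))
                S[a, b] = S[b, a] = sto_overlap(zet[a], zet[b], R)
        return S

    def frontier_index(self, role: str) -> int:
        try:
            return self.frontier[role]
        except KeyError:
            raise ConfigurationError(
                f"fragment {self.label}: frontier role {role!r} not defined"
            ) from None

    def validate(self) -> None:
        if self.mo_coeffs.shape != (self.n_basis, len(self.orbital_energies)):
            raise InvalidParameterError(
                f"fragment {self.label}: mo_coeffs shape {self.mo_coeffs.shape} "
                f"inconsistent with {self.n_basis} basis functions and "
                f"{len(self.orbital_energies)} energies"
            )
        if np.any(np.diff(self.orbital_energies) < -1e-12):
            raise InvalidParameterError(
                f"fragment {self.label}: orbital energies must be ascending"
            )
        if not 0 < self.n_occ <= self.n_orb:
            raise InvalidParameterError(
                f"fragment {self.label}: n_occ={self.n_occ} out of range"
            )
        if "H'" in self.frontier and self.n_occ < 2:
            raise InvalidParameterError(
                f"fragment {self.label}: role H' requires n_occ >= 2"
            )
        expected = {"H": self.n_occ - 1, "L": self.n_occ, "H'": self.n_occ - 2}
        for role, idx in self.frontier.items():
            if role in expected and idx != expected[role]:
                raise InvalidParameterError(
                    f"fragment {self.label}: frontier role {role} must be "
                    f"orbital {expected[role]}, got {idx}"
                )
        ortho = self.mo_coeffs.T @ self.intra_overlap() @ self.mo_coeffs
        if not np.allclose(ortho, np.eye(self.n_orb), atol=1e-10):
            raise InvalidParameterError(
                f"fragment {self.label}: orbitals not orthonormal in the "
                f"intra-fragment metric (max dev "
                f"{np.max(np.abs(ortho - np.eye(self.n_orb))):.2e})"
            )

    def translated(self, displacement) -> "ToyFragment":
        d = np.asarray(displacement, dtype=float)
        new_sites = [
            Site(s.tag, s.position + d, s.core_charge) for s in self.sites
        ]
        return replace(self, sites=new_sites)

    def mulliken_orbital_populations(self, orbital: int) -> np.ndarray:
        """Per-site Mulliken population of one orbital (sums to 1)."""
        S = self.intra_overlap()
        c = self.mo_coeffs[:, orbital]
        per_basis = c * (S @ c)
        pops = np.zeros(len(self.sites))
        for b, (site_idx, _) in enumerate(self.basis):
            pops[site_idx] += per_basis[b]
        return pops


@dataclass
class TransitionChargeSet:
    """Mulliken-style discrete transition charges for one orbital transition.

    A point-charge discretization of the transition density between two
    orthonormal orbitals; the total charge vanishes and the dipole is exactly
    the charge-weighted position sum.
    """

    origin: str  # fragment label
    role_pair: tuple[str, str]  # (occupied role, virtual role)
    site_indices: np.ndarray
    positions: np.ndarray  # (n, 3) bohr
    charges: np.ndarray  # e

    @property
    def dipole(self) -> np.ndarray:
        """Transition dipole sum(q_t * r_t) in e*bohr."""
        return self.charges @ self.positions

    def scaled(self, factor: float) -> "TransitionChargeSet":
        return TransitionChargeSet(
            self.origin,
            self.role_pair,
            self.site_indices.copy(),
            self.positions.copy(),
            self.charges * factor,
        )


def make_toy_fragment(
    label: str = "A",
    n_sites: int = 4,
    spacing: float = 2.0,
    zeta: float = 1.2,
    orbital_energies=None,
    n_occ: int = 2,
    origin=(0.0, 0.0, 0.0),
    axis=(1.0, 0.0, 0.0),
) -> ToyFragment:
    """Build a linear-chain toy chromophore.

    ``n_sites`` sites along ``axis`` spaced ``spacing`` bohr apart, one
    normalized 1s Slater function (exponent ``zeta``) per site.  Orbital
    shapes come from a Hueckel-like generalized eigenproblem in the chain
    (delocalized, orthonormal in the intra-fragment metric); orbital
    *energies* are prescribed (default: chlorophyll-like frontier gaps,
    see DEFAULT_ORBITAL_ENERGIES) so that the Qy/Qx/CT level structure is
    controllable independent of the chain geometry.
    """
    if n_sites < 1:
        raise InvalidParameterError("n_sites must be >= 1")
    origin = np.asarray(origin, dtype=float)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)

    if orbital_energies is None:
        orbital_energies = np.array(DEFAULT_ORBITAL_ENERGIES[: max(n_sites, 2)])
        if n_sites < len(orbital_energies):
            orbital_energies = orbital_energies[:n_sites]
        elif n_sites > 4:
            extra = -0.05 + 0.05 * np.arange(1, n_sites - 3)
            orbital_energies = np.concatenate([orbital_energies, extra])
    orbital_energies = np.sort(np.asarray(orbital_energies, dtype=float))
    if len(orbital_energies) != n_sites:
        raise InvalidParameterError(
            "need one orbital energy per basis function "
            f"({n_sites} sites, {len(orbital_energies)} energies)"
        )

    core = 2.0 * n_occ / n_sites  # neutral fragment: cores balance 2*n_occ electrons
    sites = [
        Site(f"{label}{i + 1}", origin + i * spacing * axis, core)
        for i in range(n_sites)
    ]
    basis = [(i, zeta) for i in range(n_sites)]

    frag = ToyFragment.__new__(ToyFragment)
    frag.label = label
    frag.sites = sites
    frag.basis = basis
    # orbital shapes: Hueckel model alpha*I + WH overlap off-diagonals
    S = np.eye(n_sites)
    pos = np.array([s.position for s in sites])
    for a in range(n_sites):
        for b in range(a + 1, n_sites):
            S[a, b] = S[b, a] = sto_overlap(
                zeta, zeta, float(np.linalg.norm(pos[a] - pos[b]))
            )
    alpha = -0.2
    H = alpha * DEFAULT_WH_K * S
    np.fill_diagonal(H, alpha)
    _, C = scipy.linalg.eigh(H, S)
    C = _fix_sign(C)

    return ToyFragment(
        label=label,
        sites=sites,
        basis=basis,
        mo_coeffs=C,
        orbital_energies=orbital_energies,
        n_occ=n_occ,
    )


@dataclass
class DimerSystem:
    """Two fragments plus model supermolecular orbitals and all overlaps.

    ``S`` is the inter-fragment orbital overlap (rows: A orbitals, columns:
    B orbitals); ``Sprime`` has one row per supermolecular orbital and one
    column per fragment orbital (A columns first, then B).
    """

    fragA: ToyFragment
    fragB: ToyFragment  # already displaced
    wh_k: float
    overlap_scale: float
    ao_overlap: np.ndarray  # union basis metric
    frag_coeffs: np.ndarray  # union-basis coefficients of fragment orbitals
    frag_energies: np.ndarray
    sup_energies: np.ndarray  # ascending
    sup_coeffs: np.ndarray  # union-basis coefficients of supermolecular orbitals
    S: np.ndarray
    Sprime: np.ndarray
    n_occ: int

    @property
    def n_frag_orb(self) -> int:
        return self.fragA.n_orb + self.fragB.n_orb

    @property
    def occ_indices(self) -> np.ndarray:
        return np.arange(self.n_occ)

    @property
    def virt_indices(self) -> np.ndarray:
        return np.arange(self.n_occ, len(self.sup_energies))

    def frag_orbital_index(self, fragment: str, role: str) -> int:
        """Global fragment-orbital column index for a frontier role."""
        if fragment == "A":
            return self.fragA.frontier_index(role)
        if fragment == "B":
            return self.fragA.n_orb + self.fragB.frontier_index(role)
        raise ConfigurationError(f"unknown fragment label {fragment!r}")


def build_dimer(
    fragA: ToyFragment,
    fragB: ToyFragment,
    displacement,
    wh_k: float = DEFAULT_WH_K,
    overlap_scale: float = 1.0,
    cond_threshold: float = 1e10,
    min_site_distance: float = 1e-6,
) -> DimerSystem:
    """Combine two fragments into a model supermolecule.

    Fragment B is rigidly displaced by ``displacement`` (bohr).  The model
    supermolecular Hamiltonian in the union fragment-orbital basis is
    ``H_pp = eps_p`` within a fragment and the Wolfsberg-Helmholz form
    ``H_pq = 0.5 * K * (eps_p + eps_q) * S_pq`` between fragments; orbitals
    and energies come from the generalized eigenproblem in the union metric.

    ``overlap_scale`` multiplies every inter-fragment overlap (1 = physical,
    0 = exactly non-interacting), which is how overlap-scaling consistency
    checks of the coupling formulas are run.
    """
    fragB = fragB.translated(displacement)

    posA, posB = fragA.site_positions(), fragB.site_positions()
    d2 = np.linalg.norm(posA[:, None, :] - posB[None, :, :], axis=-1)
    if d2.min() < min_site_distance:
        ia, ib = np.unravel_index(np.argmin(d2), d2.shape)
        raise SingularityError(
            f"fragments overlap after displacement: site {fragA.sites[ia].tag} "
            f"coincides with {fragB.sites[ib].tag}"
        )

    nA_b, nB_b = fragA.n_basis, fragB.n_basis
    pos = np.vstack([fragA.basis_positions(), fragB.basis_positions()])
    zet = np.concatenate([fragA.basis_zetas(), fragB.basis_zetas()])
    n_b = nA_b + nB_b
    S_ao = np.eye(n_b)
    for a in range(n_b):
        for b in range(a + 1, n_b):
            s = sto_overlap(zet[a], zet[b], float(np.linalg.norm(pos[a] - pos[b])))
            if (a < nA_b) != (b < nA_b):
                s *= overlap_scale
            S_ao[a, b] = S_ao[b, a] = s

    nA, nB = fragA.n_orb, fragB.n_orb
    C = np.zeros((n_b, nA + nB))
    C[:nA_b, :nA] = fragA.mo_coeffs
    C[nA_b:, nA:] = fragB.mo_coeffs
    eps = np.concatenate([fragA.orbital_energies, fragB.orbital_energies])

    sigma = C.T @ S_ao @ C  # union fragment-orbital metric
    cond = np.linalg.cond(sigma)
    if cond > cond_threshold:
        inter = np.abs(sigma[:nA, nA:])
        ia, ib = np.unravel_index(np.argmax(inter), inter.shape)
        raise NearLinearDependenceError(
            f"union orbital basis nearly linearly dependent (cond={cond:.2e}); "
            f"largest inter-fragment overlap {inter[ia, ib]:.6f} between "
            f"A orbital {ia} and B orbital {ib}"
        )

    H = np.diag(eps).astype(float)
    wh = 0.5 * wh_k * (eps[:, None] + eps[None, :]) * sigma
    H[:nA, nA:] = wh[:nA, nA:]
    H[nA:, :nA] = wh[nA:, :nA]

    w, V = scipy.linalg.eigh(H, sigma)
    V = _fix_sign(V)

    Sprime = V.T @ sigma  # (sup orbitals) x (fragment orbitals)
    return DimerSystem(
        fragA=fragA,
        fragB=fragB,
        wh_k=wh_k,
        overlap_scale=overlap_scale,
        ao_overlap=S_ao,
        frag_coeffs=C,
        frag_energies=eps,
        sup_energies=w,
        sup_coeffs=C @ V,
        S=sigma[:nA, nA:].copy(),
        Sprime=Sprime,
        n_occ=fragA.n_occ + fragB.n_occ,
    )


def make_transition_charges(
    frag: ToyFragment, role_pair: tuple[str, str] = ("H", "L")
) -> TransitionChargeSet:
    """Mulliken transition charges for the ``occ -> virt`` frontier transition.

    q_t = sum over basis functions b on site t of the symmetrized Mulliken
    contraction 0.5*[c_occ,b (S c_virt)_b + c_virt,b (S c_occ)_b]; for
    orthonormal orbital pairs the charges sum to zero.
    """
    occ_role, virt_role = role_pair
    i = frag.frontier_index(occ_role)
    a = frag.frontier_index(virt_role)
    S = frag.intra_overlap()
    co, cv = frag.mo_coeffs[:, i], frag.mo_coeffs[:, a]
    per_basis = 0.5 * (co * (S @ cv) + cv * (S @ co))
    n_sites = len(frag.sites)
    q = np.zeros(n_sites)
    for b, (site_idx, _) in enumerate(frag.basis):
        q[site_idx] += per_basis[b]
    return TransitionChargeSet(
        origin=frag.label,
        role_pair=role_pair,
        site_indices=np.arange(n_sites),
        positions=frag.site_positions(),
        charges=q,
    )
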