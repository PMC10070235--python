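"""Generalized fragment-orbital LE-CT couplings.

The coupling between a locally excited state (a single hole/particle
excitation within one fragment) and a charge-transfer state (hole on one
fragment, particle on the other) is evaluated against a fixed, diagonal
supermolecular one-electron Hamiltonian.  Writing the fragment orbitals in
the supermolecular orbital basis through the mixed overlap matrix S' and
using the inter-fragment orbital overlaps S, the couplings take closed
summation forms over the supermolecular occupied (i) and virtual (a)
energies.  With H = HOMO, H' = HOMO-1, L = LUMO of a fragment, and CT1 the
H_A -> L_B, CT2 the H_B -> L_A transfer:

    V(QyA, CT1) =  sum_a eps_a S'[a,LA] S'[a,LB]  -  sum_i eps_i S[LA,LB] S'[i,HA]^2
    V(QxA, CT1) = -sum_i eps_i S[LA,LB] S'[i,H'A] S'[i,HA]
    V(QyA, CT2) = -sum_i eps_i S'[i,HA] S'[i,HB]  +  sum_a eps_a S[HA,HB] S'[a,LA]^2
    V(QxA, CT2) = -sum_i eps_i S'[i,H'A] S'[i,HB] +  sum_a eps_a S[H'A,HB] S'[a,LA]^2

and the fragment-B analogues by the mechanical A <-> B exchange.  The first
(virtual) sums carry the electron-transfer contribution, the second
(occupied) sums the hole-transfer contribution; both are governed by
inter-fragment orbital overlap and therefore decay exponentially with
separation.

All energies hartree.  ``determinant_oracle`` provides an independent
non-orthogonal configuration-expansion evaluation of the same matrix
elements used for consistency testing at small overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputError, SizeError
from .fragments import DimerSystem

__all__ = [
    "OverlapSet",
    "LE_LABELS",
    "CT_LABELS",
    "compute_overlaps",
    "v_le_ct",
    "all_le_ct_couplings",
    "determinant_oracle",
]

LE_LABELS = ("QyA", "QxA", "QyB", "QxB")
CT_LABELS = ("CT1", "CT2")

#: (fragment, occupied role, virtual role) behind each LE label
_LE_TRANSITION = {
    "QyA": ("A", "H", "L"),
    "QxA": ("A", "H'", "L"),
    "QyB": ("B", "H", "L"),
    "QxB": ("B", "H'", "L"),
}

#: CT1: hole on A (H_A), particle on B (L_B); CT2: the reverse
_CT_TRANSITION = {
    "CT1": (("A", "H"), ("B", "L")),
    "CT2": (("B", "H"), ("A", "L")),
}


@dataclass
class OverlapSet:
    """Fragment/supermolecule overlap data feeding the coupling formulas.

    ``S`` has fragment-A orbitals on rows and fragment-B orbitals on columns;
    ``Sprime`` has supermolecular orbitals on rows and all fragment orbitals
    (A first, then B) on columns, with the supermolecular energies attached.
    """

    S: np.ndarray
    Sprime: np.ndarray
    sup_energies: np.ndarray
    n_occ_sup: int
    nA: int  # number of fragment-A orbitals
    frontierA: dict[str, int]
    frontierB: dict[str, int]

    def __post_init__(self):
        if np.max(np.abs(self.S)) > 1.0 + 1e-8 or np.max(np.abs(self.Sprime)) > 1.0 + 1e-8:
            raise InputError("overlap matrix entries must have magnitude <= 1")
        if self.Sprime.shape[0] != len(self.sup_energies):
            raise InputError("Sprime rows must match supermolecular energies")

    @property
    def occ(self) -> np.ndarray:
        return np.arange(self.n_occ_sup)

    @property
    def virt(self) -> np.ndarray:
        return np.arange(self.n_occ_sup, len(self.sup_energies))

    def frag_index(self, fragment: str, role: str) -> int:
        """Column index in ``Sprime`` of a fragment frontier orbital."""
        if fragment == "A":
            return self.frontierA[role]
        if fragment == "B":
            return self.nA + self.frontierB[role]
        raise ConfigurationError(f"unknown fragment label {fragment!r}")

    def s_frag(self, roleA: str, roleB: str) -> float:
        """Inter-fragment overlap S between an A role and a B role."""
        return float(self.S[self.frontierA[roleA], self.frontierB[roleB]])


def compute_overlaps(dimer: DimerSystem) -> OverlapSet:
    """Extract the S / S' overlap set from a dimer by basis-metric contraction."""
    if dimer.frag_coeffs.shape[0] != dimer.ao_overlap.shape[0]:
        raise InputError("fragment orbitals and dimer metric use different bases")
    sigma = dimer.frag_coeffs.T @ dimer.ao_overlap @ dimer.frag_coeffs
    sprime = dimer.sup_coeffs.T @ dimer.ao_overlap @ dimer.frag_coeffs
    nA = dimer.fragA.n_orb
    return OverlapSet(
        S=sigma[:nA, nA:].copy(),
        Sprime=sprime,
        sup_energies=dimer.sup_energies.copy(),
        n_occ_sup=dimer.n_occ,
        nA=nA,
        frontierA=dict(dimer.fragA.frontier),
        frontierB=dict(dimer.fragB.frontier),
    )


def _frontier_cols(ov: OverlapSet, frag: str):
    hp = ov.frag_index(frag, "H'") if "H'" in (
        ov.frontierA if frag == "A" else ov.frontierB
    ) else None
    return hp, ov.frag_index(frag, "H"), ov.frag_index(frag, "L")


def v_le_ct(ov: OverlapSet, pair: tuple[str, str]) -> float:
    """One generalized fragment-orbital LE-CT coupling (hartree).

    ``pair`` is (LE label in {QyA,QxA,QyB,QxB}, CT label in {CT1,CT2}).
    Fragment-B couplings use the A <-> B exchanged formulas.
    """
    le, ct = pair
    if le not in _LE_TRANSITION or ct not in _CT_TRANSITION:
        raise ConfigurationError(f"unknown coupling pair {pair!r}")

    frag = _LE_TRANSITION[le][0]  # fragment carrying the LE
    other = "B" if frag == "A" else "A"
    eps = ov.sup_energies
    occ, virt = ov.occ, ov.virt
    Sp = ov.Sprime

    # frontier columns on the LE fragment (X) and the other fragment (Y)
    hpX, hX, lX = _frontier_cols(ov, frag)
    _, hY, lY = _frontier_cols(ov, other)
    le_occ_col = hX if le.startswith("Qy") else hpX
    if le_occ_col is None:
        raise ConfigurationError(f"{le}: HOMO-1 role not defined on fragment {frag}")

    def s_between(col_on_frag: int, col_on_other: int) -> float:
        # inter-fragment overlap respecting the A-rows/B-columns layout of S
        if frag == "A":
            return float(ov.S[col_on_frag, col_on_other - ov.nA])
        return float(ov.S[col_on_other, col_on_frag - ov.nA])

    ct_hole_frag = _CT_TRANSITION[ct][0][0]
    if ct_hole_frag == frag:
        # hole on the LE fragment ("CT1-like" for this LE): electron-transfer
        # channel is L_X -> L_Y
        s_ll = s_between(lX, lY)
        if le.startswith("Qy"):
            return float(
                np.sum(eps[virt] * Sp[virt, lX] * Sp[virt, lY])
                - np.sum(eps[occ] * s_ll * Sp[occ, hX] ** 2)
            )
        return float(-np.sum(eps[occ] * s_ll * Sp[occ, le_occ_col] * Sp[occ, hX]))

    # hole on the other fragment ("CT2-like"): hole-transfer channel H_X -> H_Y
    s_hh = s_between(le_occ_col, hY)
    return float(
        -np.sum(eps[occ] * Sp[occ, le_occ_col] * Sp[occ, hY])
        + np.sum(eps[virt] * s_hh * Sp[virt, lX] ** 2)
    )


def all_le_ct_couplings(dimer: DimerSystem) -> dict[tuple[str, str], float]:
    """All eight LE-CT couplings of a dimer (hartree), keyed by (LE, CT) label."""
    ov = compute_overlaps(dimer)
    return {
        (le, ct): v_le_ct(ov, (le, ct)) for le in LE_LABELS for ct in CT_LABELS
    }


# ---------------------------------------------------------------------------
# independent oracle: non-orthogonal configuration expansion
# ---------------------------------------------------------------------------

def _resolve_state(ov: OverlapSet, state) -> tuple[int, int]:
    """Resolve a state label or (hole, particle) index pair to global columns."""
    if isinstance(state, str):
        if state in _LE_TRANSITION:
            frag, o, v = _LE_TRANSITION[state]
            return ov.frag_index(frag, o), ov.frag_index(frag, v)
        if state in _CT_TRANSITION:
            (hf, hr), (pf, pr) = _CT_TRANSITION[state]
            return ov.frag_index(hf, hr), ov.frag_index(pf, pr)
        if state == "reference":
            return (-1, -1)
        raise ConfigurationError(f"unknown state label {state!r}")
    hole, particle = state
    return int(hole), int(particle)


def determinant_oracle(dimer: DimerSystem, state1, state2) -> float:
    """Matrix element of the diagonal normal-ordered Hamiltonian (hartree).

    Each singly excited determinant built from *fragment* orbitals is expanded
    in the supermolecular determinant basis through the S' coefficients: the
    hole component projects onto occupied, the particle component onto virtual
    supermolecular orbitals.  The normal-ordered Hamiltonian (reference = the
    supermolecular ground determinant) is diagonal in that basis with
    excitation energies eps_a - eps_i, so the matrix element contracts to

        sum_{i,a} S'[i,h1] S'[a,p1] S'[i,h2] S'[a,p2] (eps_a - eps_i).

    Test oracle only: it keeps the full expansion rather than the truncated
    closed formulas of :func:`v_le_ct`, and the two agree to leading order in
    the inter-fragment overlap.
    """
    if dimer.n_frag_orb > 14:
        raise SizeError(
            f"determinant oracle limited to 14 orbitals, got {dimer.n_frag_orb}"
        )
    ov = compute_overlaps(dimer)
    h1, p1 = _resolve_state(ov, state1)
    h2, p2 = _resolve_state(ov, state2)
    if (h1, p1) == (-1, -1) and (h2, p2) == (-1, -1):
        return 0.0  # reference against reference: normal ordering
    if (h1, p1) == (-1, -1) or (h2, p2) == (-1, -1):
        return 0.0  # diagonal H_N has no reference/single coupling

    eps, occ, virt, Sp = ov.sup_energies, ov.occ, ov.virt, ov.Sprime
    c1 = np.outer(Sp[occ, h1], Sp[virt, p1])
    c2 = np.outer(Sp[occ, h2], Sp[virt, p2])
    de = eps[virt][None, :] - eps[occ][:, None]
    return float(np.sum(c1 * c2 * de))
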