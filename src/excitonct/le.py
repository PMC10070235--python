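"""Locally-excited block: site energies and Coulomb (Foerster-type) couplings.

The LE/LE coupling is the Coulomb interaction between the transition densities
of excitations localized on the two fragments, evaluated here between their
discrete transition-charge representations; the classical point-dipole
approximation is provided for comparison.  Short-range exchange-correlation
and kinetic kernel contributions are outside this model (the Coulomb term is
the dominant Foerster contribution) and are reported as zero in metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError, InvalidParameterError, SingularityError
from .fragments import DimerSystem, TransitionChargeSet, make_transition_charges
from .units import HARTREE_TO_EV

__all__ = [
    "SiteEnergies",
    "coulomb_coupling",
    "pda_coupling",
    "site_energies_from_dimer",
    "le_couplings_from_dimer",
]

SITE_LABELS = ("Qy1", "Qx1", "Qy2", "Qx2")


@dataclass
class SiteEnergies:
    """Excitation (site) energies of the four LE states, in eV."""

    energies: dict[str, float]
    provenance: str = "toy"  # toy | file | external

    def __post_init__(self):
        missing = [k for k in SITE_LABELS if k not in self.energies]
        if missing:
            raise InputError(f"missing site energies for {missing}")
        if any(v <= 0 for v in self.energies.values()):
            raise InputError("site energies must be positive")
        if self.provenance == "toy":
            for frag in ("1", "2"):
                if self.energies[f"Qx{frag}"] < self.energies[f"Qy{frag}"] - 1e-12:
                    raise InputError(
                        f"toy site energies must have Qx{frag} >= Qy{frag}"
                    )

    def __getitem__(self, label: str) -> float:
        return self.energies[label]


def coulomb_coupling(tqA: TransitionChargeSet, tqB: TransitionChargeSet) -> float:
    """Coulomb coupling between two transition-charge sets (hartree).

    V = sum_{s in A, t in B} q_s q_t / |r_s - r_t|; symmetric in A <-> B and
    bilinear in the two charge sets.
    """
    d = np.linalg.norm(
        tqA.positions[:, None, :] - tqB.positions[None, :, :], axis=-1
    )
    if d.min() < 1e-10:
        raise SingularityError("coincident charge sites across the two fragments")
    return float(tqA.charges @ (1.0 / d) @ tqB.charges)


def pda_coupling(muA, muB, Rvec) -> float:
    """Point-dipole coupling [muA.muB - 3 (muA.Rhat)(muB.Rhat)] / R^3 (hartree)."""
    muA = np.asarray(muA, dtype=float)
    muB = np.asarray(muB, dtype=float)
    Rvec = np.asarray(Rvec, dtype=float)
    R = float(np.linalg.norm(Rvec))
    if R <= 0:
        raise InvalidParameterError("dipole separation must be positive")
    rhat = Rvec / R
    return float((muA @ muB - 3.0 * (muA @ rhat) * (muB @ rhat)) / R**3)


def site_energies_from_dimer(dimer: DimerSystem) -> SiteEnergies:
    """Frontier-gap site energies of a toy dimer (labels 1 = A, 2 = B), in eV."""
    out = {}
    for label, frag in (("1", dimer.fragA), ("2", dimer.fragB)):
        eps = frag.orbital_energies
        eL = eps[frag.frontier_index("L")]
        out[f"Qy{label}"] = (eL - eps[frag.frontier_index("H")]) * HARTREE_TO_EV
        out[f"Qx{label}"] = (eL - eps[frag.frontier_index("H'")]) * HARTREE_TO_EV
    return SiteEnergies(energies=out, provenance="toy")


def le_couplings_from_dimer(dimer: DimerSystem) -> dict[tuple[str, str], float]:
    """Transition-charge Coulomb couplings V_Qy and V_Qx of a toy dimer (eV)."""
    out = {}
    for name, pair in (("Qy", ("H", "L")), ("Qx", ("H'", "L"))):
        tqA = make_transition_charges(dimer.fragA, pair)
        tqB = make_transition_charges(dimer.fragB, pair)
        out[(f"{name}1", f"{name}2")] = coulomb_coupling(tqA, tqB) * HARTREE_TO_EV
    return out


#: provenance note attached to serialized LE couplings
LE_COUPLING_METADATA = {
    "xc_kinetic_kernel_terms": 0.0,
    "note": "Coulomb (Foerster) term only; short-range kernel contributions "
    "are outside the transition-charge model",
}
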