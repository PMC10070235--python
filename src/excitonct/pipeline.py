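"""End-to-end composition: toy dimer -> diabatic model -> adiabatic states.

Glues the block-level modules together for the common case of a toy dimer,
optionally embedded in a polarizable environment.  Each block is computed
independently of the others, mirroring the composite construction of the
model: site energies and LE couplings from the fragments' transition
properties, CT energies from charged-fragment energetics, LE-CT couplings
from the generalized fragment-orbital formulas.
"""

from __future__ import annotations

from .ct import ct_state_energies
from .drf import le_difference_charges, response_coupling_correction, site_energy_shift
from .fodft import all_le_ct_couplings, compute_overlaps
from .fragments import DimerSystem, make_transition_charges
from .hamiltonian import AdiabaticSolution, DiabaticModel, assemble, solve
from .le import le_couplings_from_dimer, site_energies_from_dimer, SiteEnergies
from .units import HARTREE_TO_EV

__all__ = ["diabatic_model_from_dimer", "solve_dimer"]

_LE_ROLE_PAIRS = {"Qy": ("H", "L"), "Qx": ("H'", "L")}


def diabatic_model_from_dimer(
    dimer: DimerSystem,
    env=None,
    include_overlaps: bool = True,
    apply_response_to_le: bool = True,
) -> DiabaticModel:
    """Assemble the 6x6 diabatic model of a toy dimer (entries in eV).

    With an environment, LE site energies acquire first-order shifts from
    their state-difference charges, LE/LE couplings the induced-dipole
    response correction, and CT energies the electrostatic + induction
    interaction of the separated charges with the environment.
    """
    site = site_energies_from_dimer(dimer)
    le_coup = le_couplings_from_dimer(dimer)

    if env is not None:
        shifted = dict(site.energies)
        for band, pair in _LE_ROLE_PAIRS.items():
            for num, frag in (("1", dimer.fragA), ("2", dimer.fragB)):
                pos, dq = le_difference_charges(frag, pair)
                shifted[f"{band}{num}"] += site_energy_shift(pos, dq, env)
        site = SiteEnergies(energies=shifted, provenance="toy")
        if apply_response_to_le:
            for band, pair in _LE_ROLE_PAIRS.items():
                tqA = make_transition_charges(dimer.fragA, pair)
                tqB = make_transition_charges(dimer.fragB, pair)
                key = (f"{band}1", f"{band}2")
                le_coup[key] += response_coupling_correction(tqA, tqB, env)

    ct = ct_state_energies(dimer, env=env)
    lect_ev = {
        pair: v * HARTREE_TO_EV for pair, v in all_le_ct_couplings(dimer).items()
    }
    overlaps = compute_overlaps(dimer) if include_overlaps else None
    return assemble(site, le_coup, ct.e_ct, lect_ev, overlaps=overlaps)


def solve_dimer(dimer: DimerSystem, env=None, **kwargs) -> AdiabaticSolution:
    """Convenience wrapper: assemble and solve in one call."""
    return solve(diabatic_model_from_dimer(dimer, env=env, **kwargs))
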