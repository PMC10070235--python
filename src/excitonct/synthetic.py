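"""Synthetic systems and snapshot ensembles.

Two generators:

* ``toy_dimer`` / ``toy_snapshot_table`` build genuine toy electronic
  systems (Slater fragments, model supermolecular orbitals) and run the
  full block pipeline on them; geometry jitter between snapshots emulates
  thermal fluctuation of a stacked chromophore pair.

* ``sample_snapshot_models`` draws per-snapshot diabatic matrices around
  prescribed ensemble statistics.  The default statistics
  (CHLA_DIMER_FIRST / CHLA_DIMER_LAST) describe a stacked chlorophyll-a
  dimer in the terminal-emitter domain of a light-harvesting antenna at the
  beginning and the end of an equilibration trajectory: the conformational
  change lowers the CT state energies and strengthens both the LE/LE and the
  LE/CT couplings, which is the mechanism behind the red shift of the lowest
  adiabatic state that ``drift_ensemble_shift`` measures.

Energies/couplings in eV throughout the ensemble-statistics interfaces.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ensemble import SnapshotTable
from .fragments import DimerSystem, build_dimer, make_toy_fragment
from .hamiltonian import (
    AdiabaticSolution,
    DiabaticModel,
    assemble,
    lowest_state_shift,
    solve,
)
from .le import SiteEnergies
from .pipeline import diabatic_model_from_dimer

__all__ = [
    "CHLA_DIMER_FIRST",
    "CHLA_DIMER_LAST",
    "toy_dimer",
    "toy_snapshot_table",
    "sample_snapshot_models",
    "solve_ensemble",
    "drift_ensemble_shift",
]

#: ensemble statistics {label: (mean eV, variance eV^2)} for a stacked
#: chlorophyll-a dimer before equilibration (larger inter-chromophore
#: distance): four Qy/Qx site energies, two CT energies, the Qy/Qy and Qx/Qx
#: Coulomb couplings and the fragment-orbital LE-CT couplings (magnitudes).
CHLA_DIMER_FIRST = {
    "Qy1": (2.02, 0.001),
    "Qy2": (2.01, 0.001),
    "Qx1": (2.27, 0.001),
    "Qx2": (2.26, 0.002),
    "CT1": (2.77, 0.008),
    "CT2": (3.28, 0.011),
    "V_Qy": (0.021, 6.2e-6),
    "V_Qx": (0.009, 2.8e-6),
    "V_QyA_CT1": (0.009, 4.3e-5),
    "V_QyA_CT2": (0.019, 1.8e-4),
    "V_QxA_CT2": (0.017, 2.2e-4),
    "V_QyB_CT1": (0.019, 1.9e-4),
    "V_QyB_CT2": (0.009, 4.5e-5),
    "V_QxB_CT1": (0.015, 9.1e-5),
}

#: the same dimer after equilibration (shorter stacking distance): CT states
#: come down by ~0.2-0.8 eV and every coupling grows.
CHLA_DIMER_LAST = {
    "Qy1": (2.03, 0.001),
    "Qy2": (1.99, 0.001),
    "Qx1": (2.28, 0.001),
    "Qx2": (2.21, 0.002),
    "CT1": (2.59, 0.009),
    "CT2": (2.52, 0.012),
    "V_Qy": (0.029, 3.1e-5),
    "V_Qx": (0.017, 1.6e-5),
    "V_QyA_CT1": (0.014, 1.2e-4),
    "V_QyA_CT2": (0.054, 1.6e-3),
    "V_QxA_CT2": (0.062, 2.0e-3),
    "V_QyB_CT1": (0.055, 1.6e-3),
    "V_QyB_CT2": (0.014, 1.2e-4),
    "V_QxB_CT1": (0.128, 3.4e-3),
}

_LECT_KEYS = {
    "V_QyA_CT1": ("QyA", "CT1"),
    "V_QyA_CT2": ("QyA", "CT2"),
    "V_QxA_CT2": ("QxA", "CT2"),
    "V_QyB_CT1": ("QyB", "CT1"),
    "V_QyB_CT2": ("QyB", "CT2"),
    "V_QxB_CT1": ("QxB", "CT1"),
}


def toy_dimer(
    separation: float = 7.0,
    n_sites: int = 4,
    zeta: float = 1.2,
    stacking_axis=(0.0, 0.0, 1.0),
    slip: float = 1.0,
    energy_offset_B: float = 0.0,
    overlap_scale: float = 1.0,
) -> DimerSystem:
    """A slip-stacked pair of identical toy chromophores.

    ``separation`` (bohr) displaces fragment B along ``stacking_axis``
    perpendicular to both chains; ``slip`` adds a longitudinal offset along
    the chain axis (a perfectly eclipsed stack makes several couplings vanish
    by parity, which real slip-stacked chromophore pairs do not);
    ``energy_offset_B`` (hartree) shifts every B orbital energy, breaking the
    A/B mirror symmetry when nonzero.
    """
    fragA = make_toy_fragment("A", n_sites=n_sites, zeta=zeta)
    fragB = make_toy_fragment("B", n_sites=n_sites, zeta=zeta)
    if energy_offset_B:
        fragB.orbital_energies = fragB.orbital_energies + energy_offset_B
    disp = np.asarray(stacking_axis, dtype=float)
    disp = separation * disp / np.linalg.norm(disp)
    disp = disp + np.array([slip, 0.0, 0.0])
    return build_dimer(fragA, fragB, disp, overlap_scale=overlap_scale)


def toy_snapshot_table(
    n_snapshots: int = 10,
    separation_mean: float = 7.0,
    separation_sigma: float = 0.15,
    rng: np.random.Generator | None = None,
    set_label: str = "toy",
    env=None,
) -> tuple[SnapshotTable, list[DiabaticModel]]:
    """Run the full toy pipeline on geometry-jittered snapshots.

    Each snapshot perturbs the stacking distance (Gaussian, ``sigma`` bohr)
    and records every diabatic matrix entry of the assembled model.
    """
    rng = rng or np.random.default_rng()
    rows, models = [], []
    provenance = "environment" if env is not None else "vacuum"
    for snap in range(n_snapshots):
        sep = separation_mean + separation_sigma * rng.standard_normal()
        model = diabatic_model_from_dimer(toy_dimer(separation=sep), env=env)
        models.append(model)
        for i, li in enumerate(model.labels):
            rows.append(
                {"snapshot": snap, "label": li, "value_eV": model.H[i, i],
                 "provenance": provenance}
            )
        for name, (a, b) in (("V_Qy", ("Qy1", "Qy2")), ("V_Qx", ("Qx1", "Qx2"))):
            rows.append(
                {"snapshot": snap, "label": name,
                 "value_eV": model.H[model.index(a), model.index(b)],
                 "provenance": provenance}
            )
    return SnapshotTable(pd.DataFrame(rows), set_label=set_label), models


def sample_snapshot_models(
    stats: dict[str, tuple[float, float]],
    n_snapshots: int,
    rng: np.random.Generator,
    coupling_sign: float = 1.0,
) -> list[DiabaticModel]:
    """Draw per-snapshot diabatic models around ensemble statistics.

    Each labelled quantity is sampled independently from a normal with the
    given mean and (population) variance; coupling magnitudes keep the sign
    convention ``coupling_sign``.  Sampled site energies respect the
    Qx >= Qy ordering by resampling-free clipping (swap-protection margin),
    keeping the generator deterministic under a seeded ``rng``.
    """
    models = []
    for _ in range(n_snapshots):
        draw = {
            k: m + np.sqrt(v) * rng.standard_normal() for k, (m, v) in stats.items()
        }
        for frag in ("1", "2"):
            lo = draw[f"Qy{frag}"] + 1e-6
            if draw[f"Qx{frag}"] < lo:
                draw[f"Qx{frag}"] = lo
        site = SiteEnergies(
            {k: draw[k] for k in ("Qy1", "Qx1", "Qy2", "Qx2")}, provenance="toy"
        )
        le = {
            ("Qy1", "Qy2"): coupling_sign * abs(draw["V_Qy"]),
            ("Qx1", "Qx2"): coupling_sign * abs(draw["V_Qx"]),
        }
        ct = {"CT1": draw["CT1"], "CT2": draw["CT2"]}
        lect = {
            pair: coupling_sign * abs(draw[key]) for key, pair in _LECT_KEYS.items()
        }
        models.append(assemble(site, le, ct, lect, overlaps=None))
    return models


def solve_ensemble(models: list[DiabaticModel]) -> list[AdiabaticSolution]:
    return [solve(m) for m in models]


def drift_ensemble_shift(
    n_snapshots: int = 50,
    seed: int = 0,
    stats_first: dict | None = None,
    stats_last: dict | None = None,
) -> dict:
    """Lowest-adiabatic-state drift between two snapshot ensembles.

    Samples ``n_snapshots`` diabatic models for the pre- and post-
    equilibration statistics, solves each, and reports the mean lowest
    adiabatic energies and their difference (negative = red shift of the
    second set).
    """
    rng = np.random.default_rng(seed)
    first = sample_snapshot_models(
        stats_first or CHLA_DIMER_FIRST, n_snapshots, rng
    )
    last = sample_snapshot_models(stats_last or CHLA_DIMER_LAST, n_snapshots, rng)
    sol_first = solve_ensemble(first)
    sol_last = solve_ensemble(last)
    shift = lowest_state_shift(sol_first, sol_last)
    return {
        "mean_lowest_first_eV": float(np.mean([s.energies[0] for s in sol_first])),
        "mean_lowest_last_eV": float(np.mean([s.energies[0] for s in sol_last])),
        "shift_eV": shift,
        "mean_ct_fraction_lowest_last": float(
            np.mean([s.ct_fraction[0] for s in sol_last])
        ),
        "mean_ct_fraction_lowest_first": float(
            np.mean([s.ct_fraction[0] for s in sol_first])
        ),
    }
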