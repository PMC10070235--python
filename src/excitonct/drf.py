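"""Discrete Reaction Field (DRF) polarizable environment.

The environment is a set of classical sites carrying permanent point charges
q_s and isotropic polarizabilities alpha_s.  Induced dipoles respond
self-consistently to the permanent charges, to the quantum (fragment) charge
distribution and to each other:

    mu_s = alpha_s [ E_perm(r_s) + sum_{t != s} T2_st mu_t ],

solved as one direct linear system.  The environment acts on the fragments
through the potential v_DRF = v_el + v_pol (permanent charges plus induced
dipoles), and on transition properties through the response term that uses
the transition charges themselves as the inducing source.

Exponential Thole damping of the site-site dipole tensors (default on,
a = 2.1304) prevents the polarization catastrophe at short contacts.

Units: bohr, e, bohr^3; energies returned by the shift/correction helpers
are in eV to match the file interfaces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    InvalidParameterError,
    PolarizationCatastropheError,
    SingularityError,
)
from .units import HARTREE_TO_EV

__all__ = [
    "EnvironmentSite",
    "InducedDipoleSolution",
    "interaction_tensor",
    "solve_induced_dipoles",
    "env_potentials",
    "site_energy_shift",
    "response_coupling_correction",
    "ct_difference_charges",
    "le_difference_charges",
]

THOLE_A_DEFAULT = 2.1304


@dataclass(frozen=True)
class EnvironmentSite:
    position: np.ndarray  # (3,) bohr
    charge: float = 0.0  # e
    alpha: float = 0.0  # bohr^3, isotropic

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.alpha < 0:
            raise InvalidParameterError("polarizability must be non-negative")


@dataclass
class InducedDipoleSolution:
    dipoles: np.ndarray  # (n_sites, 3) e*bohr, zero rows for alpha = 0
    residual: float
    induction_energy: float  # hartree, -1/2 sum mu.E_perm


def interaction_tensor(p, q, order: int):
    """Multipole interaction tensor T^(n) between points ``p`` and ``q``.

    With R = p - q: T0 = 1/R, T1_a = R_a/R^3, T2_ab = (3 R_a R_b - R^2 d_ab)/R^5
    (the sign convention under which a dipole mu at q produces the potential
    mu . T1 at p).
    """
    R = np.asarray(p, dtype=float) - np.asarray(q, dtype=float)
    r = float(np.linalg.norm(R))
    if r <= 1e-12:
        raise SingularityError("interaction tensor at coincident points")
    if order == 0:
        return 1.0 / r
    if order == 1:
        return R / r**3
    if order == 2:
        return (3.0 * np.outer(R, R) - r * r * np.eye(3)) / r**5
    raise InvalidParameterError(f"tensor order must be 0, 1 or 2, got {order}")


def _thole_lambdas(v: float) -> tuple[float, float]:
    # exponential Thole screening factors for T1 (lambda3) and T2 (lambda5)
    ev = math.exp(-v)
    lam3 = 1.0 - (0.5 * v * v + v + 1.0) * ev
    lam5 = lam3 - (v**3 / 6.0) * ev
    return lam3, lam5


def _damped_t2(pi, pj, ai, aj, damping, thole_a):
    T2 = interaction_tensor(pi, pj, 2)
    if damping == "none":
        return T2
    r = float(np.linalg.norm(np.asarray(pi) - np.asarray(pj)))
    v = thole_a * r / (ai * aj) ** (1.0 / 6.0)
    lam3, lam5 = _thole_lambdas(v)
    R = np.asarray(pi, dtype=float) - np.asarray(pj, dtype=float)
    return lam5 * 3.0 * np.outer(R, R) / r**5 - lam3 * np.eye(3) / r**3


def _permanent_field(
    sites: list[EnvironmentSite],
    qm_charges=None,
    external_field=None,
    include_env_charges: bool = True,
):
    """Field at every site from permanent env charges, QM charges, ext. field."""
    n = len(sites)
    E = np.zeros((n, 3))
    if external_field is not None:
        E += np.asarray(external_field, dtype=float)
    for s, site in enumerate(sites):
        if include_env_charges:
            for t, other in enumerate(sites):
                if t == s or other.charge == 0.0:
                    continue
                E[s] += other.charge * interaction_tensor(
                    site.position, other.position, 1
                )
        if qm_charges is not None:
            pos, q = qm_charges
            for rq, qq in zip(np.asarray(pos, dtype=float), np.asarray(q, dtype=float)):
                if qq == 0.0:
                    continue
                E[s] += qq * interaction_tensor(site.position, rq, 1)
    return E


def solve_induced_dipoles(
    sites: list[EnvironmentSite],
    qm_charges=None,
    external_field=None,
    damping: str = "thole",
    thole_a: float = THOLE_A_DEFAULT,
    include_env_charges: bool = True,
) -> InducedDipoleSolution:
    """Solve the coupled induced-dipole equations by direct linear solve.

    ``qm_charges`` is an optional ``(positions (n,3), charges (n,))`` pair of
    quantum-region sources; ``external_field`` an optional uniform field.
    ``damping`` is ``"thole"`` (exponential, factor ``thole_a``) or ``"none"``;
    damping acts on the site-site dipole tensors only.
    """
    if damping not in ("thole", "none"):
        raise InvalidParameterError(f"unknown damping scheme {damping!r}")
    n = len(sites)
    pos = np.array([s.position for s in sites]).reshape(n, 3)
    alphas = np.array([s.alpha for s in sites])
    pol = np.flatnonzero(alphas > 0.0)
    dipoles = np.zeros((n, 3))
    E_all = _permanent_field(sites, qm_charges, external_field, include_env_charges)
    if len(pol) == 0:
        return InducedDipoleSolution(dipoles, 0.0, 0.0)

    for i_idx, i in enumerate(pol):
        for j in pol[i_idx + 1 :]:
            if np.linalg.norm(pos[i] - pos[j]) <= 1e-12:
                raise SingularityError("coincident polarizable sites")

    m = len(pol)
    A = np.zeros((3 * m, 3 * m))
    for a in range(m):
        A[3 * a : 3 * a + 3, 3 * a : 3 * a + 3] = np.eye(3) / alphas[pol[a]]
        for b in range(a + 1, m):
            T2 = _damped_t2(
                pos[pol[a]], pos[pol[b]], alphas[pol[a]], alphas[pol[b]], damping, thole_a
            )
            A[3 * a : 3 * a + 3, 3 * b : 3 * b + 3] = -T2
            A[3 * b : 3 * b + 3, 3 * a : 3 * a + 3] = -T2
    rhs = E_all[pol].ravel()
    try:
        mu = np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:
        raise PolarizationCatastropheError(
            "singular induced-dipole response matrix; consider Thole damping "
            "or larger site separations"
        ) from exc
    if not np.all(np.isfinite(mu)):
        raise PolarizationCatastropheError("non-finite induced dipoles")
    residual = float(np.linalg.norm(A @ mu - rhs))
    dipoles[pol] = mu.reshape(m, 3)
    induction = -0.5 * float(np.sum(dipoles[pol] * E_all[pol]))
    return InducedDipoleSolution(dipoles, residual, induction)


def env_potentials(
    sites: list[EnvironmentSite],
    solution: InducedDipoleSolution | None,
    points,
) -> tuple[np.ndarray, np.ndarray]:
    """Electrostatic and polarization potentials v_el, v_pol at query points.

    v_el(r) = sum_s q_s T0(r, r_s);  v_pol(r) = sum_s mu_s . T1(r, r_s).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    v_el = np.zeros(len(points))
    v_pol = np.zeros(len(points))
    for k, r in enumerate(points):
        for s, site in enumerate(sites):
            if np.linalg.norm(r - site.position) <= 1e-12:
                raise SingularityError("query point coincides with an environment site")
            if site.charge != 0.0:
                v_el[k] += site.charge * interaction_tensor(r, site.position, 0)
            if solution is not None and np.any(solution.dipoles[s]):
                v_pol[k] += float(
                    solution.dipoles[s] @ interaction_tensor(r, site.position, 1)
                )
    return v_el, v_pol


def site_energy_shift(
    positions,
    difference_charges,
    sites: list[EnvironmentSite],
    damping: str = "thole",
    thole_a: float = THOLE_A_DEFAULT,
) -> float:
    """First-order environment shift of a state energy, in eV.

    ``difference_charges`` are the excited-minus-ground (or charged-minus-
    neutral) site charges of the fragment state.  Induced dipoles are
    re-solved with these state charges included as quantum sources, then the
    shift is sum(dq * v_DRF) over the fragment sites.
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    dq = np.asarray(difference_charges, dtype=float)
    if not np.any(dq):
        return 0.0
    sol = solve_induced_dipoles(
        sites, qm_charges=(positions, dq), damping=damping, thole_a=thole_a
    )
    v_el, v_pol = env_potentials(sites, sol, positions)
    return float(dq @ (v_el + v_pol)) * HARTREE_TO_EV


def response_coupling_correction(
    tqA,
    tqB,
    sites: list[EnvironmentSite],
    damping: str = "thole",
    thole_a: float = THOLE_A_DEFAULT,
) -> float:
    """Environment response correction to an LE/LE coupling, in eV.

    The dipoles induced by fragment A's transition charges act back on
    fragment B's transition charges:
    dV = -sum_s mu_s[tqA] . sum_t q_t T1(r_t, r_s).
    Permanent environment charges do not enter this (linear-response) term.
    """
    sol = solve_induced_dipoles(
        sites,
        qm_charges=(tqA.positions, tqA.charges),
        damping=damping,
        thole_a=thole_a,
        include_env_charges=False,
    )
    dv = 0.0
    for s, site in enumerate(sites):
        mu = sol.dipoles[s]
        if not np.any(mu):
            continue
        for rt, qt in zip(tqB.positions, tqB.charges):
            dv -= float(mu @ interaction_tensor(rt, site.position, 1)) * qt
    return dv * HARTREE_TO_EV


# ---------------------------------------------------------------------------
# state-difference charge helpers for the toy fragments
# ---------------------------------------------------------------------------

def le_difference_charges(frag, role_pair=("H", "L")):
    """Excited-minus-ground Mulliken site charges of an LE state (positions, dq).

    Promoting one electron occ -> virt changes the electron density by
    |virt|^2 - |occ|^2; the corresponding *charge* difference flips sign.
    """
    occ, virt = role_pair
    d_elec = frag.mulliken_orbital_populations(
        frag.frontier_index(virt)
    ) - frag.mulliken_orbital_populations(frag.frontier_index(occ))
    return frag.site_positions(), -d_elec


def ct_difference_charges(dimer, label: str):
    """Charge-difference distribution of a CT state over both fragments."""
    if label == "CT1":
        hole_frag, part_frag = dimer.fragA, dimer.fragB
    elif label == "CT2":
        hole_frag, part_frag = dimer.fragB, dimer.fragA
    else:
        raise InvalidParameterError(f"unknown CT label {label!r}")
    q_hole = hole_frag.mulliken_orbital_populations(hole_frag.frontier_index("H"))
    q_part = -part_frag.mulliken_orbital_populations(part_frag.frontier_index("L"))
    positions = np.vstack([hole_frag.site_positions(), part_frag.site_positions()])
    charges = np.concatenate([q_hole, q_part])
    return positions, charges
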