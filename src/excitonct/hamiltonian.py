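"""Assembly of the six-state diabatic model and its adiabatic solution.

The diabatic basis is ordered [Qy1, Qx1, Qy2, Qx2, CT1, CT2]: the four
locally excited states of the two fragments and the two charge-transfer
states (CT1 = A+B-, CT2 = A-B+).  The ground state is excluded from the
solved basis (its couplings to LE states vanish by construction and to CT
states are weak).  The Hamiltonian block structure:

* LE diagonal: site energies; LE off-diagonal: Coulomb transition-density
  couplings; the LE block of the overlap matrix is the unit matrix.
* CT diagonal: diabatic CT energies; the CT1-CT2 coupling and overlap are
  exactly zero (opposite-polarity transfer is a two-electron process).
* LE-CT block: generalized fragment-orbital couplings; the matching overlap
  entries default to single-determinant products (hole-overlap delta times
  electron overlap) and are zeroed when no orbital overlaps are supplied.

Adiabatic states solve H C = E S C (generalized, non-orthogonal); per-state
diabatic characters use Loewdin symmetric weights (S^(1/2) C) squared, with a
Mulliken-style alternative behind a flag.

All matrix entries in eV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import AssemblyError, InputError, MetricError
from .le import SiteEnergies

__all__ = [
    "BASIS_LABELS",
    "DiabaticModel",
    "AdiabaticSolution",
    "assemble",
    "solve",
    "characters",
    "lowest_state_shift",
]

logger = logging.getLogger(__name__)

BASIS_LABELS = ("Qy1", "Qx1", "Qy2", "Qx2", "CT1", "CT2")

#: LE-label translation between the coupling tables (fragment A/B) and the
#: diabatic basis (site 1/2)
_LE_TO_BASIS = {"QyA": "Qy1", "QxA": "Qx1", "QyB": "Qy2", "QxB": "Qx2"}

#: overlap-role products behind the default single-determinant S entries:
#: (LE label, CT label) -> (hole-overlap is delta?, (A role, B role) of the
#: non-trivial electron/hole overlap factor) or None for an exact zero
_S_LECT_RULES = {
    ("QyA", "CT1"): ("L", "L"),  # holes both H_A -> delta=1; electrons L_A|L_B
    ("QxA", "CT1"): None,  # holes H'_A vs H_A orthogonal
    ("QyA", "CT2"): ("H", "H"),  # electrons both L_A; holes H_A|H_B
    ("QxA", "CT2"): ("H'", "H"),
    ("QyB", "CT2"): ("L", "L"),
    ("QxB", "CT2"): None,
    ("QyB", "CT1"): ("H", "H"),
    ("QxB", "CT1"): ("H", "H'"),
}


@dataclass
class DiabaticModel:
    """6x6 diabatic Hamiltonian and overlap with block provenance (eV)."""

    H: np.ndarray
    S: np.ndarray
    labels: tuple[str, ...] = BASIS_LABELS
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.H = np.asarray(self.H, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        n = len(self.labels)
        if self.H.shape != (n, n) or self.S.shape != (n, n):
            raise InputError("H and S must be square over the basis labels")
        if np.max(np.abs(self.H - self.H.T)) > 1e-12:
            raise InputError("H must be symmetric to 1e-12")
        if np.max(np.abs(self.S - self.S.T)) > 1e-12:
            raise InputError("S must be symmetric to 1e-12")
        if np.max(np.abs(np.diag(self.S) - 1.0)) > 1e-12:
            raise InputError("S must have a unit diagonal")
        i1, i2 = self.labels.index("CT1"), self.labels.index("CT2")
        if self.H[i1, i2] != 0.0 or self.S[i1, i2] != 0.0:
            raise InputError(
                "CT1-CT2 coupling and overlap must be exactly zero "
                "(two-electron process)"
            )

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class AdiabaticSolution:
    """Generalized eigenpairs with per-state diabatic character weights."""

    energies: np.ndarray  # eV, ascending (degeneracies tie-broken, see solve)
    coefficients: np.ndarray  # columns S-normalized: C^T S C = I
    weights: list[dict[str, float]]  # per state: diabatic label -> weight
    labels: tuple[str, ...] = BASIS_LABELS

    @property
    def le_fraction(self) -> np.ndarray:
        return np.array(
            [sum(w[l] for l in self.labels if not l.startswith("CT")) for w in self.weights]
        )

    @property
    def ct_fraction(self) -> np.ndarray:
        return np.array(
            [sum(w[l] for l in self.labels if l.startswith("CT")) for w in self.weights]
        )


def assemble(
    site: SiteEnergies,
    le_couplings: dict,
    ct_energies: dict[str, float],
    lect: dict[tuple[str, str], float],
    overlaps=None,
    zero_same_side_qx: bool = False,
) -> DiabaticModel:
    """Assemble the 6x6 diabatic model from its block inputs (all in eV).

    ``le_couplings`` maps basis-label pairs, e.g. ("Qy1", "Qy2"), to Coulomb
    couplings; ``ct_energies`` maps CT1/CT2 to diabatic energies; ``lect``
    maps (LE, CT) pairs in either fragment (QyA...) or basis (Qy1...) naming
    to fragment-orbital couplings.  ``overlaps`` is an OverlapSet used for
    the default single-determinant LE-CT overlap entries; without it those
    entries are zero.  ``zero_same_side_qx`` additionally zeroes the
    Qx/same-side-CT couplings, mirroring tabulations that omit them.
    """
    n = len(BASIS_LABELS)
    H = np.zeros((n, n))
    S = np.eye(n)
    idx = {l: i for i, l in enumerate(BASIS_LABELS)}

    for label in ("Qy1", "Qx1", "Qy2", "Qx2"):
        try:
            H[idx[label], idx[label]] = site[label]
        except KeyError:
            raise AssemblyError(f"LE block: missing site energy {label}") from None
    for label in ("CT1", "CT2"):
        if label not in ct_energies:
            raise AssemblyError(f"CT block: missing energy {label}")
        H[idx[label], idx[label]] = ct_energies[label]

    for (a, b), v in le_couplings.items():
        if a not in idx or b not in idx:
            raise AssemblyError(f"LE block: unknown coupling labels ({a}, {b})")
        H[idx[a], idx[b]] = H[idx[b], idx[a]] = v

    for (le, ctl), v in lect.items():
        le_basis = _LE_TO_BASIS.get(le, le)
        if le_basis not in idx or ctl not in ("CT1", "CT2"):
            raise AssemblyError(f"LE-CT block: unknown pair ({le}, {ctl})")
        if zero_same_side_qx and _S_LECT_RULES.get(
            (_basis_to_frag(le_basis), ctl)
        ) is None:
            v = 0.0
        H[idx[le_basis], idx[ctl]] = H[idx[ctl], idx[le_basis]] = v

    if overlaps is not None:
        for (le, ctl), rule in _S_LECT_RULES.items():
            if rule is None:
                continue
            roleA, roleB = rule
            s = overlaps.s_frag(roleA, roleB)
            le_basis = _LE_TO_BASIS[le]
            S[idx[le_basis], idx[ctl]] = S[idx[ctl], idx[le_basis]] = s

    return DiabaticModel(
        H=H,
        S=S,
        provenance={
            "site_energies": site.provenance,
            "lect_overlaps": "single-determinant products" if overlaps is not None else "zeroed",
        },
    )


def _basis_to_frag(label: str) -> str:
    for frag, basis in _LE_TO_BASIS.items():
        if basis == label:
            return frag
    return label


def _sqrtm_spd(S: np.ndarray) -> np.ndarray:
    w, U = np.linalg.eigh(S)
    if w.min() <= 0:
        raise MetricError(f"overlap matrix not positive definite (min eig {w.min():.3e})")
    return U @ np.diag(np.sqrt(w)) @ U.T


def characters(
    coefficients: np.ndarray, model: DiabaticModel, scheme: str = "lowdin"
) -> list[dict[str, float]]:
    """Per-state diabatic weights.

    ``lowdin``: w_dk = (S^(1/2) C)^2_dk (sums to 1 per S-normalized state);
    ``mulliken``: diagonal of C * (S C) per column.
    """
    if scheme == "lowdin":
        W = (_sqrtm_spd(model.S) @ coefficients) ** 2
    elif scheme == "mulliken":
        W = coefficients * (model.S @ coefficients)
    else:
        raise InputError(f"unknown character scheme {scheme!r}")
    return [
        {label: float(W[d, k]) for d, label in enumerate(model.labels)}
        for k in range(coefficients.shape[1])
    ]


def solve(
    model: DiabaticModel,
    character_scheme: str = "lowdin",
    metric_eig_floor: float = 1e-8,
) -> AdiabaticSolution:
    """Solve the generalized eigenvalue problem H C = E S C.

    Uses the symmetric generalized solver for a positive definite S; if S has
    metric eigenvalues below ``metric_eig_floor`` those directions are
    discarded by canonical orthogonalization (with a logged warning).  Nearly
    degenerate eigenvalues are ordered by descending LE fraction, then by
    diabatic label order, so output is deterministic.
    """
    s_eigs = np.linalg.eigh(model.S)[0]
    if s_eigs.min() < -metric_eig_floor:
        raise MetricError(
            f"indefinite overlap matrix (min eig {s_eigs.min():.3e}, "
            f"cond {s_eigs.max() / abs(s_eigs.min()):.3e})"
        )
    if s_eigs.min() < metric_eig_floor:
        logger.warning(
            "overlap metric nearly singular (min eig %.3e); discarding "
            "directions below %.1e by canonical orthogonalization",
            s_eigs.min(),
            metric_eig_floor,
        )
        w, U = np.linalg.eigh(model.S)
        keep = w >= metric_eig_floor
        X = U[:, keep] / np.sqrt(w[keep])
        e, V = np.linalg.eigh(X.T @ model.H @ X)
        C = X @ V
    else:
        e, C = scipy.linalg.eigh(model.H, model.S)

    wts = characters(C, model, scheme=character_scheme)
    le_frac = np.array(
        [sum(w[l] for l in model.labels if not l.startswith("CT")) for w in wts]
    )
    # deterministic ordering for near-degenerate pairs
    order = sorted(
        range(len(e)),
        key=lambda k: (
            round(float(e[k]), 10),
            -round(float(le_frac[k]), 10),
            _dominant_label_rank(wts[k], model.labels),
        ),
    )
    e = e[order]
    C = C[:, order]
    wts = [wts[k] for k in order]
    return AdiabaticSolution(energies=e, coefficients=C, weights=wts, labels=model.labels)


def _dominant_label_rank(w: dict[str, float], labels) -> int:
    return max(range(len(labels)), key=lambda d: w[labels[d]])


def lowest_state_shift(ensembleA, ensembleB) -> float:
    """Mean lowest-adiabatic-energy difference, mean(E1 of B) - mean(E1 of A).

    Negative values mean ensemble B is red-shifted relative to A (eV).
    """
    if not ensembleA or not ensembleB:
        raise InputError("ensembles must be non-empty")
    eA = np.mean([sol.energies[0] for sol in ensembleA])
    eB = np.mean([sol.energies[0] for sol in ensembleB])
    return float(eB - eA)
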