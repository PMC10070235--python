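"""Analytic and semi-analytic integrals over normalized 1s Slater-type orbitals.

A normalized 1s STO with exponent zeta (bohr^-1) is
chi(r) = (zeta^3/pi)^(1/2) * exp(-zeta*r); its density integrates to one
electron.  Slater functions (rather than Gaussians) are used throughout so
that inter-fragment overlaps -- and with them every LE/CT coupling built on
top of them -- decay as exp(-beta*R), the physically correct long-range
behaviour for orbital-overlap-mediated couplings.

All distances in bohr, all energies in hartree.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.integrate import quad
from scipy.special import gamma, gammaincc

from .errors import InvalidParameterError, SingularityError

__all__ = ["sto_overlap", "sto_coulomb", "sto_coulomb_general", "sto_nuclear"]

#: exponents closer than this are treated as equal (closed forms apply)
_EQUAL_ZETA_TOL = 1e-12


def _check_exponent(zeta: float, name: str = "zeta") -> None:
    if not zeta > 0.0:
        raise InvalidParameterError(f"{name} must be positive, got {zeta}")


def sto_overlap(zeta1: float, zeta2: float, R: float) -> float:
    """Overlap of two normalized 1s STOs separated by ``R``.

    Equal exponents use the closed form ``exp(-rho)*(1 + rho + rho^2/3)``
    with ``rho = zeta*R``; unequal exponents are evaluated by quadrature in
    prolate-spheroidal coordinates (the two angular factors separate into
    1-D radial integrals).
    """
    _check_exponent(zeta1, "zeta1")
    _check_exponent(zeta2, "zeta2")
    if R < 0:
        raise InvalidParameterError(f"R must be non-negative, got {R}")

    if abs(zeta1 - zeta2) < _EQUAL_ZETA_TOL * max(zeta1, zeta2):
        rho = 0.5 * (zeta1 + zeta2) * R
        return math.exp(-rho) * (1.0 + rho + rho * rho / 3.0)

    if R * (zeta1 + zeta2) < 1e-6:
        # concentric limit, analytic (correction O((zeta R)^2) below 1e-12)
        return 8.0 * (zeta1 * zeta2) ** 1.5 / (zeta1 + zeta2) ** 3

    # prolate spheroidal coordinates: r1 = R(u+v)/2, r2 = R(u-v)/2,
    # dV = (R/2)^3 (u^2-v^2) du dv dphi;  the integrand separates into the
    # standard A_n / B_n auxiliary integrals.
    p = 0.5 * R * (zeta1 + zeta2)
    q = 0.5 * R * (zeta1 - zeta2)

    def a_int(n: int) -> float:
        # int_1^inf u^n e^(-p u) du, via the upper incomplete gamma function
        return float(gamma(n + 1) * gammaincc(n + 1, p) / p ** (n + 1))

    def b_int(n: int) -> float:
        val, _ = quad(lambda v: v**n * math.exp(-q * v), -1.0, 1.0)
        return val

    pref = (zeta1 * zeta2) ** 1.5 * R**3 / 4.0
    return pref * (a_int(2) * b_int(0) - a_int(0) * b_int(2))


def sto_coulomb(zeta: float, R: float) -> float:
    """Two-center Coulomb repulsion of two unit 1s charge clouds, equal ``zeta``.

    Closed form: ``1/R - exp(-2 zeta R) (1/R + 11 zeta/8 + 3 zeta^2 R/4
    + zeta^3 R^2/6)``.  Strictly below the point-charge value 1/R and tends
    to it as R grows.  At R = 0 the (finite) self-energy ``5 zeta/8`` is
    returned with a warning, since callers normally mean separated clouds.
    """
    _check_exponent(zeta)
    if R < 0:
        raise InvalidParameterError(f"R must be non-negative, got {R}")
    if R == 0.0:
        warnings.warn(
            "sto_coulomb at R=0: returning the finite self-energy 5*zeta/8",
            stacklevel=2,
        )
        return 5.0 * zeta / 8.0
    x = zeta * R
    return 1.0 / R - math.exp(-2.0 * x) * (
        1.0 / R + 11.0 * zeta / 8.0 + 0.75 * zeta * x + zeta * x * x / 6.0
    )


def _cloud_potential_antideriv(zeta: float, s: float) -> float:
    # antiderivative of s*Phi(s) where Phi is the potential of a unit 1s cloud
    return s + math.exp(-2.0 * zeta * s) * (0.75 / zeta + 0.5 * s)


def sto_coulomb_general(zeta1: float, zeta2: float, R: float) -> float:
    """Coulomb repulsion of two unit 1s clouds with independent exponents.

    The angular integral over the second cloud's potential is analytic; the
    remaining radial integral over the first density is done by quadrature.
    Falls back to the equal-exponent closed form when applicable.
    """
    _check_exponent(zeta1, "zeta1")
    _check_exponent(zeta2, "zeta2")
    if abs(zeta1 - zeta2) < 1e-9 * max(zeta1, zeta2):
        return sto_coulomb(zeta1, R)
    if R == 0.0:
        warnings.warn("sto_coulomb_general at R=0: concentric clouds", stacklevel=2)

    def integrand(r: float) -> float:
        rho = (zeta1**3 / math.pi) * math.exp(-2.0 * zeta1 * r)
        if R == 0.0:
            # spherical average of Phi2 over a shell centred on the cloud
            avg = sto_nuclear(zeta2, r) if r > 0 else zeta2
        else:
            hi = _cloud_potential_antideriv(zeta2, r + R)
            lo = _cloud_potential_antideriv(zeta2, abs(r - R))
            avg = (hi - lo) / (2.0 * r * R) if r > 0 else sto_nuclear(zeta2, R)
        return 4.0 * math.pi * r * r * rho * avg

    val, _ = quad(integrand, 0.0, np.inf, limit=200)
    return val


def sto_nuclear(zeta: float, R: float) -> float:
    """Coulomb interaction magnitude between a unit 1s cloud and a unit point charge.

    ``Phi(R) = 1/R - exp(-2 zeta R) (1/R + zeta)``; finite limit ``zeta`` at R = 0.
    """
    _check_exponent(zeta)
    if R < 0:
        raise InvalidParameterError(f"R must be non-negative, got {R}")
    if R == 0.0:
        return zeta
    return 1.0 / R - math.exp(-2.0 * zeta * R) * (1.0 / R + zeta)


def point_coulomb(q1: float, q2: float, R: float) -> float:
    """Point-charge Coulomb energy q1*q2/R (hartree)."""
    if R <= 0:
        raise SingularityError("coincident point charges")
    return q1 * q2 / R
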