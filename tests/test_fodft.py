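"""Generalized fragment-orbital LE-CT couplings.

The algebraic check re-implements every coupling formula as naive explicit
loops inside the test and demands agreement to 1e-12; the physical checks
use the determinant-expansion oracle and the exponential distance dependence.
"""

import numpy as np
import pytest

from excitonct.errors import ConfigurationError, SizeError
from excitonct.fodft import (
    CT_LABELS,
    LE_LABELS,
    OverlapSet,
    all_le_ct_couplings,
    compute_overlaps,
    determinant_oracle,
    v_le_ct,
)
from excitonct.synthetic import toy_dimer
from excitonct.units import HARTREE_TO_EV

FRONTIER = {"H'": 0, "H": 1, "L": 2}


def random_overlap_set(rng, scale=0.3):
    nA = nB = 3
    n_sup = nA + nB
    S = scale * (2 * rng.random((nA, nB)) - 1)
    Sprime = 2 * rng.random((n_sup, nA + nB)) - 1
    Sprime /= np.max(np.abs(Sprime)) + 0.1
    eps = np.sort(rng.normal(-0.2, 0.1, n_sup))
    return OverlapSet(
        S=S, Sprime=Sprime, sup_energies=eps, n_occ_sup=3, nA=nA,
        frontierA=dict(FRONTIER), frontierB=dict(FRONTIER),
    )


def naive_coupling(ov, pair):
    """Term-by-term loop implementation of the eight printed formulas."""
    eps = ov.sup_energies
    occ = range(ov.n_occ_sup)
    virt = range(ov.n_occ_sup, len(eps))
    Sp = ov.Sprime
    iHA, iHpA, iLA = (ov.frag_index("A", r) for r in ("H", "H'", "L"))
    iHB, iHpB, iLB = (ov.frag_index("B", r) for r in ("H", "H'", "L"))
    fA, fB = ov.frontierA, ov.frontierB
    sAB = lambda ra, rb: ov.S[fA[ra], fB[rb]]

    le, ct = pair
    total = 0.0
    if (le, ct) == ("QyA", "CT1"):
        for a in virt:
            total += eps[a] * Sp[a, iLA] * Sp[a, iLB]
        for i in occ:
            total -= eps[i] * sAB("L", "L") * Sp[i, iHA] ** 2
    elif (le, ct) == ("QxA", "CT1"):
        for i in occ:
            total -= eps[i] * sAB("L", "L") * Sp[i, iHpA] * Sp[i, iHA]
    elif (le, ct) == ("QyA", "CT2"):
        for i in occ:
            total -= eps[i] * Sp[i, iHA] * Sp[i, iHB]
        for a in virt:
            total += eps[a] * sAB("H", "H") * Sp[a, iLA] ** 2
    elif (le, ct) == ("QxA", "CT2"):
        for i in occ:
            total -= eps[i] * Sp[i, iHpA] * Sp[i, iHB]
        for a in virt:
            total += eps[a] * sAB("H'", "H") * Sp[a, iLA] ** 2
    elif (le, ct) == ("QyB", "CT2"):
        for a in virt:
            total += eps[a] * Sp[a, iLB] * Sp[a, iLA]
        for i in occ:
            total -= eps[i] * sAB("L", "L") * Sp[i, iHB] ** 2
    elif (le, ct) == ("QxB", "CT2"):
        for i in occ:
            total -= eps[i] * sAB("L", "L") * Sp[i, iHpB] * Sp[i, iHB]
    elif (le, ct) == ("QyB", "CT1"):
        for i in occ:
            total -= eps[i] * Sp[i, iHB] * Sp[i, iHA]
        for a in virt:
            total += eps[a] * sAB("H", "H") * Sp[a, iLB] ** 2
    elif (le, ct) == ("QxB", "CT1"):
        for i in occ:
            total -= eps[i] * Sp[i, iHpB] * Sp[i, iHA]
        for a in virt:
            total += eps[a] * sAB("H", "H'") * Sp[a, iLB] ** 2
    else:
        raise KeyError(pair)
    return total


ALL_PAIRS = [(le, ct) for le in LE_LABELS for ct in CT_LABELS]


class TestComputeOverlaps:
    def test_noninteracting_limits(self):
        d = toy_dimer(overlap_scale=0.0)
        ov = compute_overlaps(d)
        assert np.allclose(ov.S, 0.0)
        perm = np.abs(ov.Sprime)
        assert np.allclose(perm @ perm.T, np.eye(perm.shape[0]), atol=1e-10)

    def test_parseval_per_fragment(self, dimer):
        """S'^T S' restricted to one fragment = identity (complete expansion).

        Holds in the union metric: the supermolecular orbitals are
        orthonormal under sigma, so S'^T sigma^-1 S' = sigma; the fragment
        diagonal blocks of both sides are identities.
        """
        ov = compute_overlaps(dimer)
        sigma = dimer.frag_coeffs.T @ dimer.ao_overlap @ dimer.frag_coeffs
        lhs = ov.Sprime.T @ np.linalg.inv(
            dimer.sup_coeffs.T @ dimer.ao_overlap @ dimer.sup_coeffs
        ) @ ov.Sprime
        assert np.allclose(lhs, sigma, atol=1e-10)

    def test_hand_built_entries_match_direct_integrals(self):
        """S of a 1+1 orbital dimer equals the direct Slater overlap."""
        from excitonct.slater import sto_overlap
        from test_fragments import one_orbital_fragment
        from excitonct.fragments import build_dimer

        R = 4.0
        d = build_dimer(
            one_orbital_fragment("A"), one_orbital_fragment("B"), (0, 0, R)
        )
        ov = compute_overlaps(d)
        assert ov.S[0, 0] == pytest.approx(sto_overlap(1.0, 1.0, R), abs=1e-12)


class TestVleCT:
    @pytest.mark.parametrize("pair", ALL_PAIRS, ids=str)
    def test_matches_naive_summation_oracle(self, pair, rng):
        for _ in range(5):
            ov = random_overlap_set(rng)
            assert v_le_ct(ov, pair) == pytest.approx(
                naive_coupling(ov, pair), abs=1e-12
            )

    def test_noninteracting_all_zero(self):
        table = all_le_ct_couplings(toy_dimer(overlap_scale=0.0))
        assert all(abs(v) < 1e-12 for v in table.values())
        assert len(table) == 8

    def test_zero_ll_overlap_kills_qxa_ct1(self, rng):
        ov = random_overlap_set(rng)
        ov.S[FRONTIER["L"], FRONTIER["L"]] = 0.0
        assert v_le_ct(ov, ("QxA", "CT1")) == 0.0

    def test_mirror_symmetry(self, mirror_dimer):
        t = all_le_ct_couplings(mirror_dimer)
        assert abs(t[("QyA", "CT1")]) == pytest.approx(
            abs(t[("QyB", "CT2")]), abs=1e-10
        )
        assert abs(t[("QyA", "CT2")]) == pytest.approx(
            abs(t[("QyB", "CT1")]), abs=1e-10
        )

    def test_phase_flip_leaves_magnitudes(self, dimer, rng):
        ov = compute_overlaps(dimer)
        flip = rng.integers(0, ov.Sprime.shape[1])
        ov2 = OverlapSet(
            S=ov.S.copy(), Sprime=ov.Sprime.copy(),
            sup_energies=ov.sup_energies, n_occ_sup=ov.n_occ_sup, nA=ov.nA,
            frontierA=ov.frontierA, frontierB=ov.frontierB,
        )
        ov2.Sprime[:, flip] *= -1
        if flip < ov.nA:
            ov2.S[flip, :] *= -1
        else:
            ov2.S[:, flip - ov.nA] *= -1
        for pair in ALL_PAIRS:
            assert abs(v_le_ct(ov2, pair)) == pytest.approx(
                abs(v_le_ct(ov, pair)), abs=1e-12
            )

    def test_exponential_distance_dependence(self):
        """Each non-negligible |V| is log-linear in R with R^2 > 0.9."""
        Rs = np.linspace(5.0, 10.0, 6)
        tables = [all_le_ct_couplings(toy_dimer(separation=R)) for R in Rs]
        checked = 0
        for pair in ALL_PAIRS:
            vals = np.array([abs(t[pair]) for t in tables])
            if vals.min() < 1e-13:  # parity-suppressed couplings sit at the
                continue            # numerical floor in this geometry
            logv = np.log(vals)
            slope, b = np.polyfit(Rs, logv, 1)
            r2 = 1 - np.sum((logv - slope * Rs - b) ** 2) / np.sum(
                (logv - logv.mean()) ** 2
            )
            assert r2 > 0.9 and slope < 0
            checked += 1
        assert checked >= 6

    def test_unknown_pair_rejected(self, dimer):
        with pytest.raises(ConfigurationError):
            v_le_ct(compute_overlaps(dimer), ("QzA", "CT1"))

    def test_magnitudes_chlorophyll_scale(self, dimer):
        """At ~3.7 A stacking the couplings sit in the 1e-4..0.1 eV window."""
        table = all_le_ct_couplings(dimer)
        big = max(abs(v) for v in table.values()) * HARTREE_TO_EV
        assert 1e-3 < big < 0.5


class TestDeterminantOracle:
    def test_reference_element_vanishes(self, dimer):
        assert determinant_oracle(dimer, "reference", "reference") == 0.0

    def test_koopmans_diagonal_in_identical_basis(self):
        d = toy_dimer(overlap_scale=0.0)
        eps = d.fragA.orbital_energies
        expect = eps[d.fragA.frontier["L"]] - eps[d.fragA.frontier["H"]]
        assert determinant_oracle(d, "QyA", "QyA") == pytest.approx(
            expect, abs=1e-10
        )

    def test_size_guard(self):
        big = toy_dimer(n_sites=8)
        with pytest.raises(SizeError):
            determinant_oracle(big, "QyA", "CT1")

    @pytest.mark.parametrize("pair", [("QyA", "CT2"), ("QyB", "CT1")], ids=str)
    def test_agrees_with_formula_at_leading_order(self, pair):
        """|v_le_ct - oracle| shrinks monotonically with overlap scale eta,
        with fitted decay exponent >= 1 (leading-order agreement)."""
        etas = np.array([0.2, 0.1, 0.05, 0.025])
        diffs = []
        for eta in etas:
            d = toy_dimer(separation=6.0, overlap_scale=eta)
            ov = compute_overlaps(d)
            diffs.append(abs(v_le_ct(ov, pair) - determinant_oracle(d, *pair)))
        diffs = np.array(diffs)
        assert np.all(np.diff(diffs) < 0)
        slope = np.polyfit(np.log(etas), np.log(diffs), 1)[0]
        assert slope >= 1.0
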